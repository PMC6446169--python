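# Base-case model inputs for the adjunctive-cannabis neuropathic-pain
# cost-effectiveness microsimulation (2017 USD throughout).
#
# Each leaf is a distribution spec: `family` is one of
# normal | beta | gamma | triangular | log_odds_normal | point.
# `mean` is the point estimate used in base-case analysis; `sd` the
# dispersion used when the parameter is redrawn in probabilistic
# sensitivity analysis.  Entries parameterized by a 95% CI (`ci`) derive
# their dispersion from the interval: odds ratios on the log scale with
# sigma = (ln hi - ln lo)/(2*1.96), the cannabis adherence mean on the
# natural scale with sd = width/4.
# Utility decrements carry sd = mean/2.

baseline:
  age: {family: normal, mean: 59.72, sd: 9.79}
  pain_score: {family: normal, mean: 6.20, sd: 1.52}

agents:
  duloxetine:
    pain_reduction: {family: normal, mean: 2.57, sd: 2.31}
    p_nonserious_ae: {family: beta, mean: 0.660, sd: 0.012}
    p_intolerable_ae: {family: beta, mean: 0.157, sd: 0.012}
    p_serious_ae: {family: beta, mean: 0.024, sd: 0.004}
    adherence: {family: beta, mean: 0.86, sd: 0.18}
    discontinuation_rate: {family: beta, mean: 0.017, sd: 0.004}
    wholesale_cost_per_month: {family: gamma, mean: 254.0, sd: 20.0}
    oop_cost_per_month: {family: gamma, mean: 13.00, sd: 2.34}
  desipramine:
    pain_reduction: {family: normal, mean: 1.99, sd: 2.16}
    p_nonserious_ae: {family: beta, mean: 0.744, sd: 0.049}
    p_intolerable_ae: {family: beta, mean: 0.138, sd: 0.045}
    p_serious_ae: {family: beta, mean: 0.013, sd: 0.013}
    adherence: {family: beta, mean: 0.76, sd: 0.24}
    discontinuation_rate: {family: beta, mean: 0.026, sd: 0.018}
    wholesale_cost_per_month: {family: gamma, mean: 236.0, sd: 58.0}
    oop_cost_per_month: {family: gamma, mean: 22.25, sd: 7.04}
  gabapentin:
    pain_reduction: {family: normal, mean: 2.42, sd: 2.34}
    p_nonserious_ae: {family: beta, mean: 0.664, sd: 0.025}
    p_intolerable_ae: {family: beta, mean: 0.147, sd: 0.023}
    p_serious_ae: {family: beta, mean: 0.040, sd: 0.011}
    adherence: {family: beta, mean: 0.74, sd: 0.24}
    discontinuation_rate: {family: beta, mean: 0.023, sd: 0.008}
    wholesale_cost_per_month: {family: gamma, mean: 305.0, sd: 99.0}
    oop_cost_per_month: {family: gamma, mean: 8.79, sd: 3.54}
  pregabalin:
    pain_reduction: {family: normal, mean: 2.59, sd: 1.87}
    p_nonserious_ae: {family: beta, mean: 0.691, sd: 0.015}
    p_intolerable_ae: {family: beta, mean: 0.125, sd: 0.013}
    p_serious_ae: {family: beta, mean: 0.026, sd: 0.005}
    adherence: {family: beta, mean: 0.69, sd: 0.25}
    discontinuation_rate: {family: beta, mean: 0.039, sd: 0.007}
    wholesale_cost_per_month: {family: gamma, mean: 485.0, sd: 33.0}
    oop_cost_per_month: {family: gamma, mean: 19.63, sd: 9.98}

cannabis:
  pain_reduction: {family: normal, mean: 1.11, sd: 2.38}
  # "monotherapy" rates: nonadherent to the standard agent, adherent to cannabis
  p_nonserious_mono: {family: beta, mean: 0.586, sd: 0.034}
  p_intolerable_mono: {family: beta, mean: 0.046, sd: 0.014}
  p_serious_mono: {family: beta, mean: 0.005, sd: 0.005}
  or_nonserious: {family: log_odds_normal, mean: 1.74, ci: [1.42, 2.14]}
  or_nonserious_nonuser: {family: log_odds_normal, mean: 2.07, ci: [1.59, 2.70]}
  or_serious: {family: log_odds_normal, mean: 1.08, ci: [0.57, 2.04]}
  or_serious_nonuser: {family: log_odds_normal, mean: 1.77, ci: [0.72, 4.32]}
  adherence: {family: beta, mean: 0.84, ci: [0.78, 0.90]}
  discontinuation_rate: {family: beta, mean: 0.107, sd: 0.021}
  price_per_gram: {family: gamma, mean: 11.06, sd: 3.78}
  daily_thc_g: {family: gamma, mean: 0.067, sd: 0.034}
  thc_fraction: {family: point, mean: 0.125}
  # applied only in the wastage scenario; base case assumes fully
  # efficient consumption
  wastage: {family: beta, mean: 0.389, sd: 0.132}

adherence_threshold: {family: triangular, mean: 0.8, lo: 0.5, mode: 0.8, hi: 1.0}

sae_death_risk:
  age_18_44: {family: beta, mean: 0.012, sd: 0.001}
  age_45_64: {family: beta, mean: 0.016, sd: 0.002}
  age_65_84: {family: beta, mean: 0.019, sd: 0.002}
  age_85_plus: {family: beta, mean: 0.026, sd: 0.006}

sae_hospital_cost:
  age_18_44: {family: gamma, mean: 7387.0, sd: 130.0}
  age_45_64: {family: gamma, mean: 9447.0, sd: 165.0}
  age_65_84: {family: gamma, mean: 9664.0, sd: 292.0}
  age_85_plus: {family: gamma, mean: 8658.0, sd: 340.0}

sae_hospital_oop: {family: gamma, mean: 70.0, sd: 37.0}

utilities:
  mild: {family: beta, mean: 0.7, sd: 0.2}
  moderate_severe: {family: beta, mean: 0.39, sd: 0.33}

decrements:
  tolerable: {family: beta, mean: 0.05, sd: 0.025}
  intolerable: {family: beta, mean: 0.11, sd: 0.055}
  serious: {family: beta, mean: 0.12, sd: 0.06}

visit_costs:
  regular: {family: gamma, mean: 111.0, sd: 7.0}
  sae: {family: gamma, mean: 150.0, sd: 10.0}
  regular_oop: {family: gamma, mean: 51.0, sd: 4.0}
  sae_oop: {family: gamma, mean: 57.0, sd: 8.0}

settings:
  discount_rate: 0.03
  cycle_days: 42.0
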