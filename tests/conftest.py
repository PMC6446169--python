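import dataclasses

import numpy as np
import pytest

from cannacea import load_parameter_specs
from cannacea.parameters import AgentParams, CannabisParams


@pytest.fixture(scope="session")
def specs():
    return load_parameter_specs()


@pytest.fixture(scope="session")
def params(specs):
    return specs.point()


def tweak_agents(params, **changes):
    """All four standard agents modified the same way."""
    return params.replace(agents=tuple(dataclasses.replace(a, **changes)
                                       for a in params.agents))


def tweak_cannabis(params, **changes):
    return params.replace(cannabis=dataclasses.replace(params.cannabis, **changes))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def deterministic_mild_params(params):
    """Every patient: baseline pain 6, duloxetine-style reduction 3 with no
    dispersion, universal adherence, no adverse events, no discontinuation,
    so relief is good from the first cycle on every agent."""
    p = tweak_agents(params,
                     pain_reduction_mean=3.0, pain_reduction_sd=0.0,
                     p_nonserious_ae=0.0, p_intolerable_ae=0.0, p_serious_ae=0.0,
                     discontinuation_rate=0.0)
    p = tweak_cannabis(p,
                       pain_reduction_mean=0.0, pain_reduction_sd=0.0,
                       p_nonserious_mono=0.0, p_intolerable_mono=0.0,
                       p_serious_mono=0.0, discontinuation_rate=0.0,
                       or_nonserious=1.0, or_serious=1.0, price_per_gram=0.0)
    return p.replace(baseline_pain_mean=6.0, baseline_pain_sd=0.0,
                     adherence_threshold=0.0)


@pytest.fixture(scope="session")
def null_cannabis_params(params):
    """Cannabis made inert: zero efficacy, identity odds ratios, zero price,
    no cannabis-specific adverse events or discontinuation.  All four arms
    should then be indistinguishable."""
    return tweak_cannabis(params,
                          pain_reduction_mean=0.0, pain_reduction_sd=0.0,
                          or_nonserious=1.0, or_serious=1.0,
                          p_nonserious_mono=0.0, p_intolerable_mono=0.0,
                          p_serious_mono=0.0, discontinuation_rate=0.0,
                          price_per_gram=0.0)
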