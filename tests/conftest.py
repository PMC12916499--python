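import numpy as np
import pandas as pd
import pytest

import factorverse as fv


@pytest.fixture(scope="session")
def small_spec():
    """3 questionnaires x 8 items, 2 oblique factors — fast fitting fixture."""
    return fv.build_default_spec(3, [8, 8, 8], 2, seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    ds = fv.simulate_responses(small_spec, 600, seed=17)
    for cs in fv.default_cognition_specs().values():
        targets = {small_spec.factors[i]: v
                   for i, v in enumerate(cs.target_f2_per_factor.values())}
        planted = fv.CognitionSpec(outcome_label=cs.outcome_label,
                                   target_f2_per_factor=targets,
                                   covariate_effects=cs.covariate_effects,
                                   noise_sd=cs.noise_sd)
        ds = fv.attach_cognition(ds, planted, seed=23,
                                 factor_corr=small_spec.factor_corr)
    return ds


@pytest.fixture(scope="session")
def small_hetcor(small_dataset):
    return fv.heterogeneous_matrix(small_dataset.responses)


def random_correlation(p, rng, strength=0.6):
    """Random PSD correlation matrix from a low-rank loading structure."""
    L = rng.normal(scale=strength, size=(p, max(2, p // 3)))
    S = L @ L.T + np.diag(rng.uniform(0.3, 1.0, size=p))
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)
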