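"""Shared fixtures: all data are generated programmatically at test time."""

import numpy as np
import pytest

from mvgreml import MgremlModel, make_simulation_design, simulate_dataset


def small_dataset(n=40, m=80, t=2, rho=0.3, replicate=0, seed=0):
    """A tiny simulated dataset with a well-conditioned GRM (M > N)."""
    design = make_simulation_design(1, N=n, M=m, T=t, rho=rho, seed=seed)
    return simulate_dataset(design, replicate=replicate)


@pytest.fixture(scope="session")
def tiny_model():
    """Aligned model at oracle scale (N=30, T=2, L=0) with intercepts."""
    ds = small_dataset(n=30, m=70, t=2)
    return MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)


@pytest.fixture(scope="session")
def fitted_small():
    """A converged saturated fit (N=300, T=2) reused across tests."""
    ds = small_dataset(n=300, m=400, t=2, rho=0.5)
    model = MgremlModel(ds.grm, ds.phen, drop_leading_pcs=0)
    return model.fit()


def random_theta(spec_g, spec_e, rng, loc=0.7, scale=0.4):
    """A random parameter vector with diagonal-ish positive loadings."""
    from mvgreml.factors import ParameterVector, parameter_index

    index = parameter_index(spec_g, spec_e)
    values = rng.normal(loc=0.0, scale=scale, size=len(index))
    for i, (tag, t, f) in enumerate(index):
        if t == f:
            # diagonal loadings bounded away from zero keep V_E safely PD
            values[i] = rng.uniform(loc - 0.1, loc + 0.5)
    return ParameterVector(values=values, index=index)
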