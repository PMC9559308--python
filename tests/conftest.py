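"""Shared fixtures: the reference virtual plant and derived models.

Everything is generated programmatically from the synthetic-plant module;
session scope keeps the expensive artifacts (particle walks, fermentation
runs) shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from dyncompart.compartments import CompartmentStep
from dyncompart.fermentation import oxygen_saturation, simulate_fermentation, uniform_state
from dyncompart.synthetic import (
    make_reference_spec,
    synthetic_compartment_model,
)

#: solver settings used for calibration-grade simulations (coarse but fast)
FIT_SIM_KW = dict(rtol=1e-6, atol=1e-9, n_eval=5)


def make_step(V, Q, j=1, t_start=0.0, t_end=3600.0, eps=0.0, P=2.0e5, T=306.0):
    """Minimal compartment step for network-level tests (unit area)."""
    V = np.asarray(V, dtype=float)
    edges = np.concatenate([[0.0], np.cumsum(V)])
    K = V.size
    return CompartmentStep(
        j,
        t_start,
        t_end,
        float(edges[-1]),
        edges,
        V,
        np.asarray(Q, dtype=float),
        np.full(K, eps),
        np.full(K, P),
        np.full(K, T),
        np.full(max(K - 1, 0), 1000.0),
    )


@pytest.fixture(scope="session")
def ref_spec():
    return make_reference_spec(seed=7)


@pytest.fixture(scope="session")
def ref_model(ref_spec):
    """Full-resolution analytic compartment model (J=32, dz0=0.5 m)."""
    return synthetic_compartment_model(ref_spec)


@pytest.fixture(scope="session")
def coarse_model(ref_spec):
    """Coarse model used for fermentation/calibration studies."""
    return synthetic_compartment_model(ref_spec, dz0=6.0, dt_update=4 * 3600.0)


@pytest.fixture(scope="session")
def coarse_initial(ref_spec, coarse_model):
    first = coarse_model.zoned_steps[0]
    C_o0 = float(np.mean(oxygen_saturation(first.P_k)))
    return uniform_state(first, ref_spec.C_x0, ref_spec.C_s0, ref_spec.C_p0, C_o0)


@pytest.fixture(scope="session")
def coarse_truth_run(ref_spec, coarse_model, coarse_initial):
    """Ground-truth fermentation on the coarse model (the calibration
    reference scenario)."""
    return simulate_fermentation(
        coarse_model,
        ref_spec.truth,
        coarse_initial,
        ref_spec.feed,
        ref_spec.gas,
        kla_coeff=ref_spec.kla_coeff,
        **FIT_SIM_KW,
    )
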