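"""Synthetic virtual plant with known ground truth.

Everything the pipeline consumes — flow-follower pressure traces,
operating profiles, a compartment model and noisy concentration
observations — can be generated here from a prescribed axial velocity
field, liquid-height ramp and kinetic parameter set, so every processing
and modelling step is testable against exact truth without any external
data.

The particle model is a telegraph-style random walk: the device moves
with the local field speed, keeps its direction for an exponentially
distributed run time, and reflects at the vessel bottom and at the
liquid surface.  That reproduces the only statistics the pipeline
consumes (interface crossing speeds and occupancy) at trivial cost
compared to turbulence modelling.

The reference scenario emulates a 600 m^3 industrial bubble column:
5.3 m diameter, gassed liquid height ramping 16 -> 26 m over a 32-hr
fed-batch, ~0.2 m/s superficial gas velocity with a late-process
rampdown, and a two-loop axial circulation (strong mid-column flow, weak
ends) whose peak speed scales with the classical (g v_s D)^(1/3)
circulation-velocity group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .calibration import ObservationSet
from .compartments import (
    CompartmentStep,
    DynamicCompartmentModel,
    ZoneMap,
    autozone,
    _slab_edges,
)
from .constants import (
    G,
    P_REF,
    RHO_G_DEFAULT,
    RHO_L_DEFAULT,
    S_PER_HR,
    T_REF,
    TAU_CRIT_DEFAULT,
)
from .fermentation import FermentationResult, KineticParameters
from .profiles import Profile
from .traces import (
    AxialKinematics,
    ProcessedDevice,
    ReactorGeometry,
    SensorTrace,
    estimate_gas_holdup,
    fluid_density,
)

__all__ = [
    "PlantSpec",
    "make_reference_spec",
    "piecewise_speed_spec",
    "simulate_flow_follower",
    "truth_processed_device",
    "synthetic_compartment_model",
    "make_observations",
]

T_BROTH = 306.0  # broth temperature [K], constant by design


@dataclass
class PlantSpec:
    """Full description of the virtual plant (ground truth)."""

    geometry: ReactorGeometry
    t_end_hr: float = 32.0
    H_L0: float = 16.0  # initial gassed liquid height [m]
    H_L_end: float = 26.0  # final gassed liquid height [m]
    p_head0: float = 121_325.0  # headspace pressure at t=0 [Pa]
    p_head_drift: float = 3_000.0  # linear headspace drift over the process [Pa]
    gas: Profile = None  # type: ignore[assignment]  # [Nm^3/s]
    feed: Profile = None  # type: ignore[assignment]  # [kg/s]
    speed: Callable[[float, float], float] = None  # type: ignore[assignment]
    switch_time: float = 150.0  # mean direction-persistence time [s]
    pressure_noise: float = 200.0  # 1-sigma pressure noise [Pa]
    obs_cv: float = 0.05  # observation coefficient of variation
    truth: KineticParameters = field(default_factory=KineticParameters)
    kla_coeff: float = 0.288 * 3600.0  # [1/hr per m/s]; see docs/methods.md
    rho_l: float = RHO_L_DEFAULT
    C_x0: float = 2.0  # inoculum biomass [kg/m^3]
    C_s0: float = 15.0  # initial substrate [kg/m^3]
    C_p0: float = 2.0  # product carried over from the seed stage [kg/m^3]
    seed: int = 0

    @property
    def t_end(self) -> float:
        return self.t_end_hr * S_PER_HR

    def H_L(self, t_s):
        """Gassed liquid height [m] (linear ramp)."""
        frac = np.clip(np.asarray(t_s, dtype=float) / self.t_end, 0.0, 1.0)
        return self.H_L0 + (self.H_L_end - self.H_L0) * frac

    def p_head(self, t_s):
        """Headspace pressure [Pa] (slow linear drift from aeration)."""
        frac = np.clip(np.asarray(t_s, dtype=float) / self.t_end, 0.0, 1.0)
        return self.p_head0 + self.p_head_drift * frac

    def fluid_state(self, t_s):
        """Height-uniform dispersion state at time ``t_s``.

        The superficial gas velocity is corrected to the column-mid
        pressure; since that pressure itself depends on the dispersion
        density, a short fixed-point iteration closes the loop.
        """
        t_s = np.asarray(t_s, dtype=float)
        Qg = self.gas(t_s)
        A = self.geometry.A
        H = self.H_L(t_s)
        ph = self.p_head(t_s)
        rho = np.full_like(np.atleast_1d(ph), 900.0)
        for _ in range(4):
            P_mid = np.atleast_1d(ph) + rho * G * np.atleast_1d(H) / 2.0
            v_s = np.atleast_1d(Qg) / A * (P_REF / P_mid) * (T_BROTH / T_REF)
            eps = estimate_gas_holdup(v_s, self.geometry.D)
            rho = fluid_density(eps, self.rho_l, RHO_G_DEFAULT)
        if t_s.ndim == 0:
            return float(v_s[0]), float(eps[0]), float(rho[0])
        return v_s, eps, rho


def make_reference_spec(seed: int = 0) -> PlantSpec:
    """The packaged reference scenario (see module docstring)."""
    geom = ReactorGeometry(D=5.3, H_total=27.2, probe_clearance=5.85)
    t_end = 32.0 * S_PER_HR
    gas = Profile(
        np.array([0.0, 15.0 * S_PER_HR, t_end]),
        np.array([4.75, 4.75, 1.4]),
        name="Q_g_Nm3_per_s",
    )
    feed = Profile(
        np.array([0.0, 3 * S_PER_HR, 24 * S_PER_HR, 24 * S_PER_HR + 1.0, t_end]),
        np.array([0.3, 1.6, 1.6, 0.9, 0.9]),
        name="F_s_kg_per_s",
    )
    spec = PlantSpec(geometry=geom, gas=gas, feed=feed, seed=seed)

    # peak circulation speed tabulated once on a 60 s grid (the fluid-state
    # fixed point is far too slow to re-solve per particle step)
    t_grid = np.arange(0.0, t_end + 60.0, 60.0)
    v_s_grid, _, _ = spec.fluid_state(t_grid)
    peak_grid = 0.9 * np.cbrt(G * v_s_grid * geom.D)

    def speed(z, t_s):
        """Two-loop circulation: weak ends, strong mid-column; peak speed
        follows the (g v_s D)^(1/3) circulation group."""
        peak = np.interp(t_s, t_grid, peak_grid)
        x = np.clip(z / spec.H_L(t_s), 0.0, 1.0)
        return peak * (0.12 + 0.88 * np.sin(np.pi * x))

    spec.speed = speed
    return spec


def piecewise_speed_spec(
    bands: list[tuple[float, float]],
    H_L: float = 16.0,
    t_end_hr: float = 4.0,
    seed: int = 0,
) -> PlantSpec:
    """Spec with a piecewise-constant speed profile and a constant liquid
    height — the controlled configuration for flow-recovery checks.

    ``bands`` is a list of ``(top_height_m, speed_m_per_s)`` with
    increasing top heights covering ``[0, H_L]``.
    """
    geom = ReactorGeometry(D=5.3, H_total=H_L + 2.0, probe_clearance=min(5.85, H_L))
    tops = np.array([b[0] for b in bands])
    speeds = np.array([b[1] for b in bands])
    if tops[-1] < H_L:
        raise ValueError("bands must cover the full liquid height")
    spec = PlantSpec(
        geometry=geom,
        t_end_hr=t_end_hr,
        H_L0=H_L,
        H_L_end=H_L,
        p_head_drift=0.0,
        gas=Profile.constant(4.75, "Q_g_Nm3_per_s"),
        feed=Profile.constant(0.0, "F_s_kg_per_s"),
        seed=seed,
    )
    def speed(z, t_s):
        idx = np.clip(np.searchsorted(tops, z, side="left"), 0, speeds.size - 1)
        return speeds[idx] if not np.isscalar(z) else float(speeds[int(idx)])

    spec.speed = speed
    return spec


# ---------------------------------------------------------------------------
# flow-follower simulation
# ---------------------------------------------------------------------------


def simulate_flow_follower(
    spec: PlantSpec,
    device_density: float = 950.0,
    duration: float | None = None,
    seed: int | None = None,
    dt: float = 1.0,
    device_id: str | None = None,
    noise_sigma: float | None = None,
) -> tuple[SensorTrace, AxialKinematics]:
    """Simulate one device and emit its (noisy) trace plus exact truth.

    The particle's axial walk: move at the local field speed in the
    current direction; reverse with probability ``dt / switch_time`` per
    step; reflect at the bottom and at the (moving) liquid surface.  The
    pressure signal is ``P = p_head + rho_f (t) g (H_L - z)`` plus white
    Gaussian noise; temperature is the constant broth temperature.
    """
    if duration is None:
        duration = spec.t_end
    if duration > spec.t_end + 1e-6:
        raise ValueError("duration exceeds the plant-spec horizon")
    if seed is None:
        seed = spec.seed
    if noise_sigma is None:
        noise_sigma = spec.pressure_noise
    rng = np.random.default_rng(seed)
    n = int(np.floor(duration / dt)) + 1
    t = np.arange(n) * dt

    _, _, rho_f = spec.fluid_state(t)
    H = np.atleast_1d(spec.H_L(t))
    ph = np.atleast_1d(spec.p_head(t))

    z = np.empty(n)
    v = np.empty(n)
    zi = float(rng.uniform(0.2, 0.8) * H[0])
    diri = 1.0 if rng.random() < 0.5 else -1.0
    flips = rng.random(n) < dt / spec.switch_time
    for i in range(n):
        if flips[i]:
            diri = -diri
        s = float(spec.speed(zi, t[i]))
        v[i] = diri * s
        z[i] = zi
        zi = zi + diri * s * dt
        if zi <= 0.0:
            zi = -zi
            diri = 1.0
        h_next = H[min(i + 1, n - 1)]
        if zi >= h_next:
            zi = 2.0 * h_next - zi
            diri = -1.0
            zi = max(zi, 0.0)

    P = ph + rho_f * G * (H - z)
    if noise_sigma > 0:
        P = P + rng.normal(0.0, noise_sigma, size=n)
    dev = device_id or f"dev{int(device_density)}"
    trace = SensorTrace(dev, t, P, np.full(n, T_BROTH), device_density)
    truth = AxialKinematics(dev, t, z, v)
    return trace, truth


def truth_processed_device(
    spec: PlantSpec,
    trace: SensorTrace,
    truth: AxialKinematics,
) -> ProcessedDevice:
    """Wrap a simulated trace with its exact truth kinematics and fluid
    state, bypassing the pressure-inversion pipeline.

    Useful for testing the compartment builder in isolation from the
    trace-processing errors.
    """
    v_s, eps, rho_f = spec.fluid_state(trace.t)
    H = np.atleast_1d(spec.H_L(trace.t))
    base = np.atleast_1d(spec.p_head(trace.t)) + rho_f * G * H
    return ProcessedDevice(
        trace, truth, np.atleast_1d(v_s), np.atleast_1d(eps), rho_f, base, H
    )


# ---------------------------------------------------------------------------
# analytic compartment model (no particle statistics)
# ---------------------------------------------------------------------------


def synthetic_compartment_model(
    spec: PlantSpec,
    dz0: float = 0.5,
    dt_update: float = 3600.0,
    tau_crit: float = TAU_CRIT_DEFAULT,
) -> DynamicCompartmentModel:
    """Build the compartment model directly from the prescribed field.

    Volumes, hold-up and interface flows are evaluated analytically at
    each update step's midpoint (``Q = A (1 - eps) s(z_i) / 2``), skipping
    the particle statistics entirely.  This is the fast, deterministic
    route used for fermentation and calibration studies; the data-driven
    builder is exercised separately against the same prescription.
    """
    J = int(np.floor(spec.t_end / dt_update + 1e-9))
    A = spec.geometry.A
    steps = []
    zone_maps = []
    for j in range(1, J + 1):
        ts, te = (j - 1) * dt_update, j * dt_update
        tm = 0.5 * (ts + te)
        H = float(spec.H_L(tm))
        _, eps, rho = spec.fluid_state(tm)
        edges = _slab_edges(H, dz0)
        z_mid = 0.5 * (edges[:-1] + edges[1:])
        internal = edges[1:-1]
        eps_k = np.full(edges.size - 1, eps)
        V = A * np.diff(edges) * (1.0 - eps_k)
        speed_if = np.array([float(spec.speed(h, tm)) for h in internal])
        Q = A * (1.0 - eps) * speed_if / 2.0
        P_k = float(spec.p_head(tm)) + rho * G * (H - z_mid)
        step = CompartmentStep(
            j, ts, te, H, edges, V, Q,
            eps_k, P_k, np.full(edges.size - 1, T_BROTH),
            np.full(max(edges.size - 2, 0), 10_000.0),
        )
        steps.append(step)
        zone_maps.append(ZoneMap(j, autozone(V, Q, tau_crit)))
    return DynamicCompartmentModel(steps, zone_maps, spec.geometry, tau_crit)


# ---------------------------------------------------------------------------
# observations
# ---------------------------------------------------------------------------


def make_observations(
    spec: PlantSpec,
    result: FermentationResult,
    n_times: int = 15,
    cv: float | None = None,
    seed: int | None = None,
) -> ObservationSet:
    """Sample noisy observations from a simulated fermentation.

    Height-averaged biomass, substrate and product plus probe-height DO
    at ``n_times`` uniformly spaced times, with multiplicative lognormal
    noise of coefficient of variation ``cv``.
    """
    if cv is None:
        cv = spec.obs_cv
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    s = result.summary
    t_grid = np.linspace(0.5, spec.t_end_hr - 0.5, n_times)
    cols = {"biomass": "C_x_avg", "substrate": "C_s_avg", "product": "C_p_avg", "DO": "C_o_probe"}
    sigma = float(np.sqrt(np.log(1.0 + cv**2))) if cv > 0 else 0.0
    rows = []
    for var, col in cols.items():
        vals = np.interp(t_grid, s["t_hr"].to_numpy(), s[col].to_numpy())
        if sigma > 0:
            vals = vals * rng.lognormal(-0.5 * sigma**2, sigma, size=vals.size)
        for ti, vi in zip(t_grid, vals):
            rows.append({"t_hr": float(ti), "variable": var, "value": float(max(vi, 0.0))})
    return ObservationSet(pd.DataFrame(rows))
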