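"""Fed-batch fermentation on the dynamic compartment model.

State variables per zone: biomass ``C_x``, substrate ``C_s``, product
``C_p`` and dissolved oxygen ``C_o`` (all kg/m^3).  Kinetics (time unit:
hours):

    mu  = mu_max * Cs/(Cs+Ks) * Co/(Co+Ko) * (1 - Cp/Kp)      (growth,
          Monod in substrate and oxygen with linear product inhibition;
          mu < 0 for Cp > Kp represents cell death)
    r_p = Y_px * mu + r_xp                                    (growth- and
          non-growth-associated product formation)
    r_s = mu / Y_xs + r_p / Y_ps + r_ms                       (substrate
          uptake incl. maintenance)
    r_o = r_s / Y_so + r_mo                                   (oxygen
          uptake)

Oxygen enters through gas-liquid transfer ``kLa (C_sat - C_o)`` with a
per-zone ``kLa`` from the linear superficial-gas-velocity correlation and
a Henry's-law saturation concentration at the zone's hydrostatic
pressure.  Feed adds substrate to the top zone only; within an update
step volumes, flows and feed rate are frozen.  Between steps the species
masses are conservatively re-binned from one step's compartment geometry
onto the next's.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .compartments import CompartmentStep, DynamicCompartmentModel
from .constants import ATM, HENRY_CP, KLA_COEFF, M_O2, S_PER_HR, X_O2
from .profiles import Profile
from .traces import superficial_gas_velocity

__all__ = [
    "KineticParameters",
    "StateField",
    "TransferField",
    "StepTrajectory",
    "FermentationResult",
    "specific_growth_rate",
    "reaction_rates",
    "local_kla",
    "oxygen_saturation",
    "make_transfer_field",
    "simulate_step",
    "rebin_state",
    "simulate_fermentation",
    "uniform_state",
]

SPECIES = ("x", "s", "p", "o")

#: Substrate / oxygen concentrations [kg/m^3] below which maintenance and
#: uptake rates are smoothly gated to zero (starvation handling).
S_GATE = 1e-3
O_GATE = 1e-5


@dataclass
class KineticParameters:
    """Kinetic and stoichiometric parameters (units in field comments).

    The defaults are order-of-magnitude literature-style placeholder
    values for an aerobic glucose-to-diol E. coli process; any real
    application calibrates them against plant observations.
    """

    mu_max: float = 0.40  # max specific growth rate [1/hr]
    K_s: float = 0.05  # substrate half-saturation [kg/m^3]
    K_o: float = 2e-4  # oxygen half-saturation [kg/m^3]
    K_p: float = 110.0  # critical (growth-arresting) product conc. [kg/m^3]
    Y_px: float = 1.6  # growth-associated product yield [kg P / kg X]
    r_xp: float = 0.06  # non-growth-associated production [kg P / kg X / hr]
    Y_xs: float = 0.35  # biomass yield on substrate [kg X / kg S]
    Y_ps: float = 0.50  # product yield on substrate [kg P / kg S]
    Y_so: float = 8.0  # substrate per oxygen [kg S / kg O2] (largely
    # fermentative product pathway: modest O2 demand per substrate)
    r_ms: float = 0.02  # maintenance substrate uptake [kg S / kg X / hr]
    r_mo: float = 0.002  # maintenance oxygen uptake [kg O2 / kg X / hr]

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("r_xp", "r_ms", "r_mo"):
                if v < 0:
                    raise ValueError(f"{f.name} must be non-negative")
            elif v <= 0:
                raise ValueError(f"{f.name} must be strictly positive")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(**d)

    def replace(self, **kw) -> "KineticParameters":
        return replace(self, **kw)


@dataclass
class StateField:
    """Per-zone concentrations on one step's zoning; ``C`` is (4, K) in
    the species order (x, s, p, o)."""

    j: int
    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        if self.C.shape[0] != 4:
            raise ValueError("state must have 4 species rows (x, s, p, o)")

    @property
    def K(self) -> int:
        return self.C.shape[1]


@dataclass
class TransferField:
    """Per-zone oxygen-transfer quantities for one step."""

    kla: np.ndarray  # [1/hr]
    C_sat: np.ndarray  # [kg/m^3]
    v_s_local: np.ndarray  # [m/s]

    def __post_init__(self) -> None:
        self.kla = np.asarray(self.kla, dtype=float)
        self.C_sat = np.asarray(self.C_sat, dtype=float)
        self.v_s_local = np.asarray(self.v_s_local, dtype=float)
        if np.any(self.kla < 0):
            raise ValueError("kLa must be non-negative")
        if np.any(self.C_sat <= 0):
            raise ValueError("saturation concentration must be positive")


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------


def specific_growth_rate(C_s, C_o, C_p, params: KineticParameters):
    """Monod growth with oxygen limitation and linear product inhibition;
    negative above the critical product concentration (cell death)."""
    C_s = np.asarray(C_s, dtype=float)
    C_o = np.asarray(C_o, dtype=float)
    C_p = np.asarray(C_p, dtype=float)
    return (
        params.mu_max
        * (C_s / (C_s + params.K_s))
        * (C_o / (C_o + params.K_o))
        * (1.0 - C_p / params.K_p)
    )


def reaction_rates(C_s, C_o, C_p, params: KineticParameters):
    """Specific rates ``(mu, r_p, r_s, r_o)`` [per kg biomass, per hr].

    Maintenance and non-growth-associated terms are smoothly gated to
    zero as the corresponding substrate/oxygen concentration vanishes,
    so that starvation cannot drive concentrations negative.
    """
    C_s = np.asarray(C_s, dtype=float)
    C_o = np.asarray(C_o, dtype=float)
    gate_s = C_s / (C_s + S_GATE)
    gate_o = C_o / (C_o + O_GATE)
    mu = specific_growth_rate(C_s, C_o, C_p, params)
    r_p = params.Y_px * mu + params.r_xp * gate_s
    r_s = mu / params.Y_xs + r_p / params.Y_ps + params.r_ms * gate_s
    r_o = (r_s / params.Y_so + params.r_mo * gate_s) * gate_o
    return mu, r_p, r_s, r_o


def local_kla(v_s_local, coeff: float = KLA_COEFF):
    """Volumetric mass-transfer coefficient, ``kLa = coeff * v_s`` [1/hr].

    The default coefficient 0.288 is the literal correlation constant
    (kLa in 1/hr with v_s in m/s); see docs/methods.md for the unit
    discussion and the value used by the reference scenario.
    """
    v = np.asarray(v_s_local, dtype=float)
    if np.any(v < 0):
        raise ValueError("superficial gas velocity must be non-negative")
    out = coeff * v
    return float(out) if np.isscalar(v_s_local) else out


def oxygen_saturation(
    P_local,
    x_O2: float = X_O2,
    H_cp: float = HENRY_CP,
    M_o2: float = M_O2,
):
    """Henry's-law oxygen saturation concentration [kg/m^3].

    ``C_sat = H_cp * x_O2 * (P / 1 atm) * M_O2 * 1000`` with ``H_cp`` in
    mol/L/atm (pure-water solubility at 306 K by default).
    """
    P = np.asarray(P_local, dtype=float)
    if np.any(P <= 0):
        raise ValueError("pressure must be positive")
    out = H_cp * x_O2 * (P / ATM) * M_o2 * 1000.0
    return float(out) if np.isscalar(P_local) else out


def make_transfer_field(
    step: CompartmentStep,
    Q_g_ref: float,
    A: float,
    kla_coeff: float = KLA_COEFF,
    x_O2: float = X_O2,
    H_cp: float = HENRY_CP,
) -> TransferField:
    """Per-zone kLa and oxygen saturation from the step's mean pressures
    and temperatures and the gas flow at reference conditions."""
    v_s = superficial_gas_velocity(Q_g_ref, A, step.P_k, step.T_k)
    return TransferField(local_kla(v_s, kla_coeff), oxygen_saturation(step.P_k, x_O2, H_cp), v_s)


# ---------------------------------------------------------------------------
# within-step integration
# ---------------------------------------------------------------------------


@dataclass
class StepTrajectory:
    """Solution of one update step."""

    step_j: int
    t_hr: np.ndarray  # absolute process time at eval points [hr]
    C: np.ndarray  # (4, K, n_t)
    C_end: np.ndarray  # (4, K)
    fed_kg: float  # substrate fed during the step
    consumed_kg: float  # substrate consumed (integrated r_s Cx V)


def simulate_step(
    step: CompartmentStep,
    state0: StateField,
    transfer: TransferField,
    params: KineticParameters,
    feed_rate: float,
    feed_zone: int | None = None,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_eval: int = 25,
    flow_multiplier: float = 1.0,
) -> StepTrajectory:
    """Integrate one update step with frozen volumes, flows and feed.

    ``feed_rate`` is in kg/s (converted internally to the hourly kinetics
    regime); feed enters ``feed_zone`` (default: the top zone).  An extra
    quadrature state tracks cumulative substrate consumption so that the
    substrate balance closes to solver precision.
    """
    K = step.K
    if state0.K != K:
        raise ValueError("initial state does not match the step zoning")
    if feed_zone is None:
        feed_zone = K - 1
    V = step.V
    Q_hr = step.Q * S_PER_HR * flow_multiplier
    kla, C_sat = transfer.kla, transfer.C_sat
    F_hr = feed_rate * S_PER_HR  # kg/hr
    dt_hr = (step.t_end - step.t_start) / S_PER_HR

    def rhs(t, y):
        C = np.maximum(y[: 4 * K].reshape(4, K), 0.0)
        Cx, Cs, Cp, Co = C[0], C[1], C[2], C[3]
        mu, r_p, r_s, r_o = reaction_rates(Cs, Co, Cp, params)
        dC = np.empty((4, K))
        dC[0] = mu * Cx
        dC[1] = -r_s * Cx
        dC[2] = r_p * Cx
        dC[3] = kla * (C_sat - Co) - r_o * Cx
        if K > 1:
            flux = Q_hr * (C[:, 1:] - C[:, :-1])
            dC[:, :-1] += flux / V[:-1]
            dC[:, 1:] -= flux / V[1:]
        dC[1, feed_zone] += F_hr / V[feed_zone]
        dy = np.empty(4 * K + 1)
        dy[: 4 * K] = dC.ravel()
        dy[4 * K] = float(np.sum(r_s * Cx * V))  # kg substrate / hr
        return dy

    y0 = np.concatenate([state0.C.ravel(), [0.0]])
    t_hr = np.linspace(step.t_start / S_PER_HR, step.t_end / S_PER_HR, n_eval)
    sol = solve_ivp(
        rhs,
        (t_hr[0], t_hr[-1]),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_hr,
    )
    if not sol.success:
        raise RuntimeError(
            f"fermentation integration failed at step {step.j}: {sol.message}; "
            f"state snapshot {np.array2string(sol.y[:, -1], precision=4)}"
        )
    C_traj = sol.y[: 4 * K].reshape(4, K, -1)
    return StepTrajectory(
        step.j,
        t_hr,
        C_traj,
        C_traj[..., -1].copy(),
        fed_kg=F_hr * dt_hr,
        consumed_kg=float(sol.y[4 * K, -1]),
    )


# ---------------------------------------------------------------------------
# inter-step mass re-binning
# ---------------------------------------------------------------------------


def rebin_state(
    C_end: np.ndarray, step_j: CompartmentStep, step_j1: CompartmentStep
) -> np.ndarray:
    """Conservative three-stage mass map between consecutive geometries.

    1. Concentrations become masses via the current step's volumes.
    2. Masses are diluted into temporary compartments: the current
       geometry with every volume scaled by the total-volume ratio
       ``V_{j+1}/V_j``.
    3. Masses redistribute onto the next step's compartments by
       fractional volume overlap (a compartment split in half by a new
       interface passes half its mass to each part).

    Works on any ``(n_species, K_j)`` concentration array; returns the
    ``(n_species, K_{j+1})`` initial concentrations for the next step.
    """
    C_end = np.atleast_2d(np.asarray(C_end, dtype=float))
    V1, V2 = step_j.V, step_j1.V
    tot1, tot2 = V1.sum(), V2.sum()
    if tot1 <= 0 or tot2 <= 0:
        raise ValueError("total volume must be positive")
    M = C_end * V1  # (n, K1) masses, unchanged by the dilution stage
    # temporary geometry: current compartments scaled to the next total
    edges_tmp = np.concatenate([[0.0], np.cumsum(V1 * (tot2 / tot1))])
    edges_new = np.concatenate([[0.0], np.cumsum(V2)])
    edges_new[-1] = edges_tmp[-1]  # identical totals by construction
    # cumulative mass is piecewise linear in the volume coordinate
    out = np.empty((C_end.shape[0], V2.size))
    for i in range(C_end.shape[0]):
        cumM = np.concatenate([[0.0], np.cumsum(M[i])])
        out[i] = np.diff(np.interp(edges_new, edges_tmp, cumM))
    return out / V2


# ---------------------------------------------------------------------------
# full-process simulation
# ---------------------------------------------------------------------------


@dataclass
class FermentationResult:
    """Chained multi-step fermentation solution."""

    trajectories: pd.DataFrame  # long format: t_hr, step, zone, z_mid_m, C_*
    summary: pd.DataFrame  # t_hr, volume-average concentrations, q_p, ...
    params: KineticParameters
    fed_kg: float
    consumed_kg: float
    final_state: StateField

    def species_mass(self, species: str) -> pd.Series:
        """Total mass of one species (kg) vs. time, from the trajectories."""
        col = f"C_{species}"
        df = self.trajectories
        return df.groupby("t_hr").apply(
            lambda g: float(np.sum(g[col].to_numpy() * g["V_m3"].to_numpy())),
            include_groups=False,
        )


def uniform_state(step: CompartmentStep, C_x=1.0, C_s=10.0, C_p=0.0, C_o=0.008) -> StateField:
    """Spatially uniform initial state on a step's zoning."""
    K = step.K
    C = np.vstack(
        [np.full(K, C_x), np.full(K, C_s), np.full(K, C_p), np.full(K, C_o)]
    )
    return StateField(step.j, C)


def simulate_fermentation(
    model: DynamicCompartmentModel,
    params: KineticParameters,
    initial: StateField,
    feed_profile: Profile,
    gas_profile: Profile,
    *,
    feed_height: float | None = None,
    feed_shifts: list[tuple[float, float, float]] | None = None,
    flow_multiplier: float = 1.0,
    kla_coeff: float = KLA_COEFF,
    x_O2: float = X_O2,
    H_cp: float = HENRY_CP,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_eval: int = 25,
) -> FermentationResult:
    """Chain :func:`simulate_step` and :func:`rebin_state` over all steps.

    ``feed_height``: height of the feed entry point [m]; ``None`` feeds
    the liquid surface (top zone).  ``feed_shifts`` applies piecewise
    offsets ``(delta_kg_s, t_start_s, t_end_s)`` to the feed profile for
    what-if scenarios.  ``flow_multiplier`` scales every exchange flow
    (large values emulate ideal mixing).
    """
    steps = model.zoned_steps
    if initial.K != steps[0].K:
        raise ValueError("initial state must be on the first step's zoning")
    feed = feed_profile.shifted(feed_shifts) if feed_shifts else feed_profile
    A = model.geometry.A
    probe_h = model.geometry.probe_clearance

    state = initial
    rows = []
    srows = []
    fed_total = 0.0
    consumed_total = 0.0
    for i, step in enumerate(steps):
        F = feed.mean(step.t_start, step.t_end)
        Qg = gas_profile.mean(step.t_start, step.t_end)
        transfer = make_transfer_field(step, Qg, A, kla_coeff, x_O2, H_cp)
        fz = None if feed_height is None else step.zone_for_height(min(feed_height, step.H_L))
        traj = simulate_step(
            step,
            state,
            transfer,
            params,
            F,
            fz,
            rtol=rtol,
            atol=atol,
            n_eval=n_eval,
            flow_multiplier=flow_multiplier,
        )
        fed_total += traj.fed_kg
        consumed_total += traj.consumed_kg

        z_mid = step.z_mid
        V = step.V
        probe_zone = step.zone_for_height(probe_h)
        # last eval point of a step coincides with the first of the next;
        # keep the earlier step's copy only
        sel = slice(None, -1) if i < len(steps) - 1 else slice(None)
        for ti, t in enumerate(traj.t_hr[sel]):
            C = traj.C[:, :, ti]
            for k in range(step.K):
                rows.append(
                    (t, step.j, k, z_mid[k], V[k], C[0, k], C[1, k], C[2, k], C[3, k])
                )
            mu, r_p, _, _ = reaction_rates(C[1], C[3], C[2], params)
            q_p = float(np.sum(r_p * C[0] * V) / V.sum())
            srows.append(
                (
                    t,
                    step.j,
                    float(V.sum()),
                    *(float(np.average(C[s], weights=V)) for s in range(4)),
                    float(C[3, probe_zone]),
                    q_p,
                )
            )
        if i + 1 < len(steps):
            C_next = rebin_state(traj.C_end, step, steps[i + 1])
            state = StateField(steps[i + 1].j, C_next)
        else:
            state = StateField(step.j, traj.C_end)

    trajectories = pd.DataFrame(
        rows,
        columns=["t_hr", "step", "zone", "z_mid_m", "V_m3", "C_x", "C_s", "C_p", "C_o"],
    )
    summary = pd.DataFrame(
        srows,
        columns=[
            "t_hr",
            "step",
            "V_tot_m3",
            "C_x_avg",
            "C_s_avg",
            "C_p_avg",
            "C_o_avg",
            "C_o_probe",
            "q_p",
        ],
    )
    return FermentationResult(
        trajectories, summary, params, fed_total, consumed_total, state
    )
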