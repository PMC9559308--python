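"""Kinetic-parameter estimation against plant observations.

The objective is the (optionally weighted) sum of squared errors between
simulated and observed concentrations.  Biomass, substrate and product
observations are compared against the volume-weighted height-average
concentration; dissolved oxygen is compared against the zone containing
the DO probe height.  Minimisation uses the derivative-free Nelder-Mead
simplex, by default on log-transformed parameters so positivity is
preserved without explicit constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .compartments import DynamicCompartmentModel
from .fermentation import (
    FermentationResult,
    KineticParameters,
    StateField,
    simulate_fermentation,
)
from .profiles import Profile

__all__ = [
    "ObservationSet",
    "FitResult",
    "sse_objective",
    "fit_parameters",
    "recovery_report",
]

VARIABLES = ("biomass", "substrate", "product", "DO")
_VAR_COL = {"biomass": "C_x_avg", "substrate": "C_s_avg", "product": "C_p_avg", "DO": "C_o_probe"}

#: Large finite penalty returned when a candidate parameter set makes the
#: simulation fail (keeps the simplex moving instead of crashing).
PENALTY = 1e12


@dataclass
class ObservationSet:
    """Sampled plant observations.

    ``records`` is a DataFrame with columns ``t_hr``, ``variable`` (one of
    biomass / substrate / product / DO) and ``value`` (kg/m^3).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = {"t_hr", "variable", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        bad = set(df["variable"]) - set(VARIABLES)
        if bad:
            raise ValueError(f"unknown observation variables {sorted(bad)}")
        if (df["value"] < 0).any():
            raise ValueError("observed concentrations must be non-negative")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservationSet":
        return cls(pd.read_csv(path, comment="#"))

    def default_weights(self) -> dict[str, float]:
        """Per-variable weights 1/var(observed values) — normalises the
        very different scales of biomass (kg/m^3) and DO (g/m^3)."""
        out = {}
        for var, grp in self.records.groupby("variable"):
            v = float(np.var(grp["value"].to_numpy()))
            out[str(var)] = 1.0 / v if v > 0 else 1.0
        return out


def _predictions(result: FermentationResult, obs: ObservationSet) -> np.ndarray:
    s = result.summary
    t = s["t_hr"].to_numpy()
    pred = np.empty(len(obs))
    for var, col in _VAR_COL.items():
        m = (obs.records["variable"] == var).to_numpy()
        if m.any():
            pred[m] = np.interp(obs.records.loc[m, "t_hr"].to_numpy(), t, s[col].to_numpy())
    return pred


def sse_objective(
    params: KineticParameters,
    model: DynamicCompartmentModel,
    initial: StateField,
    feed_profile: Profile,
    gas_profile: Profile,
    obs: ObservationSet,
    weights: dict[str, float] | None = None,
    **sim_kwargs,
) -> float:
    """Weighted sum of squared simulated-minus-observed errors.

    A failed simulation returns a large finite penalty rather than
    raising, so the optimiser can back out of a bad region.
    """
    if len(obs) == 0:
        raise ValueError("observation set is empty")
    if weights is None:
        weights = obs.default_weights()
    try:
        result = simulate_fermentation(
            model, params, initial, feed_profile, gas_profile, **sim_kwargs
        )
    except (RuntimeError, ValueError, FloatingPointError) as exc:  # pragma: no cover
        warnings.warn(f"simulation failed during fitting: {exc}", stacklevel=2)
        return PENALTY
    pred = _predictions(result, obs)
    w = obs.records["variable"].map(weights).to_numpy(dtype=float)
    resid = pred - obs.records["value"].to_numpy(dtype=float)
    sse = float(np.sum(w * resid**2))
    return sse if np.isfinite(sse) else PENALTY


@dataclass
class FitResult:
    params: KineticParameters
    sse: float
    nfev: int
    converged: bool
    message: str
    free: tuple[str, ...]
    history: list[float] = field(default_factory=list, repr=False)


def fit_parameters(
    init: KineticParameters,
    model: DynamicCompartmentModel,
    initial_state: StateField,
    feed_profile: Profile,
    gas_profile: Profile,
    obs: ObservationSet,
    free: tuple[str, ...] = ("mu_max", "K_p", "Y_px"),
    log_scale: bool = True,
    maxfev: int = 2000,
    xatol: float = 1e-6,
    fatol: float = 1e-10,
    weights: dict[str, float] | None = None,
    **sim_kwargs,
) -> FitResult:
    """Nelder-Mead minimisation of :func:`sse_objective` over ``free``
    parameters (all others held at their ``init`` values).

    With ``log_scale`` the simplex moves in log-parameter space, which
    keeps every parameter positive without imposing bounds; raw-space
    search is available for strict fidelity to an unconstrained fit.
    """
    if weights is None:
        weights = obs.default_weights()
    x0 = np.array([getattr(init, name) for name in free], dtype=float)
    if log_scale:
        x0 = np.log(x0)
    history: list[float] = []

    def unpack(x) -> KineticParameters:
        vals = np.exp(x) if log_scale else x
        return init.replace(**dict(zip(free, vals)))

    def fun(x):
        if not log_scale and np.any(x <= 0):
            return PENALTY * (1.0 + float(np.sum(np.maximum(-x, 0.0))))
        val = sse_objective(
            unpack(x), model, initial_state, feed_profile, gas_profile, obs,
            weights=weights, **sim_kwargs,
        )
        history.append(val)
        return val

    res = minimize(
        fun,
        x0,
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol},
    )
    if not res.success:
        warnings.warn(f"optimiser did not converge: {res.message}", stacklevel=2)
    return FitResult(
        unpack(res.x), float(res.fun), int(res.nfev), bool(res.success),
        str(res.message), tuple(free), history,
    )


def recovery_report(
    truth: KineticParameters,
    fitted: list[KineticParameters],
    free: tuple[str, ...] | None = None,
    unident_rmse: float = 0.5,
) -> pd.DataFrame:
    """Per-parameter relative bias and RMSE over a fit ensemble.

    Parameters with relative RMSE above ``unident_rmse`` are flagged as
    practically unidentifiable on the given observation design.
    """
    if len(fitted) < 2:
        raise ValueError("need at least two fits for a recovery report")
    names = free if free is not None else tuple(truth.to_dict())
    rows = []
    for name in names:
        tv = getattr(truth, name)
        vals = np.array([getattr(f, name) for f in fitted], dtype=float)
        rel = (vals - tv) / tv
        rows.append(
            {
                "parameter": name,
                "truth": tv,
                "median_fit": float(np.median(vals)),
                "rel_bias": float(np.mean(rel)),
                "rel_rmse": float(np.sqrt(np.mean(rel**2))),
                "median_abs_rel_err": float(np.median(np.abs(rel))),
                "unidentifiable": bool(np.sqrt(np.mean(rel**2)) > unident_rmse),
            }
        )
    return pd.DataFrame(rows)
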