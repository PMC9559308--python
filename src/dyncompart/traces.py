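"""Flow-follower trace processing.

A flow-following sensor device is a neutrally buoyant instrumented sphere
carried with the broth that logs absolute pressure and temperature at 1 Hz.
Because hydrostatic pressure increases linearly with depth, the axial
position of the device follows from Pascal's law,

    z(t) = (P_max(t) - P(t)) / (rho_f * g),

where ``P_max`` is the (dynamic) pressure at the vessel bottom and
``rho_f`` the density of the aerated gas-liquid dispersion.  This module
turns raw ``(t, P, T)`` traces into axial positions and velocities,
correcting for headspace-pressure drift, liquid-volume growth and gas
hold-up.

The bottom-pressure envelope ``P_max(t)`` is estimated with a rolling
maximum over a window long enough (default 1 hr) for the device to visit
the vessel bottom at least once, then smoothed with a rolling average.
Gas hold-up is estimated from the superficial gas velocity with a
heterogeneous-churn-flow correlation,

    eps = v_s / (0.25 + 0.45 * (g * v_s * D)**(1/3)),

and the dispersion density is the volume-weighted mean
``rho_f = (1 - eps) * rho_l + eps * rho_g``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    G,
    P_REF,
    RHO_G_DEFAULT,
    RHO_L_DEFAULT,
    T_REF,
)
from .profiles import Profile

__all__ = [
    "ReactorGeometry",
    "SensorTrace",
    "FluidState",
    "AxialKinematics",
    "ProcessedDevice",
    "estimate_gas_holdup",
    "fluid_density",
    "baseline_pressure",
    "pressure_to_position",
    "axial_velocity",
    "superficial_gas_velocity",
    "process_device",
    "process_trace",
    "select_devices",
    "read_traces_csv",
    "write_kinematics_csv",
    "read_kinematics_csv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ReactorGeometry:
    """Bubble-column geometry (cylindrical shell, flat-bottom idealisation).

    Parameters
    ----------
    D : column diameter [m].
    H_total : vessel height [m].
    probe_clearance : height of the wall-mounted DO/pH probes above the
        bottom drain valve [m].
    bottom_shape : only ``"cylindrical"`` is modelled; the real dished
        bottom head is deliberately ignored (slight overestimate of the
        bottom compartment volume).
    """

    D: float
    H_total: float
    probe_clearance: float = 0.0
    bottom_shape: str = "cylindrical"

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError("reactor diameter must be positive")
        if not (0.0 <= self.probe_clearance <= self.H_total):
            raise ValueError("probe clearance must lie within the vessel height")
        if self.bottom_shape != "cylindrical":
            raise ValueError("only a cylindrical bottom is supported")

    @property
    def A(self) -> float:
        """Cross-sectional area [m^2]."""
        return float(np.pi * self.D**2 / 4.0)


@dataclass
class SensorTrace:
    """One device's time series of absolute pressure and temperature."""

    device_id: str
    t: np.ndarray  # [s], strictly increasing, nominally 1 Hz
    P: np.ndarray  # [Pa], absolute
    T: np.ndarray  # [K]
    rho_p: float  # device density [kg/m^3]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if self.t.size < 2:
            raise ValueError("sensor trace needs at least two samples")
        if not (self.t.shape == self.P.shape == self.T.shape):
            raise ValueError("t, P, T must have identical shapes")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("trace times must be strictly increasing")
        if np.any(self.P <= 0):
            raise ValueError("absolute pressure must be positive everywhere")

    @property
    def dt(self) -> float:
        """Median sampling interval [s]."""
        return float(np.median(np.diff(self.t)))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class FluidState:
    """Instantaneous gas-liquid dispersion state."""

    eps: np.ndarray  # gas fraction [-]
    rho_l: float  # liquid density [kg/m^3]
    rho_g: float  # gas density [kg/m^3]
    rho_f: np.ndarray  # dispersion density [kg/m^3]
    v_s: np.ndarray  # superficial gas velocity [m/s]


@dataclass
class AxialKinematics:
    """Derived axial position and velocity for one device."""

    device_id: str
    t: np.ndarray  # [s]
    z: np.ndarray  # [m] above vessel bottom
    v_z: np.ndarray  # [m/s]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.v_z = np.asarray(self.v_z, dtype=float)
        if not (self.t.shape == self.z.shape == self.v_z.shape):
            raise ValueError("t, z, v_z must have identical shapes")
        if not np.all(np.isfinite(self.v_z)):
            raise ValueError("axial velocity must be finite")
        if np.any(self.z < -1e-9):
            raise ValueError("axial position must be non-negative")


@dataclass
class ProcessedDevice:
    """Bundle of a raw trace with all derived per-sample quantities.

    The compartment builder needs more than bare kinematics (pressures,
    temperatures and gas fractions are averaged into compartments), so the
    processing pipeline returns this richer record; :func:`process_trace`
    is the thin wrapper that extracts only the kinematics.
    """

    trace: SensorTrace
    kin: AxialKinematics
    v_s: np.ndarray
    eps: np.ndarray
    rho_f: np.ndarray
    baseline: np.ndarray  # bottom-pressure envelope [Pa]
    H_L: np.ndarray  # instantaneous gassed liquid height [m]


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def estimate_gas_holdup(v_s, D: float, g: float = G):
    """Gas hold-up from the heterogeneous-regime correlation.

    ``eps = v_s / (0.25 + 0.45 (g v_s D)^(1/3))``; returns 0 for zero gas
    flow.  Accepts scalars or arrays of superficial gas velocity.
    """
    v_arr = np.asarray(v_s, dtype=float)
    if np.any(v_arr < 0):
        raise ValueError("superficial gas velocity must be non-negative")
    if D <= 0:
        raise ValueError("diameter must be positive")
    eps = v_arr / (0.25 + 0.45 * np.cbrt(g * v_arr * D))
    return float(eps) if np.isscalar(v_s) else eps


def fluid_density(eps, rho_l: float = RHO_L_DEFAULT, rho_g: float = RHO_G_DEFAULT):
    """Dispersion density as the volume-weighted phase mean.

    ``rho_f = (1 - eps) rho_l + eps rho_g``.
    """
    eps_arr = np.asarray(eps, dtype=float)
    if np.any(eps_arr < 0) or np.any(eps_arr >= 1):
        raise ValueError("gas fraction must lie in [0, 1)")
    if not rho_l > rho_g >= 0:
        raise ValueError("need rho_l > rho_g >= 0")
    rho = (1.0 - eps_arr) * rho_l + eps_arr * rho_g
    return float(rho) if np.isscalar(eps) else rho


def _rolling(series: np.ndarray, n: int, how: str) -> np.ndarray:
    s = pd.Series(series).rolling(n, center=True, min_periods=1)
    return getattr(s, how)().to_numpy()


def baseline_pressure(
    trace: SensorTrace,
    window_max: float = 3600.0,
    window_smooth: float = 600.0,
) -> np.ndarray:
    """Dynamic bottom-pressure envelope ``P_max(t)``.

    Rolling maximum of the measured pressure over ``window_max`` seconds
    (centred; the device is assumed to visit the vessel bottom within any
    such window) followed by a rolling average over ``window_smooth``
    seconds to remove the staircase artifacts of the maximum filter.
    """
    if trace.duration < window_max:
        raise ValueError(
            f"trace of {trace.duration:.0f} s is shorter than the "
            f"{window_max:.0f} s rolling-maximum window: insufficient data"
        )
    n_max = max(int(round(window_max / trace.dt)), 1)
    n_smooth = max(int(round(window_smooth / trace.dt)), 1)
    return _rolling(_rolling(trace.P, n_max, "max"), n_smooth, "mean")


def pressure_to_position(P, P_max, rho_f, g: float = G, H_L=None):
    """Invert Pascal's law: ``z = (P_max - P) / (rho_f g)``.

    Small negative pressure differences (noise while the device rides the
    surface) clip to ``z = 0`` ... at the *bottom*; note z increases upward
    so negative ``P_max - P`` means the device momentarily measured more
    than the bottom envelope and is clipped to 0 height difference from
    the bottom reference, i.e. ``z = 0``.  If ``H_L`` is given, positions
    above the instantaneous liquid height clip to ``H_L``.
    """
    rho_arr = np.asarray(rho_f, dtype=float)
    if np.any(rho_arr <= 0):
        raise ValueError("fluid density must be positive")
    z = (np.asarray(P_max, dtype=float) - np.asarray(P, dtype=float)) / (rho_arr * g)
    z = np.maximum(z, 0.0)
    if H_L is not None:
        z = np.minimum(z, np.asarray(H_L, dtype=float))
    return float(z) if np.isscalar(P) else z


def axial_velocity(t, z, smooth_window: float = 5.0) -> np.ndarray:
    """Axial velocity by central finite differences of ``z(t)``.

    ``z`` is optionally pre-smoothed with a centred moving average of
    ``smooth_window`` seconds to suppress 1 Hz pressure noise; endpoints
    use one-sided differences (``numpy.gradient`` semantics).
    """
    t = np.asarray(t, dtype=float)
    z = np.asarray(z, dtype=float)
    if t.size < 3:
        raise ValueError("need at least three samples to differentiate")
    dt_all = np.diff(t)
    if np.any(dt_all <= 0):
        raise ValueError("time must be strictly increasing")
    if smooth_window and smooth_window > 0:
        n = max(int(round(smooth_window / float(np.median(dt_all)))), 1)
        z = _rolling(z, n, "mean")
    return np.gradient(z, t)


def superficial_gas_velocity(
    Q_g_ref,
    A: float,
    P_local,
    T_local,
    P_ref: float = P_REF,
    T_ref: float = T_REF,
):
    """Local superficial gas velocity by ideal-gas rescaling.

    ``v_s = (Q_g_ref / A) * (P_ref / P_local) * (T_local / T_ref)`` where
    ``Q_g_ref`` is the gas volumetric flow at reference conditions
    (normal m^3/s).
    """
    if A <= 0:
        raise ValueError("cross-section must be positive")
    P_arr = np.asarray(P_local, dtype=float)
    if np.any(P_arr <= 0):
        raise ValueError("local pressure must be positive")
    return (
        np.asarray(Q_g_ref, dtype=float)
        / A
        * (P_ref / P_arr)
        * (np.asarray(T_local, dtype=float) / T_ref)
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def process_device(
    trace: SensorTrace,
    geom: ReactorGeometry,
    gas_profile: Profile,
    headspace_profile: Profile | None = None,
    *,
    rho_l: float = RHO_L_DEFAULT,
    rho_g: float = RHO_G_DEFAULT,
    window_max: float = 3600.0,
    window_smooth: float = 600.0,
    vel_smooth: float = 5.0,
    pressure_correction: str = "column_mid",
    g: float = G,
) -> ProcessedDevice:
    """Full processing pipeline for one device.

    Steps: local superficial gas velocity from the gas profile corrected
    to instantaneous pressure/temperature; gas hold-up from the churn-flow
    correlation; dispersion density; bottom-pressure baseline; position by
    Pascal's law; velocity by finite differences.

    ``pressure_correction`` selects the pressure at which the gas velocity
    (and hence hold-up and density) is evaluated:

    - ``"column_mid"`` (default): the instantaneous column-mid pressure,
      i.e. the mean of the rolling bottom-pressure and top-pressure
      envelopes.  This matches the single, height-uniform dispersion
      density that Pascal's-law inversion assumes.
    - ``"device"``: the pressure measured at the device's own depth.
    """
    if trace.t[0] < gas_profile.t[0] - 1e-9 and gas_profile.t.size > 1:
        raise ValueError("gas profile does not cover the start of the trace")

    Q_g = gas_profile(trace.t)
    base = baseline_pressure(trace, window_max, window_smooth)

    n_max = max(int(round(window_max / trace.dt)), 1)
    n_smooth = max(int(round(window_smooth / trace.dt)), 1)
    top_env = _rolling(_rolling(trace.P, n_max, "min"), n_smooth, "mean")

    if pressure_correction == "column_mid":
        P_corr = 0.5 * (base + top_env)
    elif pressure_correction == "device":
        P_corr = trace.P
    else:
        raise ValueError("pressure_correction must be 'column_mid' or 'device'")

    v_s = superficial_gas_velocity(Q_g, geom.A, P_corr, trace.T)
    eps = estimate_gas_holdup(v_s, geom.D, g)
    rho_f = fluid_density(eps, rho_l, rho_g)

    if headspace_profile is not None:
        p_head = headspace_profile(trace.t)
        if np.any(trace.P < p_head - 5000.0):
            warnings.warn(
                f"device {trace.device_id}: measured pressure drops below the "
                "headspace profile; check the profile alignment",
                stacklevel=2,
            )

    # instantaneous gassed liquid height from the envelope span
    H_L = (base - top_env) / (rho_f * g)
    z = pressure_to_position(trace.P, base, rho_f, g, H_L=H_L)
    v_z = axial_velocity(trace.t, z, vel_smooth)
    kin = AxialKinematics(trace.device_id, trace.t, z, v_z)
    return ProcessedDevice(trace, kin, v_s, eps, rho_f, base, H_L)


def process_trace(
    trace: SensorTrace,
    geom: ReactorGeometry,
    gas_profile: Profile,
    headspace_profile: Profile | None = None,
    **kwargs,
) -> AxialKinematics:
    """As :func:`process_device`, returning only the axial kinematics."""
    return process_device(trace, geom, gas_profile, headspace_profile, **kwargs).kin


def select_devices(
    devices: list[ProcessedDevice], mode: str = "closest_density"
) -> list[ProcessedDevice]:
    """Select devices used to build the compartment model.

    ``"closest_density"`` keeps the devices whose density is closest to
    the time-averaged dispersion density (they follow the flow best);
    ``"all"`` pools every device.
    """
    if not devices:
        raise ValueError("no devices given")
    if mode == "all":
        return list(devices)
    if mode != "closest_density":
        raise ValueError("mode must be 'closest_density' or 'all'")
    rho_mean = float(np.mean(np.concatenate([d.rho_f for d in devices])))
    gaps = {d.trace.device_id: abs(d.trace.rho_p - rho_mean) for d in devices}
    best = min(gaps.values())
    return [d for d in devices if abs(gaps[d.trace.device_id] - best) < 1e-9]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------


def read_traces_csv(path, densities: dict[str, float] | None = None) -> list[SensorTrace]:
    """Read one CSV holding one or more devices.

    Required columns: ``device_id, t_s, P_Pa, T_K``; an optional
    ``rho_p_kg_m3`` column (or the ``densities`` mapping) supplies the
    device density.
    """
    df = pd.read_csv(path, comment="#")
    required = {"device_id", "t_s", "P_Pa", "T_K"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for dev, grp in df.groupby("device_id", sort=True):
        grp = grp.sort_values("t_s")
        if "rho_p_kg_m3" in grp.columns:
            rho_p = float(grp["rho_p_kg_m3"].iloc[0])
        elif densities and str(dev) in densities:
            rho_p = densities[str(dev)]
        else:
            raise ValueError(f"{path}: no density for device {dev!r}")
        out.append(
            SensorTrace(
                str(dev),
                grp["t_s"].to_numpy(),
                grp["P_Pa"].to_numpy(),
                grp["T_K"].to_numpy(),
                rho_p,
            )
        )
    return out


def write_traces_csv(path, traces: list[SensorTrace]) -> None:
    frames = [
        pd.DataFrame(
            {
                "device_id": tr.device_id,
                "t_s": tr.t,
                "P_Pa": tr.P,
                "T_K": tr.T,
                "rho_p_kg_m3": tr.rho_p,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_kinematics_csv(path, kins: list[AxialKinematics]) -> None:
    frames = [
        pd.DataFrame(
            {"device_id": k.device_id, "t_s": k.t, "z_m": k.z, "v_z_m_per_s": k.v_z}
        )
        for k in kins
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_kinematics_csv(path) -> list[AxialKinematics]:
    df = pd.read_csv(path, comment="#")
    out = []
    for dev, grp in df.groupby("device_id", sort=True):
        grp = grp.sort_values("t_s")
        out.append(
            AxialKinematics(
                str(dev),
                grp["t_s"].to_numpy(),
                grp["z_m"].to_numpy(),
                grp["v_z_m_per_s"].to_numpy(),
            )
        )
    return out
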