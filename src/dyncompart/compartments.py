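"""Dynamic compartment model construction.

The column liquid is discretised into axial slabs (initial compartments of
height ``dz0``) exchanging mass through bidirectional flows at their
interfaces.  Within an update step (default 1 hr) volumes and flows are
frozen; between steps the liquid height, hold-up and flow rates are
re-derived from the pooled device samples of that window.

Interface exchange flow: with mean interface crossing speed <|v_z|> the
bidirectional flow is ``Q = A (1 - eps) <|v_z|> / 2`` (half the samples
cross upward, half downward in a closed column, so the symmetric split
enforces zero net axial flow).

Auto-zoning merges adjacent slabs into well-mixed zones bottom-up while
the candidate zone's local residence time ``tau = V_zone / min(Q_int)``
stays below the critical residence time ``tau_crit`` (default 1.5 s):
slabs that exchange mass much faster than any process time scale behave
as one ideally mixed volume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import (
    DT_UPDATE_DEFAULT,
    DZ0_DEFAULT,
    G,
    MIN_SAMPLES_DEFAULT,
    TAU_CRIT_DEFAULT,
)
from .traces import AxialKinematics, ProcessedDevice, ReactorGeometry

__all__ = [
    "CompartmentStep",
    "ZoneMap",
    "DynamicCompartmentModel",
    "step_liquid_height",
    "interface_velocity_stats",
    "interface_flows",
    "autozone",
    "apply_zoning",
    "build_dynamic_model",
    "flow_map",
]

SCHEMA_VERSION = "dyncompart-model-1"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CompartmentStep:
    """One update step's frozen compartment geometry and flows.

    ``interfaces`` holds the K+1 slab edges from the vessel bottom (0) to
    the gassed liquid height ``H_L``; ``Q`` holds the K-1 internal
    bidirectional exchange flows; per-compartment arrays run bottom to top.
    """

    j: int
    t_start: float  # [s]
    t_end: float  # [s]
    H_L: float  # gassed liquid height [m]
    interfaces: np.ndarray  # (K+1,) edge heights [m]
    V: np.ndarray  # (K,) liquid volumes [m^3]
    Q: np.ndarray  # (K-1,) exchange flows [m^3/s]
    eps_k: np.ndarray  # (K,) gas fraction
    P_k: np.ndarray  # (K,) mean pressure [Pa]
    T_k: np.ndarray  # (K,) mean temperature [K]
    n_samples: np.ndarray  # (K-1,) velocity samples per internal interface

    def __post_init__(self) -> None:
        for name in ("interfaces", "V", "Q", "eps_k", "P_k", "T_k", "n_samples"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        K = self.V.size
        if self.interfaces.size != K + 1:
            raise ValueError("interfaces must have K+1 entries")
        if self.Q.size != K - 1:
            raise ValueError("Q must have K-1 entries")
        if np.any(self.V <= 0):
            raise ValueError("compartment volumes must be positive")
        if np.any(self.Q < 0):
            raise ValueError("exchange flows must be non-negative")

    @property
    def K(self) -> int:
        return int(self.V.size)

    @property
    def V_tot(self) -> float:
        return float(self.V.sum())

    @property
    def z_mid(self) -> np.ndarray:
        return 0.5 * (self.interfaces[:-1] + self.interfaces[1:])

    @property
    def t_mid(self) -> float:
        return 0.5 * (self.t_start + self.t_end)

    def zone_for_height(self, h: float) -> int:
        """Index of the compartment containing height ``h`` (heights above
        the liquid surface map to the top compartment)."""
        idx = int(np.searchsorted(self.interfaces, h, side="right")) - 1
        return int(np.clip(idx, 0, self.K - 1))

    def scaled_flows(self, factor: float) -> "CompartmentStep":
        """Copy of this step with all exchange flows multiplied by ``factor``."""
        return CompartmentStep(
            self.j,
            self.t_start,
            self.t_end,
            self.H_L,
            self.interfaces.copy(),
            self.V.copy(),
            self.Q * factor,
            self.eps_k.copy(),
            self.P_k.copy(),
            self.T_k.copy(),
            self.n_samples.copy(),
        )


@dataclass
class ZoneMap:
    """Contiguous partition of the initial compartments into zones.

    ``zones[i] = (a, b)`` merges initial compartments ``a..b`` inclusive.
    """

    j: int
    zones: list[tuple[int, int]]

    def __post_init__(self) -> None:
        prev_end = -1
        for a, b in self.zones:
            if a != prev_end + 1 or b < a:
                raise ValueError("zones must contiguously partition the compartments")
            prev_end = b

    @property
    def n_zones(self) -> int:
        return len(self.zones)


@dataclass
class DynamicCompartmentModel:
    """Ordered update steps plus their zone maps.

    ``steps`` keeps the initial (slab) resolution; ``zoned_steps`` gives
    the merged, ideally mixed zones actually used by the tracer and
    fermentation simulators.
    """

    steps: list[CompartmentStep]
    zone_maps: list[ZoneMap]
    geometry: ReactorGeometry
    tau_crit: float = TAU_CRIT_DEFAULT

    def __post_init__(self) -> None:
        if len(self.steps) != len(self.zone_maps):
            raise ValueError("one zone map per step required")
        for a, b in zip(self.steps[:-1], self.steps[1:]):
            if abs(a.t_end - b.t_start) > 1e-6:
                raise ValueError("steps must be contiguous in time")

    @property
    def J(self) -> int:
        return len(self.steps)

    @property
    def zoned_steps(self) -> list[CompartmentStep]:
        if not hasattr(self, "_zoned"):
            self._zoned = [
                apply_zoning(s, zm) for s, zm in zip(self.steps, self.zone_maps)
            ]
        return self._zoned

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": SCHEMA_VERSION,
            "tau_crit": self.tau_crit,
            "geometry": {
                "D": self.geometry.D,
                "H_total": self.geometry.H_total,
                "probe_clearance": self.geometry.probe_clearance,
                "bottom_shape": self.geometry.bottom_shape,
            },
            "steps": [
                {
                    "j": s.j,
                    "t_start": s.t_start,
                    "t_end": s.t_end,
                    "H_L": s.H_L,
                    "interfaces": s.interfaces.tolist(),
                    "V": s.V.tolist(),
                    "Q": s.Q.tolist(),
                    "eps": s.eps_k.tolist(),
                    "P": s.P_k.tolist(),
                    "T": s.T_k.tolist(),
                    "n_samples": s.n_samples.tolist(),
                }
                for s in self.steps
            ],
            "zone_maps": [
                {"j": zm.j, "zones": [list(z) for z in zm.zones]}
                for zm in self.zone_maps
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DynamicCompartmentModel":
        if d.get("schema") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {d.get('schema')!r}")
        geom = ReactorGeometry(**d["geometry"])
        steps = [
            CompartmentStep(
                int(s["j"]),
                s["t_start"],
                s["t_end"],
                s["H_L"],
                np.array(s["interfaces"]),
                np.array(s["V"]),
                np.array(s["Q"]),
                np.array(s["eps"]),
                np.array(s["P"]),
                np.array(s["T"]),
                np.array(s["n_samples"]),
            )
            for s in d["steps"]
        ]
        zone_maps = [
            ZoneMap(int(zm["j"]), [tuple(z) for z in zm["zones"]])
            for zm in d["zone_maps"]
        ]
        return cls(steps, zone_maps, geom, d["tau_crit"])

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "DynamicCompartmentModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def step_liquid_height(
    devices: list[ProcessedDevice],
    t_start: float,
    t_end: float,
    g: float = G,
) -> float:
    """Gassed liquid height over a window from the pooled pressure span.

    ``H_L = (max P - min P) / (mean rho_f * g)`` over all samples of all
    devices inside ``[t_start, t_end]`` — valid when devices traverse the
    full height within the window.
    """
    p_lo, p_hi, rho_sum, n = np.inf, -np.inf, 0.0, 0
    for d in devices:
        m = (d.trace.t >= t_start) & (d.trace.t < t_end)
        if not m.any():
            continue
        p = d.trace.P[m]
        p_lo = min(p_lo, float(p.min()))
        p_hi = max(p_hi, float(p.max()))
        rho_sum += float(d.rho_f[m].sum())
        n += int(m.sum())
    if n == 0:
        raise ValueError(f"no samples in window [{t_start}, {t_end}]")
    return (p_hi - p_lo) / (rho_sum / n * g)


def interface_velocity_stats(
    kins: list[AxialKinematics],
    interfaces: np.ndarray,
    t_start: float,
    t_end: float,
    capture_band: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean crossing speed and sample count per internal interface.

    A sample contributes to interface ``z_i`` when ``|z - z_i| <=
    capture_band / 2`` and its time lies inside the window.  The statistic
    is the mean of ``|v_z|`` (speed magnitude — the up/down split is
    handled by the symmetric flow assignment downstream).
    """
    if capture_band <= 0:
        raise ValueError("capture band must be positive")
    interfaces = np.asarray(interfaces, dtype=float)
    zs, vs = [], []
    for k in kins:
        m = (k.t >= t_start) & (k.t < t_end)
        if m.any():
            zs.append(k.z[m])
            vs.append(np.abs(k.v_z[m]))
    mean_speed = np.zeros(interfaces.size)
    counts = np.zeros(interfaces.size, dtype=int)
    if not zs:
        return mean_speed, counts
    z = np.concatenate(zs)
    v = np.concatenate(vs)
    order = np.argsort(z)
    z, v = z[order], v[order]
    csum = np.concatenate([[0.0], np.cumsum(v)])
    half = capture_band / 2.0
    lo = np.searchsorted(z, interfaces - half, side="left")
    hi = np.searchsorted(z, interfaces + half, side="right")
    counts = (hi - lo).astype(int)
    with np.errstate(invalid="ignore"):
        mean_speed = np.where(counts > 0, (csum[hi] - csum[lo]) / np.maximum(counts, 1), 0.0)
    return mean_speed, counts


def interface_flows(
    mean_speed: np.ndarray,
    counts: np.ndarray,
    A: float,
    eps_if: np.ndarray,
    min_samples: int = MIN_SAMPLES_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Bidirectional exchange flows, ``Q = A (1 - eps) <|v_z|> / 2``.

    Returns ``(Q, valid)`` where ``valid`` flags interfaces with at least
    ``min_samples`` velocity samples.
    """
    Q = A * (1.0 - np.asarray(eps_if, dtype=float)) * np.asarray(mean_speed) / 2.0
    valid = np.asarray(counts) >= min_samples
    return Q, valid


def autozone(V: np.ndarray, Q: np.ndarray, tau_crit: float = TAU_CRIT_DEFAULT) -> list[tuple[int, int]]:
    """Greedy bottom-up merging of slabs into well-mixed zones.

    A zone grows by appending the next slab while the candidate zone's
    residence time ``sum(V) / min(internal Q)`` stays within ``tau_crit``.
    Single slabs always form valid zones.
    """
    if tau_crit <= 0:
        raise ValueError("tau_crit must be positive")
    V = np.asarray(V, dtype=float)
    Q = np.asarray(Q, dtype=float)
    K = V.size
    zones: list[tuple[int, int]] = []
    s = 0
    while s < K:
        e = s
        while e + 1 < K:
            q_int = Q[s : e + 1]  # internal interfaces of candidate zone s..e+1
            q_min = q_int.min()
            if q_min <= 0:
                break
            tau = V[s : e + 2].sum() / q_min
            if tau <= tau_crit:
                e += 1
            else:
                break
        zones.append((s, e))
        s = e + 1
    return zones


def apply_zoning(step: CompartmentStep, zmap: ZoneMap) -> CompartmentStep:
    """Aggregate an initial-resolution step into its zoned form.

    Zone volumes are sums; zone boundary flows are the flows at the
    retained boundary interfaces (internal interfaces cease to exist);
    scalar fields are volume-weighted means.
    """
    if zmap.zones[-1][1] != step.K - 1:
        raise ValueError("zone map does not cover all compartments")
    edges = [step.interfaces[0]]
    V, eps, P, T = [], [], [], []
    for a, b in zmap.zones:
        edges.append(step.interfaces[b + 1])
        v = step.V[a : b + 1]
        V.append(v.sum())
        eps.append(np.average(step.eps_k[a : b + 1], weights=v))
        P.append(np.average(step.P_k[a : b + 1], weights=v))
        T.append(np.average(step.T_k[a : b + 1], weights=v))
    boundary = [b for _, b in zmap.zones[:-1]]  # interface below zone i+1
    Q = step.Q[boundary] if boundary else np.zeros(0)
    n = step.n_samples[boundary] if boundary else np.zeros(0)
    return CompartmentStep(
        step.j,
        step.t_start,
        step.t_end,
        step.H_L,
        np.array(edges),
        np.array(V),
        np.asarray(Q),
        np.array(eps),
        np.array(P),
        np.array(T),
        np.asarray(n),
    )


def _slab_edges(H_L: float, dz: float) -> np.ndarray:
    """Slab edges from 0 to H_L every ``dz``; a thin top remainder
    (< dz/2) is merged into the slab below."""
    n_full = int(np.floor(H_L / dz + 1e-9))
    edges = np.arange(n_full + 1) * dz
    if H_L - edges[-1] > 0.5 * dz:
        edges = np.append(edges, H_L)
    else:
        edges[-1] = H_L
    if edges.size < 2:
        edges = np.array([0.0, H_L])
    return edges


def _bin_means(z, values, edges):
    """Per-slab means of ``values`` binned by ``z``; empty slabs filled by
    linear interpolation over slab centres."""
    idx = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, edges.size - 2)
    K = edges.size - 1
    sums = np.bincount(idx, weights=values, minlength=K)
    counts = np.bincount(idx, minlength=K)
    means = np.full(K, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    if not nz.all():
        centres = 0.5 * (edges[:-1] + edges[1:])
        if not nz.any():
            raise ValueError("no samples fall inside the column")
        means[~nz] = np.interp(centres[~nz], centres[nz], means[nz])
    return means


def build_dynamic_model(
    devices: list[ProcessedDevice],
    geometry: ReactorGeometry,
    *,
    dz0: float = DZ0_DEFAULT,
    dt_update: float = DT_UPDATE_DEFAULT,
    tau_crit: float = TAU_CRIT_DEFAULT,
    min_samples: int = MIN_SAMPLES_DEFAULT,
    capture_band: float | None = None,
    max_doublings: int = 3,
    g: float = G,
) -> DynamicCompartmentModel:
    """Discretise processed device data into a dynamic compartment model.

    For each update step: pooled liquid height; slab edges every ``dz0``;
    per-interface crossing-speed statistics within a capture band of one
    slab height; exchange flows scaled by the local liquid fraction;
    per-slab mean gas fraction, pressure and temperature; auto-zoning.

    If any internal interface collects fewer than ``min_samples`` velocity
    samples the step is re-discretised at doubled slab height (up to
    ``max_doublings`` times) before an error is raised naming the step and
    interface height.
    """
    if not devices:
        raise ValueError("no processed devices given")
    t0 = max(float(d.trace.t[0]) for d in devices)
    t1 = min(float(d.trace.t[-1]) for d in devices)
    J = int(np.floor((t1 - t0) / dt_update + 1e-9))
    if J < 1:
        raise ValueError("device traces shorter than one update step")

    A = geometry.A
    steps: list[CompartmentStep] = []
    zone_maps: list[ZoneMap] = []
    prev_H = None
    for j in range(1, J + 1):
        ts = t0 + (j - 1) * dt_update
        te = ts + dt_update
        H_L = step_liquid_height(devices, ts, te, g)
        if prev_H is not None and H_L < 0.9 * prev_H:
            warnings.warn(
                f"step {j}: liquid height {H_L:.2f} m is <90% of the previous "
                "step's; devices may not have traversed the full column",
                stacklevel=2,
            )
        prev_H = H_L

        # pooled per-sample fields for this window
        zs, vs, Ps, Ts, es = [], [], [], [], []
        for d in devices:
            m = (d.trace.t >= ts) & (d.trace.t < te)
            if m.any():
                zs.append(d.kin.z[m])
                vs.append(d.kin.v_z[m])
                Ps.append(d.trace.P[m])
                Ts.append(d.trace.T[m])
                es.append(d.eps[m])
        z_all = np.concatenate(zs)
        P_all = np.concatenate(Ps)
        T_all = np.concatenate(Ts)
        e_all = np.concatenate(es)
        kins = [d.kin for d in devices]

        dz = dz0
        for attempt in range(max_doublings + 1):
            edges = _slab_edges(H_L, dz)
            internal = edges[1:-1]
            band = capture_band if capture_band is not None else dz
            speed, counts = interface_velocity_stats(kins, internal, ts, te, band)
            if internal.size == 0 or counts.min() >= min_samples:
                break
            dz *= 2.0
        else:
            pass
        if internal.size and counts.min() < min_samples:
            bad = internal[int(np.argmin(counts))]
            raise ValueError(
                f"step {j}: interface at {bad:.2f} m has {int(counts.min())} "
                f"< {min_samples} velocity samples even after coarsening"
            )

        eps_k = np.clip(_bin_means(z_all, e_all, edges), 0.0, 0.999)
        P_k = _bin_means(z_all, P_all, edges)
        T_k = _bin_means(z_all, T_all, edges)
        V = A * np.diff(edges) * (1.0 - eps_k)
        eps_if = 0.5 * (eps_k[:-1] + eps_k[1:])
        Q, _ = interface_flows(speed, counts, A, eps_if, min_samples)

        step = CompartmentStep(
            j, ts, te, H_L, edges, V, Q, eps_k, P_k, T_k, counts.astype(float)
        )
        steps.append(step)
        zone_maps.append(ZoneMap(j, autozone(V, Q, tau_crit)))

    return DynamicCompartmentModel(steps, zone_maps, geometry, tau_crit)


def flow_map(model: DynamicCompartmentModel, zoned: bool = False) -> pd.DataFrame:
    """Long-format table of interface flows over the process (one row per
    step and internal interface), suitable for a flow heat map."""
    rows = []
    steps = model.zoned_steps if zoned else model.steps
    for s in steps:
        for h, q in zip(s.interfaces[1:-1], s.Q):
            rows.append(
                {
                    "step": s.j,
                    "t_mid_hr": s.t_mid / 3600.0,
                    "interface_height_m": h,
                    "Q_m3_per_s": q,
                }
            )
    return pd.DataFrame(rows)
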