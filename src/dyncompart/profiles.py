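"""Time profiles of operating variables (feed rate, gas flow, headspace
pressure), stored as breakpoint tables with linear interpolation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Profile"]


@dataclass
class Profile:
    """Piecewise-linear profile ``value(t)`` with time in seconds.

    Evaluation outside the tabulated range clamps to the end values,
    which matches how a plant historian trace is normally extended.
    """

    t: np.ndarray
    v: np.ndarray
    name: str = "value"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.v.shape:
            raise ValueError("profile t and value arrays must be 1-D and equal length")
        if self.t.size < 1:
            raise ValueError("profile needs at least one breakpoint")
        if np.any(np.diff(self.t) < 0):
            raise ValueError("profile times must be non-decreasing")

    @classmethod
    def constant(cls, value: float, name: str = "value") -> "Profile":
        return cls(np.array([0.0]), np.array([float(value)]), name=name)

    def __call__(self, t):
        return np.interp(t, self.t, self.v)

    def mean(self, t_start: float, t_end: float) -> float:
        """Time-average of the profile over ``[t_start, t_end]`` (trapezoid
        on the union of breakpoints and window edges, so reallocating mass
        between aligned windows is exactly conservative)."""
        if t_end <= t_start:
            raise ValueError("t_end must exceed t_start")
        inner = self.t[(self.t > t_start) & (self.t < t_end)]
        grid = np.concatenate([[t_start], inner, [t_end]])
        return float(np.trapezoid(self(grid), grid) / (t_end - t_start))

    def shifted(self, deltas: list[tuple[float, float, float]]) -> "Profile":
        """Return a new profile with piecewise-constant offsets applied.

        ``deltas`` is a list of ``(delta, t_start_s, t_end_s)``; each adds
        ``delta`` to the profile on ``[t_start, t_end)``.  Used for feed
        what-if scenarios (move feed mass between process windows).
        """
        edges = set(self.t.tolist())
        for _, a, b in deltas:
            edges.update((a, b))
        grid = np.array(sorted(edges))
        # sample just inside each segment so steps stay sharp
        eps = 1e-9 * max(1.0, grid[-1] - grid[0])
        pts: list[float] = []
        for g in grid:
            pts.extend((g - eps, g, g + eps))
        pts_arr = np.array(sorted(set(p for p in pts if grid[0] <= p <= grid[-1])))
        vals = self(pts_arr)
        for d, a, b in deltas:
            vals = vals + np.where((pts_arr >= a) & (pts_arr < b), d, 0.0)
        return Profile(pts_arr, vals, name=self.name)

    # -- delimited-text I/O ------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame({"t_s": self.t, self.name: self.v}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, value_col: str | None = None) -> "Profile":
        df = pd.read_csv(path, comment="#")
        if "t_s" not in df.columns:
            raise ValueError(f"{path}: profile file needs a 't_s' column")
        if value_col is None:
            others = [c for c in df.columns if c != "t_s"]
            if len(others) != 1:
                raise ValueError(f"{path}: ambiguous value column, pass value_col")
            value_col = others[0]
        return cls(df["t_s"].to_numpy(), df[value_col].to_numpy(), name=value_col)
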