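"""Phase-fraction time series container shared by the simulator and the fitters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PhaseFractionSeries"]


@dataclass
class PhaseFractionSeries:
    """Fractions of cells in G1, S and G2 at sampling times over diel cycles.

    Parameters
    ----------
    t : ndarray
        Sampling times in hours since the start of the experiment (strictly
        increasing; may span several days).
    f_g1, f_s, f_g2 : ndarray
        Phase fractions at each sampling time; each in [0, 1] and summing to 1
        per point.
    condition : str
        Scenario / light-regime label (e.g. ``"HL"``, ``"HL+UV"``).
    usable : ndarray of bool, optional
        Mask of points usable downstream (fit converged, enough events).
        Defaults to all points usable.
    """

    t: np.ndarray
    f_g1: np.ndarray
    f_s: np.ndarray
    f_g2: np.ndarray
    condition: str = ""
    usable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.f_g1 = np.asarray(self.f_g1, dtype=float)
        self.f_s = np.asarray(self.f_s, dtype=float)
        self.f_g2 = np.asarray(self.f_g2, dtype=float)
        n = self.t.size
        if not (self.f_g1.size == self.f_s.size == self.f_g2.size == n):
            raise ValueError("t and fraction arrays must have equal length")
        if n > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        for name, f in (("f_g1", self.f_g1), ("f_s", self.f_s), ("f_g2", self.f_g2)):
            if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
                raise ValueError(f"{name} outside [0, 1]")
        total = self.f_g1 + self.f_s + self.f_g2
        if np.any(np.abs(total - 1.0) > 1e-6):
            raise ValueError("phase fractions must sum to 1 at every point")
        if self.usable is None:
            self.usable = np.ones(n, dtype=bool)
        else:
            self.usable = np.asarray(self.usable, dtype=bool)
            if self.usable.size != n:
                raise ValueError("usable mask length mismatch")

    # -- views ------------------------------------------------------------

    def __len__(self) -> int:
        return self.t.size

    @property
    def clock(self) -> np.ndarray:
        """Clock time (hours since midnight, mod 24) of each sample."""
        return self.t % 24.0

    @property
    def day(self) -> np.ndarray:
        """Diel cycle index (0-based) of each sample."""
        return (self.t // 24.0).astype(int)

    def fraction(self, phase: str) -> np.ndarray:
        return {"G1": self.f_g1, "S": self.f_s, "G2": self.f_g2}[phase]

    def fold(self, phase: str):
        """Average a phase curve over days onto the 24 h clock grid.

        Only usable points contribute.  Returns ``(clock_grid, values)`` with
        the grid sorted and unique (rounded to 1e-6 h for matching).
        """
        mask = self.usable
        if not mask.any():
            raise ValueError("no usable points in series")
        clock = np.round(self.clock[mask], 6)
        values = self.fraction(phase)[mask]
        grid = np.unique(clock)
        folded = np.array([values[clock == c].mean() for c in grid])
        return grid, folded

    # -- I/O --------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.t,
                "f_G1": self.f_g1,
                "f_S": self.f_s,
                "f_G2": self.f_g2,
                "usable": self.usable.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, condition: str = "") -> "PhaseFractionSeries":
        usable = df["usable"].to_numpy().astype(bool) if "usable" in df else None
        return cls(
            t=df["time_h"].to_numpy(),
            f_g1=df["f_G1"].to_numpy(),
            f_s=df["f_S"].to_numpy(),
            f_g2=df["f_G2"].to_numpy(),
            condition=condition,
            usable=usable,
        )
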