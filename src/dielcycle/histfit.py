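"""DNA-content histogram deconvolution into G1/S/G2 fractions.

The model is a constrained mixture in the Dean-Jett-Fox tradition, for a
prokaryote in the slow-growth regime (one chromosome copy in G1, two in G2):

* G1 peak: Gaussian with mean ``m`` and fractional CV ``cv``;
* G2 peak: Gaussian with mean ``r * m`` (``r`` fixed at 2.0 by default,
  because a G2 cell carries exactly two chromosome copies) and the same
  fractional CV;
* S phase: a single rectangle of DNA content spanning ``(m, r*m)``,
  discretized into ``n_s_segments`` equal-width uniform segments, each
  convolved with the measurement noise at its own fractional CV.

Fractions enter the likelihood linearly, so fitting alternates an inner EM
for the mixture weights with an outer Nelder-Mead search over the nonlinear
shape parameters (``m``, ``cv`` and optionally ``r``), minimizing the
Poisson deviance of the binned counts (chi-square available for parity with
legacy software).  The fit is invariant to a global rescaling of the
fluorescence axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, signal
from scipy.special import ndtr  # fast standard normal CDF
from sklearn.base import BaseEstimator

from .series import PhaseFractionSeries
from .simulate import EventSample

__all__ = [
    "DNAHistogram",
    "HistFitResult",
    "PhaseMixtureModel",
    "build_histogram",
    "fit_dna_histogram",
    "fractions_series",
]

#: Default minimum number of events for a trustworthy deconvolution.
MIN_EVENTS = 5000


@dataclass
class DNAHistogram:
    """Binned DNA-fluorescence histogram with out-of-range bookkeeping."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_below: int = 0
    n_above: int = 0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("len(counts) must equal len(bin_edges) - 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_events(self) -> int:
        """Events inside the binning range."""
        return int(self.counts.sum())

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def build_histogram(
    sample: EventSample,
    n_bins: int = 256,
    range_policy="auto",
    min_events: int = MIN_EVENTS,
) -> DNAHistogram:
    """Bin an event sample linearly, reporting (not dropping) out-of-range events.

    ``range_policy`` is either an explicit ``(low, high)`` tuple or ``"auto"``,
    which uses ``[0, 2.6 * median]`` — wide enough to hold the G2 peak (at
    twice the G1 position) whatever mixture the sample contains, while
    scaling with the instrument gain.
    """
    events = sample.events
    if events.size < min_events:
        raise ValueError(
            f"too few events for histogram fitting: {events.size} < {min_events}"
        )
    if range_policy == "auto":
        lo, hi = 0.0, 2.6 * float(np.median(events))
    else:
        lo, hi = map(float, range_policy)
    if hi <= lo:
        raise ValueError("histogram range is empty")
    counts, edges = np.histogram(events, bins=n_bins, range=(lo, hi))
    n_below = int(np.count_nonzero(events < lo))
    n_above = int(np.count_nonzero(events >= hi))
    return DNAHistogram(bin_edges=edges, counts=counts, n_below=n_below, n_above=n_above)


@dataclass
class HistFitResult:
    """Result of one histogram deconvolution."""

    m: float            # G1 peak position (a.u.)
    cv: float           # shared fractional CV
    r: float            # G2/G1 position ratio
    f_g1: float
    f_s: float
    f_g2: float
    gof: float          # reduced deviance (or chi-square)
    converged: bool
    n_events: int
    n_s_segments: int

    @property
    def fractions(self):
        return (self.f_g1, self.f_s, self.f_g2)


def _gauss_bin_mass(edges: np.ndarray, mu: float, sd: float) -> np.ndarray:
    z = (edges - mu) / max(sd, 1e-12)
    cdf = ndtr(z)
    return np.diff(cdf)


def _rect_gauss_cdf(x: np.ndarray, a: float, b: float, s: float) -> np.ndarray:
    """CDF at ``x`` of Uniform(a, b) convolved with Normal(0, s)."""
    s = max(s, 1e-12)

    def j(v):
        z = v / s
        return v * ndtr(z) + s * np.exp(-0.5 * z * z) / np.sqrt(2.0 * np.pi)

    return (j(x - a) - j(x - b)) / (b - a)


def _component_matrix(
    edges: np.ndarray, m: float, cv: float, r: float, n_seg: int
) -> np.ndarray:
    """Per-bin mass of the G1, S and G2 components (columns normalized)."""
    cols = np.empty((edges.size - 1, 3))
    cols[:, 0] = _gauss_bin_mass(edges, m, cv * m)
    cols[:, 2] = _gauss_bin_mass(edges, r * m, cv * r * m)
    bounds = np.linspace(m, r * m, n_seg + 1)
    s_mass = np.zeros(edges.size - 1)
    for i in range(n_seg):
        a, b = bounds[i], bounds[i + 1]
        mid = 0.5 * (a + b)
        s_mass += np.diff(_rect_gauss_cdf(edges, a, b, cv * mid))
    cols[:, 1] = s_mass / n_seg
    sums = cols.sum(axis=0)
    for k in range(3):
        if sums[k] > 1e-12:
            cols[:, k] /= sums[k]
        else:
            cols[:, k] = 0.0
    return cols


def _em_weights(A: np.ndarray, counts: np.ndarray, w0=None, n_iter=200, tol=1e-12):
    """Multinomial-mixture weight MLE for fixed components (EM updates)."""
    n = counts.sum()
    w = np.full(3, 1.0 / 3.0) if w0 is None else np.array(w0, dtype=float)
    for _ in range(n_iter):
        mix = A @ w
        resp = counts / np.maximum(mix, 1e-300)
        w_new = w * (A.T @ resp) / n
        total = w_new.sum()
        if total <= 0:
            return w
        w_new /= total
        if np.max(np.abs(w_new - w)) < tol:
            return w_new
        w = w_new
    return w


def _poisson_deviance(counts: np.ndarray, model: np.ndarray) -> float:
    model = np.maximum(model, 1e-300)
    pos = counts > 0
    dev = model.sum() - counts.sum()
    dev += float(np.sum(counts[pos] * np.log(counts[pos] / model[pos])))
    return 2.0 * dev


def _chi_square(counts: np.ndarray, model: np.ndarray) -> float:
    var = np.maximum(counts, 1.0)
    return float(np.sum((counts - model) ** 2 / var))


def _initial_g1_position(hist: DNAHistogram) -> float:
    """Locate the G1 peak from the two largest local maxima of the histogram."""
    counts = hist.counts.astype(float)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(counts, kernel, mode="same")
    peaks, props = signal.find_peaks(
        smooth, prominence=0.02 * smooth.max(), distance=max(3, counts.size // 50)
    )
    centers = hist.centers
    if peaks.size == 0:
        return float(centers[np.argmax(smooth)])
    order = np.argsort(smooth[peaks])[::-1]
    tops = centers[peaks[order[:4]]]
    best = None
    for i in range(tops.size):
        for k in range(tops.size):
            lo, hi = tops[i], tops[k]
            if lo < hi and 1.6 <= hi / lo <= 2.4:
                height = smooth[peaks[order[i]]] + smooth[peaks[order[k]]]
                if best is None or height > best[0]:
                    best = (height, lo)
    if best is not None:
        return float(best[1])
    return float(tops[0])


class PhaseMixtureModel(BaseEstimator):
    """Constrained G1/S/G2 mixture fitted to a DNA-content histogram.

    Parameters
    ----------
    n_s_segments : int
        Number of uniform segments discretizing the S-phase rectangle.
    ratio : float
        G2/G1 position ratio when fixed (two chromosome copies => 2.0).
    free_ratio : bool
        Fit the ratio within ``ratio_bounds`` instead of fixing it.
    objective : {"poisson", "chi2"}
        Poisson deviance (robust for low-count night-time bins) or
        chi-square with variance ``max(count, 1)``.
    cv_init, cv_bounds
        Starting value and box for the shared fractional CV.
    fixed_m : float, optional
        Pin the G1 peak position instead of fitting it — used when fitting a
        diel series with a shared, externally determined G1 position (the
        position is an instrument property and should not drift between
        timepoints whose S cells crowd one end of the G1-G2 interval).

    Attributes (after :meth:`fit`)
    ------------------------------
    m_, cv_, r_ : fitted G1 position, CV and G2/G1 ratio.
    f_g1_, f_s_, f_g2_ : phase fractions (sum to 1).
    gof_ : reduced objective value.
    converged_ : False when the optimizer stalled (no exception is raised).
    result_ : the full :class:`HistFitResult`.
    """

    def __init__(
        self,
        n_s_segments: int = 8,
        ratio: float = 2.0,
        free_ratio: bool = False,
        ratio_bounds=(1.9, 2.1),
        objective: str = "poisson",
        cv_init: float = 0.05,
        cv_bounds=(1e-4, 0.3),
        max_iter: int = 400,
        fixed_m: Optional[float] = None,
    ):
        self.n_s_segments = n_s_segments
        self.ratio = ratio
        self.free_ratio = free_ratio
        self.ratio_bounds = ratio_bounds
        self.objective = objective
        self.cv_init = cv_init
        self.cv_bounds = cv_bounds
        self.max_iter = max_iter
        self.fixed_m = fixed_m

    # -- internals --------------------------------------------------------

    def _stat(self, counts, model):
        if self.objective == "poisson":
            return _poisson_deviance(counts, model)
        if self.objective == "chi2":
            return _chi_square(counts, model)
        raise ValueError(f"unknown objective {self.objective!r}")

    def _unpack(self, x):
        if self.fixed_m is None:
            m = float(np.exp(x[0]))
            rest = x[1:]
        else:
            m = float(self.fixed_m)
            rest = x
        lo, hi = self.cv_bounds
        cv = float(np.clip(np.exp(rest[0]), lo, hi))
        if self.free_ratio:
            rlo, rhi = self.ratio_bounds
            r = rlo + (rhi - rlo) / (1.0 + np.exp(-rest[1]))
        else:
            r = self.ratio
        return m, cv, r

    def fit(self, X: DNAHistogram, y=None) -> "PhaseMixtureModel":
        hist = X
        if not isinstance(hist, DNAHistogram):
            raise TypeError("PhaseMixtureModel.fit expects a DNAHistogram")
        counts = hist.counts.astype(float)
        n = counts.sum()
        if n <= 0:
            raise ValueError("histogram is empty")
        if np.count_nonzero(counts) < 2:
            raise ValueError(
                "degenerate histogram: all events in a single bin; "
                "a G1/S/G2 mixture cannot be resolved"
            )
        edges = hist.bin_edges
        m0 = _initial_g1_position(hist)
        lo_edge, hi_edge = edges[0], edges[-1]

        w_state = {"w": np.full(3, 1.0 / 3.0)}

        def objective(x):
            m, cv, r = self._unpack(x)
            if not (lo_edge < m < hi_edge) or r * m > 2.0 * hi_edge:
                return 1e12
            A = _component_matrix(edges, m, cv, r, self.n_s_segments)
            if A.sum() <= 0:
                return 1e12
            w = _em_weights(A, counts, w0=w_state["w"], n_iter=100)
            w_state["w"] = w
            return self._stat(counts, n * (A @ w))

        x0 = [] if self.fixed_m is not None else [np.log(m0)]
        x0.append(np.log(self.cv_init))
        if self.free_ratio:
            x0.append(0.0)
        res = optimize.minimize(
            objective,
            np.asarray(x0),
            method="Nelder-Mead",
            options={
                "maxiter": self.max_iter,
                "xatol": 1e-5,
                "fatol": 1e-8,
                "adaptive": True,
            },
        )
        m, cv, r = self._unpack(res.x)
        A = _component_matrix(edges, m, cv, r, self.n_s_segments)
        w = _em_weights(A, counts, w0=w_state["w"], n_iter=2000, tol=1e-14)
        stat = self._stat(counts, n * (A @ w))
        n_par = 4 + (1 if self.free_ratio else 0) - (1 if self.fixed_m is not None else 0)
        dof = max(counts.size - n_par, 1)

        self.m_ = m
        self.cv_ = cv
        self.r_ = r
        self.f_g1_, self.f_s_, self.f_g2_ = (float(v) for v in w)
        self.gof_ = stat / dof
        self.converged_ = bool(res.success) and np.all(np.isfinite(w))
        self.result_ = HistFitResult(
            m=m,
            cv=cv,
            r=r,
            f_g1=self.f_g1_,
            f_s=self.f_s_,
            f_g2=self.f_g2_,
            gof=self.gof_,
            converged=self.converged_,
            n_events=hist.n_events,
            n_s_segments=self.n_s_segments,
        )
        return self


def fit_dna_histogram(hist: DNAHistogram, **opts) -> HistFitResult:
    """Deconvolve one histogram; thin wrapper over :class:`PhaseMixtureModel`."""
    return PhaseMixtureModel(**opts).fit(hist).result_


def fractions_series(
    samples: Sequence[EventSample],
    n_bins: int = 256,
    range_policy="auto",
    min_events: int = MIN_EVENTS,
    condition: Optional[str] = None,
    shared_g1_position: bool = True,
    **fit_opts,
) -> PhaseFractionSeries:
    """Fit every timepoint of an event-sample series into a fraction series.

    Samples are ordered by absolute time; non-converged fits are kept in the
    series but flagged unusable so that downstream peak detection skips them.

    With ``shared_g1_position=True`` (default) the series is fitted in two
    passes: a free pass per timepoint, then a refit with the G1 peak pinned
    at the median fitted position.  The G1 position reflects instrument gain
    and staining, not the cell cycle, so sharing it across the diel series
    stabilizes timepoints where the S cells crowd one end of the G1-G2
    interval and the free fit is poorly conditioned.
    """
    if not samples:
        raise ValueError("no samples provided")
    ordered = sorted(samples, key=lambda s: s.t_abs)
    hists = [
        build_histogram(s, n_bins=n_bins, range_policy=range_policy,
                        min_events=min_events)
        for s in ordered
    ]
    results = [fit_dna_histogram(h, **fit_opts) for h in hists]
    if shared_g1_position and "fixed_m" not in fit_opts:
        good = [r.m for r in results if r.converged]
        if good:
            m_ref = float(np.median(good))
            results = [
                fit_dna_histogram(h, fixed_m=m_ref, **fit_opts) for h in hists
            ]
    t, rows, usable = [], [], []
    for sample, result in zip(ordered, results):
        t.append(sample.t_abs)
        rows.append(result.fractions)
        usable.append(result.converged)
    rows = np.asarray(rows)
    usable = np.asarray(usable)
    if int(usable.sum()) < 4:
        raise ValueError(
            f"fewer than 4 usable timepoints ({int(usable.sum())}) in the series"
        )
    label = condition if condition is not None else ordered[0].condition
    return PhaseFractionSeries(
        t=np.asarray(t),
        f_g1=rows[:, 0],
        f_s=rows[:, 1],
        f_g2=rows[:, 2],
        condition=label,
        usable=usable,
    )
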