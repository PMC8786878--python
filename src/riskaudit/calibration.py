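"""Overall model-calibration machinery.

Risk groups for the calibration (validation) plot are formed by
*exponential quantiles*: instead of equal-count deciles, the quantile
levels ``i / n_bins`` are transformed by ``f(q) = q**exponent`` (default
exponent 1/5) before the empirical quantiles are taken.  With a
right-skewed score distribution — the normal situation for mortality risk
under class imbalance — this concentrates bin resolution in the sparse
high-risk tail, where equal-count groups would lump almost all high-risk
patients together.

Each bin reports its mean predicted risk, observed event proportion and a
Wilson score interval for that proportion; a LOWESS smooth of outcome on
score provides grouping-independent calibration information; per-class
score histograms describe the prediction distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from ._util import as_float_array, as_label_array
from .exceptions import ConfigurationError, UndefinedIntervalError

__all__ = [
    "CalibrationConfig",
    "RiskBin",
    "ValidationCurve",
    "exponential_quantile_edges",
    "wilson_interval",
    "lowess_curve",
    "validation_curve",
]


@dataclass(frozen=True)
class CalibrationConfig:
    """Parameters of the calibration assessment.

    ``exponent`` should be adapted to the skew of the score distribution;
    1 recovers plain equal-count quantile groups.
    """

    n_bins: int = 10
    exponent: float = 1.0 / 5.0
    lowess_span: float = 0.5
    alpha: float = 0.05
    n_grid: int = 100  # LOWESS evaluation grid size
    n_hist_bins: int = 50

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ConfigurationError("n_bins must be >= 1")
        if self.exponent <= 0:
            raise ConfigurationError("exponent must be > 0")
        if not 0.0 < self.lowess_span <= 1.0:
            raise ConfigurationError("lowess_span must be in (0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass
class RiskBin:
    """One risk group of the validation plot."""

    lower: float
    upper: float
    n: int
    mean_predicted: float
    observed_proportion: float
    wilson_lo: float
    wilson_hi: float

    def to_dict(self) -> dict:
        return {
            "lower": self.lower,
            "upper": self.upper,
            "n": self.n,
            "mean_predicted": self.mean_predicted,
            "observed_proportion": self.observed_proportion,
            "wilson_lo": self.wilson_lo,
            "wilson_hi": self.wilson_hi,
        }


@dataclass
class ValidationCurve:
    """All data behind a validation plot; rendering is optional."""

    bins: list[RiskBin]
    lowess_x: np.ndarray
    lowess_y: np.ndarray
    hist_edges: np.ndarray
    hist_event: np.ndarray
    hist_nonevent: np.ndarray
    threshold: float = 0.5
    n_merges: int = 0
    merge_log: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return sum(b.n for b in self.bins)

    def to_dict(self) -> dict:
        return {
            "bins": [b.to_dict() for b in self.bins],
            "lowess_x": self.lowess_x.tolist(),
            "lowess_y": self.lowess_y.tolist(),
            "hist_edges": self.hist_edges.tolist(),
            "hist_event": self.hist_event.tolist(),
            "hist_nonevent": self.hist_nonevent.tolist(),
            "threshold": self.threshold,
            "n_merges": self.n_merges,
            "merge_log": list(self.merge_log),
        }


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def exponential_quantile_edges(scores, config: CalibrationConfig = CalibrationConfig()) -> np.ndarray:
    """Bin edges at the empirical quantiles of ``scores`` at levels
    ``(i / n_bins) ** exponent`` for i = 1..n_bins-1, flanked by the sample
    min and max.

    Empirical quantiles use linear interpolation between order statistics
    (the common "type 7" rule).  Bins are half-open ``[lo, hi)`` with the
    last bin closed; duplicate edges are possible for heavily tied scores
    and are merged downstream.
    """
    s = as_float_array(scores, "scores")
    nb = config.n_bins
    if nb == 1:
        return np.array([s.min(), s.max()])
    levels = (np.arange(1, nb) / nb) ** config.exponent
    interior = np.quantile(s, levels, method="linear")
    return np.concatenate([[s.min()], interior, [s.max()]])


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Closed-form Wilson score interval for a binomial proportion.

    Raises :class:`UndefinedIntervalError` for ``n = 0``.
    """
    if n < 1:
        raise UndefinedIntervalError("Wilson interval undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError("successes k must satisfy 0 <= k <= n")
    z = float(norm.ppf(1.0 - alpha / 2.0))
    p = k / n
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (p + z2 / (2.0 * n)) / denom
    half = z * np.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, center - half)  # exact at the boundaries
    hi = 1.0 if k == n else min(1.0, center + half)
    return (lo, hi)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w**3


def lowess_curve(x, y, span: float = 0.5, grid=None) -> tuple[np.ndarray, np.ndarray]:
    """Locally weighted linear scatterplot smoothing (tricube kernel, zero
    robustness iterations).

    At each evaluation point the bandwidth is the distance to the k-th
    nearest data point, ``k = ceil(span * n)``, and a weighted straight line
    is fitted through the in-window points.  Evaluated at sorted unique
    ``x`` unless an explicit ``grid`` is given.  Degenerate inputs (all x
    equal, or a window with no x spread) fall back to the weighted mean.
    """
    xa = as_float_array(x, "x")
    ya = as_float_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 3:
        raise ValueError("lowess needs at least 3 points")
    if grid is None:
        gx = np.unique(xa)
    else:
        gx = np.asarray(grid, dtype=float).ravel()
    n = xa.size
    if np.ptp(xa) == 0.0:
        return gx, np.full(gx.size, ya.mean())
    k = max(2, int(np.ceil(span * n)))
    k = min(k, n)
    gy = np.empty(gx.size)
    for j, x0 in enumerate(gx):
        d = np.abs(xa - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0.0:
            # at least k points coincide with x0: average them
            gy[j] = ya[d == 0.0].mean()
            continue
        w = _tricube(d / h)
        mask = w > 0.0
        xw, yw, ww = xa[mask], ya[mask], w[mask]
        sw = ww.sum()
        xbar = (ww * xw).sum() / sw
        ybar = (ww * yw).sum() / sw
        sxx = (ww * (xw - xbar) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xbar * xbar):
            gy[j] = ybar
        else:
            slope = (ww * (xw - xbar) * (yw - ybar)).sum() / sxx
            gy[j] = ybar + slope * (x0 - xbar)
    return gx, gy


def _merge_edges(edges: np.ndarray, counts: np.ndarray):
    """Merge empty bins leftward; returns (edges, merge log)."""
    log = []
    edges = list(edges)
    counts = list(counts)
    i = 0
    while i < len(counts):
        if counts[i] == 0 and len(counts) > 1:
            if i == 0:
                # no left neighbour: merge into the right one
                counts[1] += counts[0]
                log.append(f"merged empty bin [{edges[0]:.6g}, {edges[1]:.6g}) rightward")
                del counts[0]
                del edges[1]
            else:
                counts[i - 1] += counts[i]
                log.append(
                    f"merged empty bin [{edges[i]:.6g}, {edges[i + 1]:.6g}) leftward"
                )
                del counts[i]
                del edges[i]
                i -= 1
        else:
            i += 1
    return np.array(edges), np.array(counts, dtype=int), log


def _assign_bins(s: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Bin index per score for half-open [lo, hi) bins, last bin closed."""
    idx = np.searchsorted(edges[1:-1], s, side="right")
    return np.clip(idx, 0, len(edges) - 2)


def validation_curve(
    scores,
    labels,
    config: CalibrationConfig = CalibrationConfig(),
    threshold: float = 0.5,
) -> ValidationCurve:
    """Assemble all data of a validation plot.

    Requires both outcome classes.  Risk groups come from
    :func:`exponential_quantile_edges`; duplicate edges (heavily tied
    scores) and empty bins are merged leftward with the merges logged; the
    LOWESS smooth is fitted to the raw (score, label) pairs and evaluated on
    an equally spaced grid across the observed score range.
    """
    s = as_float_array(scores, "scores")
    l = as_label_array(labels)
    if s.shape != l.shape:
        raise ValueError("scores and labels must have equal length")
    if l.min() == l.max():
        raise ConfigurationError("validation curve requires both outcome classes")

    raw_edges = exponential_quantile_edges(s, config)
    edges, dup_dropped = np.unique(raw_edges), len(raw_edges) - len(np.unique(raw_edges))
    merge_log = []
    if dup_dropped:
        merge_log.append(f"dropped {dup_dropped} duplicate edge(s) from tied scores")
    if len(edges) == 1:  # all scores identical
        edges = np.array([edges[0], edges[0]])
    bin_idx = _assign_bins(s, edges)
    counts = np.bincount(bin_idx, minlength=len(edges) - 1)
    edges, counts, log2 = _merge_edges(edges, counts)
    merge_log.extend(log2)
    bin_idx = _assign_bins(s, edges)

    bins = []
    for b in range(len(edges) - 1):
        mask = bin_idx == b
        nb = int(mask.sum())
        k = int(l[mask].sum())
        lo, hi = wilson_interval(k, nb, config.alpha)
        bins.append(
            RiskBin(
                lower=float(edges[b]),
                upper=float(edges[b + 1]),
                n=nb,
                mean_predicted=float(s[mask].mean()),
                observed_proportion=k / nb,
                wilson_lo=lo,
                wilson_hi=hi,
            )
        )

    if np.ptp(s) > 0:
        grid = np.linspace(s.min(), s.max(), config.n_grid)
    else:
        grid = np.array([s.min()])
    gx, gy = lowess_curve(s, l, span=config.lowess_span, grid=grid)

    hist_edges = np.histogram_bin_edges(s, bins=config.n_hist_bins)
    hist_event, _ = np.histogram(s[l == 1], bins=hist_edges)
    hist_nonevent, _ = np.histogram(s[l == 0], bins=hist_edges)

    return ValidationCurve(
        bins=bins,
        lowess_x=gx,
        lowess_y=gy,
        hist_edges=hist_edges,
        hist_event=hist_event,
        hist_nonevent=hist_nonevent,
        threshold=threshold,
        n_merges=len(merge_log),
        merge_log=merge_log,
    )
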