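"""Discrimination metrics with bootstrap confidence intervals.

AUROC uses the Mann–Whitney formulation (ties counted 1/2), AUPRC is
step-wise average precision with tied scores treated as one rank block, and
the threshold metrics are the usual confusion-matrix ratios at a risk
cut-off.  Confidence intervals come from a seeded nonparametric bootstrap:
(score, label) pairs are resampled jointly n-out-of-n, K times, and the CI
is the empirical percentile interval of the resample statistics.  Resamples
on which a metric is undefined (single-class draws) are redrawn and the
redraw count is logged on the estimate.

Implementation note: the sample is sorted by score once; an n-out-of-n
resample is then represented by its multinomial count vector over the
sorted sample, which turns every metric — including the two ranking metrics
with their tie blocks — into cumulative sums and dot products over the
counts.  This makes the default K = 10,000 practical at cohort scale
without per-resample sorting.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from ._util import as_float_array, as_label_array
from .exceptions import ConfigurationError, UndefinedMetricError

__all__ = [
    "MetricConfig",
    "BootstrapConfig",
    "MetricEstimate",
    "ThresholdMetrics",
    "auroc",
    "auprc",
    "threshold_metrics",
    "bootstrap_ci",
    "bootstrap_cis",
    "NAMED_METRICS",
]


@dataclass(frozen=True)
class MetricConfig:
    """Threshold configuration for binary predictions (``score >= threshold``
    predicts the event)."""

    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must be in (0, 1)")


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap parameters: K resamples, two-sided level alpha, seed.

    ``exhaustive=True`` enumerates all n**n ordered resamples instead of
    sampling (only sensible for tiny n; guarded at n <= 8).
    """

    n_resamples: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ConfigurationError("n_resamples must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")

    def with_seed(self, seed: int) -> "BootstrapConfig":
        return replace(self, seed=int(seed))


@dataclass
class MetricEstimate:
    """A point estimate with a percentile-bootstrap interval."""

    name: str
    point: float
    ci_lo: float
    ci_hi: float
    k: int
    alpha: float
    n_redraws: int = 0
    degenerate: bool = False  # point outside its own interval (pathological)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "point": self.point,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "k": self.k,
            "alpha": self.alpha,
            "n_redraws": self.n_redraws,
            "degenerate": self.degenerate,
        }


@dataclass
class ThresholdMetrics:
    """Confusion-matrix ratios at a fixed risk threshold.

    Ratios with an empty denominator are ``None`` and listed in
    ``undefined`` — they are never silently reported as zero.
    """

    accuracy: float
    precision_event: float | None
    precision_nonevent: float | None
    recall_event: float | None
    recall_nonevent: float | None
    threshold: float = 0.5
    undefined: frozenset = field(default_factory=frozenset)


# ---------------------------------------------------------------------------
# sample context: the score-sorted sample and its tie-block geometry
# ---------------------------------------------------------------------------


class _SampleContext:
    """Score-ascending view of a (scores, labels) sample.

    ``bs``/``be`` give, per sorted element, the first/last index of its tie
    block (the run of elements sharing the same score value).
    """

    def __init__(self, scores: np.ndarray, labels: np.ndarray):
        order = np.argsort(scores, kind="stable")
        self.n = scores.size
        self.ss = scores[order]
        self.ls = labels[order]
        self.neg = 1.0 - self.ls
        n = self.n
        pos = np.arange(n)
        new = np.empty(n, dtype=bool)
        new[0] = True
        new[1:] = self.ss[1:] != self.ss[:-1]
        self.bs = np.maximum.accumulate(np.where(new, pos, -1))
        last = np.empty(n, dtype=bool)
        last[-1] = True
        last[:-1] = self.ss[:-1] != self.ss[1:]
        self.be = np.minimum.accumulate(np.where(last, pos, n)[::-1])[::-1]
        self.has_ties = bool((self.bs != pos).any())


# ---------------------------------------------------------------------------
# counts kernels: (C, ctx, threshold) -> (values, valid_mask)
# C is a (rows, n) float matrix of resample multiplicities over the sorted
# sample; a row summing to n represents one n-out-of-n resample
# ---------------------------------------------------------------------------


def _shift(cum: np.ndarray) -> np.ndarray:
    """cum shifted right by one column, zero-filled (strictly-below sums)."""
    out = np.empty_like(cum)
    out[:, 0] = 0.0
    out[:, 1:] = cum[:, :-1]
    return out


def _below_block(cum: np.ndarray, ctx: _SampleContext) -> np.ndarray:
    """Cumulative sum strictly below each element's tie block."""
    if not ctx.has_ties:
        return _shift(cum)
    out = cum[:, np.maximum(ctx.bs - 1, 0)]
    out[:, ctx.bs == 0] = 0.0
    return out


def _rows_auroc(C, ctx: _SampleContext, threshold):
    Cpos = C * ctx.ls
    Cneg = C * ctx.neg
    cumneg = np.cumsum(Cneg, axis=1)
    below = _below_block(cumneg, ctx)  # negatives with strictly lower score
    P = Cpos.sum(axis=1)
    N = Cneg.sum(axis=1)
    valid = (P > 0) & (N > 0)
    num = (Cpos * below).sum(axis=1)
    if ctx.has_ties:
        within = cumneg[:, ctx.be] - below  # negatives tied with this score
        num += 0.5 * (Cpos * within).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = num / (P * N)
    return vals, valid


def _rows_auprc(C, ctx: _SampleContext, threshold):
    Cpos = C * ctx.ls
    cumall = np.cumsum(C, axis=1)
    cumtp = np.cumsum(Cpos, axis=1)
    total = cumall[:, -1:]
    P = cumtp[:, -1]
    # block-level precision in descending order: positives at or above the
    # element's tie block over everything at or above it
    below_all = _below_block(cumall, ctx)
    below_tp = _below_block(cumtp, ctx)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = (P[:, None] - below_tp) / (total - below_all)
    # empty at-or-above regions (unsampled elements) give 0/0; their weight
    # in the sum is zero, so clear them
    prec[~np.isfinite(prec)] = 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (Cpos * prec).sum(axis=1) / P
    valid = P > 0
    return vals, valid


def _confusion(C, ctx, threshold):
    predpos = (ctx.ss >= threshold).astype(float)
    tp = C @ (ctx.ls * predpos)
    fp = C @ (ctx.neg * predpos)
    fn = C @ (ctx.ls * (1.0 - predpos))
    tn = C @ (ctx.neg * (1.0 - predpos))
    return tp, fp, fn, tn


def _ratio(num, den):
    valid = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = num / den
    return vals, valid


def _rows_accuracy(C, ctx, threshold):
    tp, fp, fn, tn = _confusion(C, ctx, threshold)
    return (tp + tn) / C.sum(axis=1), np.ones(C.shape[0], dtype=bool)


def _rows_precision_event(C, ctx, threshold):
    tp, fp, fn, tn = _confusion(C, ctx, threshold)
    return _ratio(tp, tp + fp)


def _rows_precision_nonevent(C, ctx, threshold):
    tp, fp, fn, tn = _confusion(C, ctx, threshold)
    return _ratio(tn, tn + fn)


def _rows_recall_event(C, ctx, threshold):
    tp, fp, fn, tn = _confusion(C, ctx, threshold)
    return _ratio(tp, tp + fn)


def _rows_recall_nonevent(C, ctx, threshold):
    tp, fp, fn, tn = _confusion(C, ctx, threshold)
    return _ratio(tn, tn + fp)


def _rows_event_rate(C, ctx, threshold):
    return (C @ ctx.ls) / C.sum(axis=1), np.ones(C.shape[0], dtype=bool)


def _rows_mean_score(C, ctx, threshold):
    return (C @ ctx.ss) / C.sum(axis=1), np.ones(C.shape[0], dtype=bool)


def _rows_citl_relative(C, ctx, threshold):
    """Calibration-in-the-large relative difference
    (mean predicted − observed rate) / observed rate."""
    sbar = C @ ctx.ss
    lbar = C @ ctx.ls
    return _ratio(sbar - lbar, lbar)


NAMED_METRICS: Mapping[str, Callable] = {
    "auroc": _rows_auroc,
    "auprc": _rows_auprc,
    "accuracy": _rows_accuracy,
    "precision_event": _rows_precision_event,
    "precision_nonevent": _rows_precision_nonevent,
    "recall_event": _rows_recall_event,
    "recall_nonevent": _rows_recall_nonevent,
    "event_rate": _rows_event_rate,
    "mean_score": _rows_mean_score,
    "citl_relative": _rows_citl_relative,
}

#: kernels needing O(n) cumulative sums per resample (vs a dot product);
#: drives the chunking choice
_HEAVY = {"auroc", "auprc"}


# ---------------------------------------------------------------------------
# scalar metrics
# ---------------------------------------------------------------------------


def _prepare(scores, labels):
    s = as_float_array(scores, "scores")
    l = as_label_array(labels)
    if s.shape != l.shape:
        raise ValueError("scores and labels must have equal length")
    return s, l


def _full_sample_value(name: str, s, l, threshold: float):
    ctx = _SampleContext(s, l)
    C = np.ones((1, ctx.n))
    vals, valid = NAMED_METRICS[name](C, ctx, threshold)
    return float(vals[0]), bool(valid[0])


def auroc(scores, labels) -> float:
    """Probability a uniformly random positive outranks a uniformly random
    negative, ties counted 1/2 (Mann–Whitney formulation).

    Raises :class:`UndefinedMetricError` unless both classes are present.
    """
    s, l = _prepare(scores, labels)
    val, ok = _full_sample_value("auroc", s, l, 0.5)
    if not ok:
        raise UndefinedMetricError("AUROC undefined: labels contain a single class")
    return val


def auprc(scores, labels) -> float:
    """Step-wise average precision (no interpolation): the mean, over
    positives ranked by descending score, of the precision at each
    positive's rank.  Tied scores form one rank block and every positive in
    the block is credited the block-level precision.

    Raises :class:`UndefinedMetricError` when there are no positives.
    """
    s, l = _prepare(scores, labels)
    val, ok = _full_sample_value("auprc", s, l, 0.5)
    if not ok:
        raise UndefinedMetricError("AUPRC undefined: no positive labels")
    return val


def threshold_metrics(scores, labels, config: MetricConfig = MetricConfig()) -> ThresholdMetrics:
    """Accuracy and per-class precision/recall at ``config.threshold``.

    Raises :class:`UndefinedMetricError` unless both classes are present in
    ``labels``; individual ratios with an empty denominator come back as
    ``None`` with the metric name recorded in ``undefined``.
    """
    s, l = _prepare(scores, labels)
    if l.min() == l.max():
        raise UndefinedMetricError("threshold metrics undefined: single-class labels")
    out: dict[str, float | None] = {}
    undefined = set()
    for name in (
        "accuracy",
        "precision_event",
        "precision_nonevent",
        "recall_event",
        "recall_nonevent",
    ):
        val, ok = _full_sample_value(name, s, l, config.threshold)
        if ok:
            out[name] = val
        else:
            out[name] = None
            undefined.add(name)
    return ThresholdMetrics(
        threshold=config.threshold, undefined=frozenset(undefined), **out
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

_MAX_REDRAW_FACTOR = 100


def _point_estimate(metric, s, l, threshold) -> float:
    if callable(metric):
        return float(metric(s, l))
    val, ok = _full_sample_value(metric, s, l, threshold)
    if not ok:
        raise UndefinedMetricError(f"metric {metric!r} undefined on the full sample")
    return val


def point_estimate(metric: str, scores, labels, threshold: float = 0.5) -> float:
    """Point value of a named metric; raises :class:`UndefinedMetricError`
    when it is undefined on this sample (single class, empty denominator)."""
    s, l = _prepare(scores, labels)
    return _point_estimate(metric, s, l, threshold)


def _resample_stats_named(kernels, ctx: _SampleContext, cfg, threshold, rng):
    """Resample statistics for several named metrics on shared resamples.
    Returns (stats dict name -> array of length K, n_redraws)."""
    n = ctx.n
    K = cfg.n_resamples
    budget_elems = 8_000_000 if any(k in _HEAVY for k in kernels) else 40_000_000
    chunk = max(1, min(K, budget_elems // max(n, 1)))
    out = {name: np.empty(K) for name in kernels}
    filled = 0
    redraws = 0
    budget = _MAX_REDRAW_FACTOR * K + 1000
    while filled < K:
        rows = min(chunk, K - filled)
        idx = rng.integers(0, n, size=(rows, n))
        idx += (np.arange(rows) * n)[:, None]
        C = np.bincount(idx.ravel(), minlength=rows * n).reshape(rows, n).astype(float)
        vals = {}
        valid = np.ones(rows, dtype=bool)
        for name, kern in kernels.items():
            v, ok = kern(C, ctx, threshold)
            vals[name] = v
            valid &= ok
        nv = int(valid.sum())
        if nv:
            for name in kernels:
                out[name][filled : filled + nv] = vals[name][valid]
            filled += nv
        redraws += rows - nv
        budget -= rows
        if budget <= 0:
            raise UndefinedMetricError(
                "bootstrap redraw budget exhausted; metric undefined on almost "
                "all resamples"
            )
    return out, redraws


def _exhaustive_stats(kernels, ctx: _SampleContext, threshold):
    n = ctx.n
    if n > 8:
        raise ConfigurationError("exhaustive bootstrap enumeration only supported for n <= 8")
    idx = np.array(list(itertools.product(range(n), repeat=n)), dtype=int)
    eye = np.eye(n)
    C = eye[idx].sum(axis=1)  # multiplicity vectors over the sorted sample
    out = {}
    dropped = {}
    for name, kern in kernels.items():
        vals, valid = kern(C, ctx, threshold)
        out[name] = vals[valid]
        dropped[name] = int((~valid).sum())
    return out, dropped


def _interval(stats: np.ndarray, alpha: float) -> tuple[float, float]:
    lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def bootstrap_cis(
    metrics: Sequence[str],
    scores,
    labels,
    config: BootstrapConfig = BootstrapConfig(),
    threshold: float = 0.5,
) -> dict[str, MetricEstimate]:
    """Percentile-bootstrap estimates for several named metrics computed on
    shared resamples.

    A resample is redrawn if *any* requested metric is undefined on it, so
    all intervals describe the same resample population.
    """
    s, l = _prepare(scores, labels)
    kernels = {}
    for m in metrics:
        if m not in NAMED_METRICS:
            raise ConfigurationError(f"unknown metric {m!r}")
        kernels[m] = NAMED_METRICS[m]
    points = {m: _point_estimate(m, s, l, threshold) for m in metrics}
    ctx = _SampleContext(s, l)
    if config.exhaustive:
        stats, dropped = _exhaustive_stats(kernels, ctx, threshold)
        redraws = {m: dropped[m] for m in metrics}
        ks = {m: stats[m].size for m in metrics}
    else:
        rng = np.random.default_rng(config.seed)
        stats, n_redraws = _resample_stats_named(kernels, ctx, config, threshold, rng)
        redraws = {m: n_redraws for m in metrics}
        ks = {m: config.n_resamples for m in metrics}
    out = {}
    for m in metrics:
        lo, hi = _interval(stats[m], config.alpha)
        point = points[m]
        out[m] = MetricEstimate(
            name=m,
            point=point,
            ci_lo=lo,
            ci_hi=hi,
            k=ks[m],
            alpha=config.alpha,
            n_redraws=redraws[m],
            degenerate=not (lo <= point <= hi),
        )
    return out


def bootstrap_ci(
    metric,
    scores,
    labels,
    config: BootstrapConfig = BootstrapConfig(),
    threshold: float = 0.5,
) -> MetricEstimate:
    """Percentile-bootstrap interval for one metric.

    ``metric`` is either a name in :data:`NAMED_METRICS` (fast, vectorized)
    or an arbitrary callable ``f(scores, labels) -> float``; a callable that
    raises :class:`UndefinedMetricError` (or returns NaN) on a resample
    causes that resample to be redrawn.
    """
    if isinstance(metric, str):
        return bootstrap_cis([metric], scores, labels, config, threshold)[metric]

    s, l = _prepare(scores, labels)
    point = _point_estimate(metric, s, l, threshold)
    if config.exhaustive:
        raise ConfigurationError("exhaustive enumeration requires a named metric")
    rng = np.random.default_rng(config.seed)
    n = s.size
    stats = np.empty(config.n_resamples)
    filled = 0
    redraws = 0
    budget = _MAX_REDRAW_FACTOR * config.n_resamples + 1000
    while filled < config.n_resamples:
        idx = rng.integers(0, n, size=n)
        try:
            v = float(metric(s[idx], l[idx]))
        except UndefinedMetricError:
            v = np.nan
        if np.isnan(v):
            redraws += 1
        else:
            stats[filled] = v
            filled += 1
        budget -= 1
        if budget <= 0:
            raise UndefinedMetricError("bootstrap redraw budget exhausted")
    lo, hi = _interval(stats, config.alpha)
    name = getattr(metric, "__name__", "custom")
    return MetricEstimate(
        name=name,
        point=point,
        ci_lo=lo,
        ci_hi=hi,
        k=config.n_resamples,
        alpha=config.alpha,
        n_redraws=redraws,
        degenerate=not (lo <= point <= hi),
    )
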