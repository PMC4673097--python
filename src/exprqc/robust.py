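"""Robust one-dimensional primitives.

Three building blocks shared by the marker-selection, normalization and
classification steps: a deterministic two-group split of a value vector,
the Rousseeuw-Croux Qn scale estimator, and normal-tail cut points derived
from robust location/scale estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

#: Asymptotic consistency constant for Qn under the normal model.
QN_CONSTANT = 2.2219


@dataclass(frozen=True)
class GroupSplit:
    """Outcome of splitting one value vector into low/high groups.

    ``low_members`` / ``high_members`` index into the original input vector
    (missing entries belong to neither group). When the vector cannot be
    split (too few values, or everything equal) all values land in the low
    group, ``high_members`` is empty and the high-group statistics are NaN.
    """

    threshold: float
    low_members: tuple[int, ...]
    high_members: tuple[int, ...]
    median_low: float
    median_high: float
    qn_low: float
    qn_high: float
    separation: float
    bimodal: bool

    @property
    def span(self) -> float:
        """High-minus-low median gap (NaN for degenerate splits)."""
        return self.median_high - self.median_low


def qn_scale(values, constant: float = QN_CONSTANT) -> float:
    """Rousseeuw-Croux Qn scale estimate of a 1-D sample.

    Computes ``constant`` times the k-th smallest of the n(n-1)/2 absolute
    pairwise differences, with ``h = floor(n/2) + 1`` and
    ``k = h*(h-1)/2``. No finite-sample correction is applied.

    Parameters
    ----------
    values:
        1-D array-like; NaNs are dropped.
    constant:
        Consistency constant (2.2219 by default).

    Raises
    ------
    ValueError
        If fewer than two non-missing values remain.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[~np.isnan(x)]
    n = x.size
    if n < 2:
        raise ValueError("qn_scale requires at least 2 non-missing values")
    h = n // 2 + 1
    k = h * (h - 1) // 2
    x = np.sort(x)
    # Materialize all pairwise differences row by row; for the sizes seen in
    # practice (n <= ~10^4) this stays within a few hundred MB.
    diffs = np.empty(n * (n - 1) // 2, dtype=float)
    pos = 0
    for i in range(n - 1):
        m = n - 1 - i
        diffs[pos : pos + m] = x[i + 1 :] - x[i]
        pos += m
    kth = np.partition(diffs, k - 1)[k - 1]
    return constant * float(kth)


def _group_stats(x: np.ndarray) -> tuple[float, float]:
    """Median and Qn of a group; Qn of a singleton group is 0."""
    med = float(np.median(x))
    qn = qn_scale(x) if x.size >= 2 else 0.0
    return med, qn


def two_group_split(
    values,
    min_group: int = 2,
    sep_min: float = 3.0,
) -> GroupSplit:
    """Deterministically split a value vector into low and high groups.

    The split threshold is found by an exhaustive scan over the n-1
    candidate cuts between consecutive sorted values, minimizing the pooled
    within-group sum of squared deviations subject to both groups having at
    least ``min_group`` members (equivalent to optimal 2-means in 1-D; no
    randomness involved). The split is called bimodal when

        separation = (median_high - median_low) / (qn_low + qn_high + eps)

    reaches ``sep_min``, with ``eps = 1e-12 * max(1, |median_high|)``
    guarding zero-scale groups.

    Degenerate inputs (all values equal, or fewer than ``2 * min_group``
    values) yield a single low group with ``bimodal=False``.
    """
    if min_group < 1:
        raise ValueError("min_group must be >= 1")
    x = np.asarray(values, dtype=float).ravel()
    keep = np.flatnonzero(~np.isnan(x))
    if keep.size < 2:
        raise ValueError("two_group_split requires at least 2 non-missing values")
    xv = x[keep]
    order = np.argsort(xv, kind="stable")
    xs = xv[order]
    n = xs.size

    def _degenerate() -> GroupSplit:
        med, qn = _group_stats(xs)
        return GroupSplit(
            threshold=float(xs[-1]),
            low_members=tuple(int(i) for i in keep[order]),
            high_members=(),
            median_low=med,
            median_high=math.nan,
            qn_low=qn,
            qn_high=math.nan,
            separation=0.0,
            bimodal=False,
        )

    if n < 2 * min_group or xs[0] == xs[-1]:
        return _degenerate()

    # Pooled within-group SSQ for every admissible low-group size, via
    # prefix sums: ssq(block) = sum(x^2) - sum(x)^2 / m.
    cs = np.cumsum(xs)
    cs2 = np.cumsum(xs * xs)
    total, total2 = cs[-1], cs2[-1]
    sizes = np.arange(min_group, n - min_group + 1)
    low_sum = cs[sizes - 1]
    low_sum2 = cs2[sizes - 1]
    ssq_low = low_sum2 - low_sum**2 / sizes
    high_sizes = n - sizes
    ssq_high = (total2 - low_sum2) - (total - low_sum) ** 2 / high_sizes
    cost = ssq_low + ssq_high
    # The threshold must strictly separate the groups.
    valid = xs[sizes - 1] < xs[sizes]
    if not np.any(valid):
        return _degenerate()
    cost = np.where(valid, cost, np.inf)
    i_low = int(sizes[int(np.argmin(cost))])

    low_idx = keep[order[:i_low]]
    high_idx = keep[order[i_low:]]
    median_low, qn_low = _group_stats(xs[:i_low])
    median_high, qn_high = _group_stats(xs[i_low:])
    eps = 1e-12 * max(1.0, abs(median_high))
    separation = (median_high - median_low) / (qn_low + qn_high + eps)
    return GroupSplit(
        threshold=float(xs[i_low - 1]),
        low_members=tuple(int(i) for i in low_idx),
        high_members=tuple(int(i) for i in high_idx),
        median_low=median_low,
        median_high=median_high,
        qn_low=qn_low,
        qn_high=qn_high,
        separation=float(separation),
        bimodal=bool(separation >= sep_min),
    )


@dataclass(frozen=True)
class CutPoint:
    """Upper-tail quantile of a normal fitted robustly to the low group.

    ``cut = median_low + z(level) * qn_low``. A zero scale makes the cut
    non-informative: downstream evidence for the probe is forced to 0.
    """

    level: float
    cut: float
    informative: bool
    probe_id: str | None = None


def cut_point(
    median_low: float,
    qn_low: float,
    level: float = 0.999,
    probe_id: str | None = None,
) -> CutPoint:
    """Normal-tail cut point from robust low-group location and scale."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    if qn_low < 0:
        raise ValueError("qn_low must be >= 0")
    cut = float(median_low + norm.ppf(level) * qn_low)
    return CutPoint(level=level, cut=cut, informative=qn_low > 0, probe_id=probe_id)
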