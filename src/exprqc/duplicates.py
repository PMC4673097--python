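"""Duplicate-sample detection by correlation-gap analysis.

High-variance probes are selected, Pearson correlations between all sample
pairs are computed, and the largest gap in the ordered correlations
separates duplicated measurements from ordinary pairs. Guards (`r_min`,
`max_frac`) keep the gap rule from firing on cohorts without duplicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .matrix import ExpressionMatrix
from .report import SampleVerdict, percentage

logger = logging.getLogger(__name__)

Pair = tuple[str, str, float]


@dataclass(frozen=True)
class DuplicateReport:
    """Result of the correlation-gap duplicate scan for one cohort.

    ``pairs`` are exactly the sample pairs whose correlation lies strictly
    above ``gap_threshold`` (and above the ``r_min`` guard), sorted by
    correlation descending; a sample may appear in several pairs.
    """

    cohort_id: str
    k_probes_used: int
    ordered_correlations: tuple[float, ...]
    gap_index: int | None
    gap_threshold: float | None
    pairs: tuple[Pair, ...]


def top_variance_probes(matrix: ExpressionMatrix, k: int) -> list[str]:
    """IDs of the k highest-variance probes (sample variance, n-1).

    Probes with any missing value are excluded before ranking; variance
    ties are broken by probe ID ascending. If fewer than k probes are
    eligible, all of them are returned with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if len(matrix.sample_ids) < 2:
        raise ValueError("top_variance_probes requires >= 2 samples")
    complete = ~np.isnan(matrix.values).any(axis=1)
    variances = np.var(matrix.values, axis=1, ddof=1)
    eligible = [
        (float(-variances[i]), matrix.probe_ids[i])
        for i in np.flatnonzero(complete)
    ]
    eligible.sort()
    if len(eligible) < k:
        logger.warning(
            "only %d of %d requested probes eligible for variance ranking",
            len(eligible),
            k,
        )
    return [probe_id for _, probe_id in eligible[:k]]


def pairwise_correlations(matrix: ExpressionMatrix) -> list[Pair]:
    """Pearson correlation for every unordered sample pair.

    Pair IDs are reported in lexicographic order so the output does not
    depend on the column order of the input. Samples with zero-variance
    vectors have undefined correlations and are excluded with a warning.
    """
    n = len(matrix.sample_ids)
    if n < 2:
        raise ValueError("pairwise_correlations requires >= 2 samples")
    if len(matrix.probe_ids) < 3:
        raise ValueError("pairwise_correlations requires >= 3 probes")
    values = matrix.values
    stds = values.std(axis=0)
    degenerate = np.flatnonzero(~(stds > 0) | np.isnan(stds))
    if degenerate.size:
        logger.warning(
            "excluding %d zero-variance sample(s) from correlation analysis: %s",
            degenerate.size,
            [matrix.sample_ids[j] for j in degenerate[:5]],
        )
    ok = np.flatnonzero((stds > 0) & ~np.isnan(stds))
    if ok.size < 2:
        return []
    corr = np.corrcoef(values[:, ok], rowvar=False)
    pairs: list[Pair] = []
    for a_pos in range(ok.size):
        for b_pos in range(a_pos + 1, ok.size):
            sa = matrix.sample_ids[ok[a_pos]]
            sb = matrix.sample_ids[ok[b_pos]]
            if sb < sa:
                sa, sb = sb, sa
            pairs.append((sa, sb, float(corr[a_pos, b_pos])))
    return pairs


def gap_split(
    ordered_correlations: Sequence[float],
    r_min: float = 0.95,
    max_frac: float = 0.1,
) -> tuple[int | None, float | None]:
    """Locate the largest admissible gap in descending ordered correlations.

    Returns ``(gap_index, gap_threshold)`` where ``gap_index`` is the size
    of the above-gap block and ``gap_threshold`` the midpoint of the gap.
    A split position is admissible when every value above it reaches
    ``r_min`` and the upper block holds at most ``max(1, max_frac * n)``
    pairs; with no admissible positive gap, ``(None, None)`` is returned
    (no duplicates).

    Setting ``r_min=-1`` and ``max_frac=1`` recovers the unguarded
    largest-gap rule.
    """
    r = np.asarray(ordered_correlations, dtype=float)
    if r.size < 2:
        raise ValueError("gap_split requires >= 2 correlation values")
    if np.any(np.diff(r) > 0):
        raise ValueError("correlations must be ordered descending")
    limit = max(1.0, max_frac * r.size)
    best_i: int | None = None
    best_gap = 0.0
    for i in range(1, r.size):
        if r[i - 1] < r_min or i > limit:
            break
        gap = r[i - 1] - r[i]
        if gap > best_gap:
            best_gap = gap
            best_i = i
    if best_i is None:
        return None, None
    return best_i, float((r[best_i - 1] + r[best_i]) / 2.0)


def find_duplicates(
    matrix: ExpressionMatrix,
    cohort_id: str = "cohort",
    config: PipelineConfig | None = None,
    k: int | None = None,
) -> DuplicateReport:
    """Full duplicate scan: top-variance probes, correlations, gap split.

    Correlations are computed on raw (unnormalized) expression values of
    the selected probes.
    """
    cfg = config or DEFAULT_CONFIG
    k = cfg.top_k_variance if k is None else k
    probes = top_variance_probes(matrix, k)
    sub = matrix.subset_probes(probes)
    pairs = pairwise_correlations(sub)
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    ordered = tuple(p[2] for p in pairs)
    if len(ordered) < 2:
        return DuplicateReport(cohort_id, len(probes), ordered, None, None, ())
    gap_index, threshold = gap_split(ordered, r_min=cfg.r_min, max_frac=cfg.max_frac)
    flagged: tuple[Pair, ...] = ()
    if threshold is not None:
        flagged = tuple(
            p for p in pairs if p[2] > threshold and p[2] >= cfg.r_min
        )
    return DuplicateReport(
        cohort_id=cohort_id,
        k_probes_used=len(probes),
        ordered_correlations=ordered,
        gap_index=gap_index,
        gap_threshold=threshold,
        pairs=flagged,
    )


def duplicate_groups(pairs: Sequence[Pair]) -> list[tuple[str, ...]]:
    """Connected components of the duplicate-pair graph (convenience)."""
    adjacency: dict[str, set[str]] = {}
    for a, b, _ in pairs:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    seen: set[str] = set()
    groups: list[tuple[str, ...]] = []
    for node in sorted(adjacency):
        if node in seen:
            continue
        stack, component = [node], []
        while stack:
            current = stack.pop()
            if current in seen:
                continue
            seen.add(current)
            component.append(current)
            stack.extend(adjacency[current] - seen)
        groups.append(tuple(sorted(component)))
    return groups


def cross_check_duplicates(
    pairs: Sequence[Pair], verdicts: Sequence[SampleVerdict]
) -> dict:
    """Overlap between duplicate pairs and misclassified samples.

    Counts the misclassified samples that belong to at least one duplicate
    pair and reports the count and its percentage of all misclassified
    samples (one decimal, half-up).
    """
    duplicate_members = {s for a, b, _ in pairs for s in (a, b)}
    misclassified = [v.sample_id for v in verdicts if v.category == "misclassified"]
    explained = [s for s in misclassified if s in duplicate_members]
    return {
        "n_misclassified": len(misclassified),
        "n_explained_by_duplicates": len(explained),
        "pct_explained": percentage(len(explained), len(misclassified)),
        "explained_sample_ids": sorted(explained),
    }
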