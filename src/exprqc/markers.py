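"""Marker selection: rank probes by univariate male-female accuracy.

Candidate probes are scored per dataset by splitting their values into two
groups (same deterministic split used throughout the pipeline), assigning
each group its majority annotated sex and counting agreement; probes are
then ranked by the median accuracy across datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .matrix import ExpressionMatrix, SexAnnotation
from .robust import two_group_split

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerCandidate:
    probe_id: str
    per_dataset_accuracy: tuple[float, ...]
    median_accuracy: float


def probe_accuracy(
    values,
    labels: Sequence[str],
    config: PipelineConfig | None = None,
) -> float:
    """Univariate male-female classification accuracy of one probe.

    Splits the values of labelled (female/male) samples into two groups,
    assigns each group the majority sex of its members, and returns the
    fraction of labelled samples whose group sex matches their label.
    Majority ties are broken toward the assignment maximizing accuracy
    (both resolutions of a tie yield the same count, so any is optimal).

    Raises
    ------
    ValueError
        If fewer than two labelled samples remain, or only one sex is
        present (accuracy undefined for selection).
    """
    cfg = config or DEFAULT_CONFIG
    x = np.asarray(values, dtype=float).ravel()
    if len(labels) != x.size:
        raise ValueError("values and labels must have equal length")
    keep = np.array(
        [lab in ("female", "male") and not np.isnan(v) for v, lab in zip(x, labels)]
    )
    x = x[keep]
    labs = np.asarray(labels, dtype=object)[keep]
    if x.size < 2:
        raise ValueError("probe_accuracy requires >= 2 labelled samples")
    if len(set(labs)) < 2:
        raise ValueError("probe_accuracy requires both sexes among labelled samples")
    split = two_group_split(x, min_group=cfg.min_group, sep_min=cfg.sep_min)
    # Map split member indices (into the filtered vector) to label arrays.
    correct = 0
    for members in (split.low_members, split.high_members):
        if not members:
            continue
        group = labs[list(members)]
        n_female = int(np.sum(group == "female"))
        correct += max(n_female, len(group) - n_female)
    return correct / x.size


def select_markers(
    datasets: Sequence[tuple[ExpressionMatrix, SexAnnotation]],
    accuracy_threshold: float = 0.75,
    top_k: int | None = None,
    config: PipelineConfig | None = None,
) -> list[MarkerCandidate]:
    """Rank shared probes by median per-dataset accuracy.

    Probes missing in more than ``config.marker_missing_max_frac`` of a
    dataset's samples, or undefined in a dataset (single sex among labelled
    samples), skip that dataset; the median is taken over the remaining
    entries. Candidates with median accuracy >= ``accuracy_threshold`` are
    returned sorted by (median accuracy desc, probe ID asc) and truncated
    to ``top_k``.
    """
    cfg = config or DEFAULT_CONFIG
    if not datasets:
        raise ValueError("select_markers requires at least one dataset")
    shared = set(datasets[0][0].probe_ids)
    for matrix, _ in datasets[1:]:
        shared &= set(matrix.probe_ids)
    if not shared:
        raise ValueError("datasets share no probes")

    aligned = [
        (matrix, matrix.sample_ids, annotation.align(matrix.sample_ids))
        for matrix, annotation in datasets
    ]
    candidates: list[MarkerCandidate] = []
    for probe_id in sorted(shared):
        accuracies: list[float] = []
        for matrix, sample_ids, labels in aligned:
            values = matrix.probe_values(probe_id)
            missing_frac = float(np.mean(np.isnan(values)))
            if missing_frac > cfg.marker_missing_max_frac:
                logger.debug(
                    "probe %s skipped in one dataset: %.0f%% missing",
                    probe_id,
                    100 * missing_frac,
                )
                continue
            try:
                accuracies.append(probe_accuracy(values, labels, cfg))
            except ValueError:
                continue
        if not accuracies:
            continue
        median_acc = float(np.median(accuracies))
        if median_acc >= accuracy_threshold:
            candidates.append(
                MarkerCandidate(probe_id, tuple(accuracies), median_acc)
            )
    candidates.sort(key=lambda c: (-c.median_accuracy, c.probe_id))
    if top_k is not None:
        candidates = candidates[:top_k]
    return candidates
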