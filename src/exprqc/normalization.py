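"""Per-probe, per-cohort linear normalization.

Each probe is rescaled within each cohort so that the median of the
low-expression group sits at 0 and the median of the high-expression group
at 1, making expression levels comparable across cohorts with arbitrary
affine shifts. Cohorts where a probe is unimodal (single-sex or unlabelled
cohorts) are anchored using the annotated majority sex and a reference
scale pooled from the bimodal cohorts of the same run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .panel import MarkerProbe
from .robust import GroupSplit, two_group_split

Provenance = Literal["two_group", "single_group_low", "single_group_high", "failed"]


@dataclass(frozen=True)
class AffineMap:
    """Orientation-preserving linear map ``x -> slope * (x - anchor)
    + offset`` with slope > 0.

    Anchored form keeps the low-group median at exactly 0 (respectively 1
    for high-anchored maps) in floating point.
    """

    slope: float
    anchor: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("slope must be > 0")

    @property
    def intercept(self) -> float:
        """Intercept of the equivalent ``slope * x + intercept`` form."""
        return self.offset - self.slope * self.anchor

    def apply(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        return self.slope * (x - self.anchor) + self.offset


@dataclass(frozen=True)
class NormalizedProbeVector:
    """One probe's cohort values on the normalized scale."""

    probe_id: str
    values: np.ndarray
    provenance: Provenance
    split: GroupSplit
    affine: AffineMap | None


def fit_affine(split: GroupSplit) -> AffineMap:
    """Map fitted from a bimodal split: low median -> 0, high median -> 1."""
    if not split.bimodal:
        raise ValueError("fit_affine requires a bimodal split")
    span = split.median_high - split.median_low
    if not span > 0:
        raise ValueError("degenerate split: median_high must exceed median_low")
    return AffineMap(slope=1.0 / span, anchor=split.median_low, offset=0.0)


def majority_sex(
    labels: Sequence[str] | None, majority: float = 0.9
) -> str | None:
    """Dominant annotated sex if it reaches the majority fraction, else None.

    Unknown labels are ignored; an all-unknown or absent annotation yields
    None (unlabelled cohort).
    """
    if labels is None:
        return None
    counts = Counter(l for l in labels if l in ("female", "male"))
    total = counts["female"] + counts["male"]
    if total == 0:
        return None
    for sex in ("female", "male"):
        if counts[sex] / total >= majority:
            return sex
    return None


def normalize_probe(
    values,
    marker: MarkerProbe,
    annotation: Sequence[str] | None = None,
    config: PipelineConfig | None = None,
    reference_scale: float | None = None,
    probe_id: str | None = None,
) -> NormalizedProbeVector:
    """Normalize one probe's cohort values to the common [0, 1] scale.

    If the two-group split is bimodal the affine map fitted from it is
    applied (provenance ``two_group``). Otherwise, if ``annotation``
    identifies the cohort as single-sex (majority fraction from config),
    the single group is oriented by the marker's evidence direction — e.g.
    a male-evidence probe in an all-female cohort is the low group — and
    shifted so its median sits at 0 (low) or 1 (high), with slope
    ``1 / reference_scale``. If neither applies the probe is marked
    ``failed`` and contributes no evidence in this cohort.

    ``annotation`` is a sequence of sex labels aligned with ``values``; it
    is used only to orient the single group, never to score individual
    samples.
    """
    cfg = config or DEFAULT_CONFIG
    x = np.asarray(values, dtype=float).ravel()
    pid = probe_id or marker.probe_id
    split = two_group_split(x, min_group=cfg.min_group, sep_min=cfg.sep_min)

    if split.bimodal:
        affine = fit_affine(split)
        return NormalizedProbeVector(pid, affine.apply(x), "two_group", split, affine)

    cohort_sex = majority_sex(annotation, cfg.single_sex_majority)
    if cohort_sex is None:
        return NormalizedProbeVector(pid, np.full_like(x, np.nan), "failed", split, None)

    scale = reference_scale if reference_scale is not None else cfg.reference_scale
    if not scale > 0:
        raise ValueError("reference scale must be > 0")
    group_median = float(np.nanmedian(x))
    if marker.evidence_sex == cohort_sex:
        # The probe is high in this cohort's sex: single observed group is
        # the high group, anchored at 1.
        affine = AffineMap(slope=1.0 / scale, anchor=group_median, offset=1.0)
        provenance: Provenance = "single_group_high"
    else:
        affine = AffineMap(slope=1.0 / scale, anchor=group_median, offset=0.0)
        provenance = "single_group_low"
    return NormalizedProbeVector(pid, affine.apply(x), provenance, split, affine)
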