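"""Male-female expression classifier.

Turns normalized marker values into binary evidence scores, combines them
into a predicted sex, and compares predictions with annotations, producing
per-sample verdicts and per-cohort reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .matrix import ExpressionMatrix, SexAnnotation
from .normalization import NormalizedProbeVector, normalize_probe
from .panel import DEFAULT_PANEL, MarkerPanel
from .report import CohortReport, SampleVerdict, percentage
from .robust import CutPoint, cut_point, qn_scale, two_group_split

logger = logging.getLogger(__name__)

SEXES = ("female", "male")


@dataclass(frozen=True)
class EvidenceVector:
    """Binary per-marker evidence scores and the combined prediction."""

    scores: dict[str, int]
    predicted_sex: str


def evidence_scores(
    values: Mapping[str, float], cuts: Mapping[str, CutPoint]
) -> dict[str, int]:
    """Score 1 iff the normalized value strictly exceeds an informative cut.

    Missing values and non-informative cut points yield 0; ties at the cut
    count as no evidence.
    """
    scores: dict[str, int] = {}
    for probe_id, value in values.items():
        cut = cuts.get(probe_id)
        if cut is None or not cut.informative or value is None or np.isnan(value):
            scores[probe_id] = 0
        else:
            scores[probe_id] = int(value > cut.cut)
    return scores


def combine_evidence(scores: Sequence[int], n_female: int = 2) -> str:
    """Combine binary evidence scores into a predicted sex.

    ``scores[:n_female]`` are female-evidence scores, the rest male
    evidence. Male requires at least one male score of 1 and all female
    scores 0; female is the mirror image; everything else (conflicting or
    absent evidence) is unconfident.
    """
    if any(s not in (0, 1) for s in scores):
        raise ValueError(f"evidence scores must be binary, got {list(scores)}")
    female = any(scores[:n_female])
    male = any(scores[n_female:])
    if female and not male:
        return "female"
    if male and not female:
        return "male"
    return "unconfident"


def verdict_category(predicted_sex: str, annotated_sex: str) -> str:
    """Category of one sample given its prediction and annotation."""
    if predicted_sex == "unconfident":
        return "unconfident"
    if annotated_sex == "unknown":
        return "unannotated"
    return "correct" if predicted_sex == annotated_sex else "misclassified"


def make_verdict(
    sample_id: str, predicted_sex: str, annotated_sex: str
) -> SampleVerdict:
    return SampleVerdict(
        sample_id=sample_id,
        annotated_sex=annotated_sex,
        predicted_sex=predicted_sex,
        category=verdict_category(predicted_sex, annotated_sex),
    )


@dataclass(frozen=True)
class CohortClassification:
    """Detailed classification outcome: report plus per-probe internals."""

    report: CohortReport
    normalized: dict[str, NormalizedProbeVector]
    cuts: dict[str, CutPoint]
    evidence: tuple[EvidenceVector, ...]

    def scatter_coordinates(
        self, panel: MarkerPanel
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mean normalized female-evidence (x) and male-evidence (y) marker
        values per sample; samples lacking all markers on an axis get NaN."""
        n = self.report.n_samples

        def axis_mean(probes) -> np.ndarray:
            rows = [
                self.normalized[p.probe_id].values
                for p in probes
                if p.probe_id in self.normalized
                and self.normalized[p.probe_id].provenance != "failed"
            ]
            if not rows:
                return np.full(n, np.nan)
            stack = np.vstack(rows)
            with np.errstate(invalid="ignore"):
                return np.nanmean(stack, axis=0)

        return axis_mean(panel.female_probes), axis_mean(panel.male_probes)


def _probe_cut(
    npv: NormalizedProbeVector,
    config: PipelineConfig,
    pooled_cuts: Mapping[str, float] | None,
) -> CutPoint:
    if config.fixed_cuts and npv.probe_id in config.fixed_cuts:
        return CutPoint(
            level=config.quantile_level,
            cut=float(config.fixed_cuts[npv.probe_id]),
            informative=True,
            probe_id=npv.probe_id,
        )
    if npv.provenance in ("two_group", "single_group_low"):
        if npv.provenance == "two_group":
            low = npv.values[list(npv.split.low_members)]
        else:
            # In a single-sex cohort the whole cohort is the low group.
            low = npv.values
        low = low[~np.isnan(low)]
        med = float(np.median(low))
        qn_low = qn_scale(low) if low.size >= 2 else 0.0
        return cut_point(med, qn_low, config.quantile_level, npv.probe_id)
    if npv.provenance == "single_group_high":
        cut = config.default_high_cut
        if pooled_cuts and npv.probe_id in pooled_cuts:
            cut = float(pooled_cuts[npv.probe_id])
        return CutPoint(
            level=config.quantile_level,
            cut=cut,
            informative=True,
            probe_id=npv.probe_id,
        )
    return CutPoint(
        level=config.quantile_level, cut=np.nan, informative=False, probe_id=npv.probe_id
    )


def classify_cohort_detailed(
    matrix: ExpressionMatrix,
    annotation: SexAnnotation,
    panel: MarkerPanel = DEFAULT_PANEL,
    config: PipelineConfig | None = None,
    cohort_id: str = "cohort",
    reference_scales: Mapping[str, float] | None = None,
    pooled_cuts: Mapping[str, float] | None = None,
) -> CohortClassification:
    """Run the full per-cohort pipeline and keep per-probe internals.

    Pipeline per panel probe: two-group split -> normalization -> cut point
    -> per-sample evidence score; scores are then combined per sample and
    compared with the annotation. ``reference_scales`` / ``pooled_cuts``
    carry pooled information from other cohorts of the same run, used for
    unimodal probes in single-sex cohorts.
    """
    cfg = config or DEFAULT_CONFIG
    present = [p for p in panel if p.probe_id in matrix.probe_ids]
    absent = [p.probe_id for p in panel if p.probe_id not in matrix.probe_ids]
    if not present:
        raise ValueError(
            f"cohort {cohort_id!r}: none of the panel probes "
            f"{list(panel.probe_ids)} are present in the matrix"
        )
    if absent:
        logger.warning(
            "cohort %s: panel probes missing from matrix: %s", cohort_id, absent
        )
    labels = annotation.align(matrix.sample_ids)

    normalized: dict[str, NormalizedProbeVector] = {}
    cuts: dict[str, CutPoint] = {}
    for probe in present:
        values = matrix.probe_values(probe.probe_id)
        ref_scale = None
        if reference_scales and probe.probe_id in reference_scales:
            ref_scale = float(reference_scales[probe.probe_id])
        npv = normalize_probe(
            values, probe, annotation=labels, config=cfg, reference_scale=ref_scale
        )
        normalized[probe.probe_id] = npv
        cuts[probe.probe_id] = _probe_cut(npv, cfg, pooled_cuts)

    female_ids = [p.probe_id for p in panel.female_probes if p.probe_id in normalized]
    male_ids = [p.probe_id for p in panel.male_probes if p.probe_id in normalized]
    verdicts: list[SampleVerdict] = []
    evidence: list[EvidenceVector] = []
    for j, sample_id in enumerate(matrix.sample_ids):
        values = {pid: float(normalized[pid].values[j]) for pid in female_ids + male_ids}
        scores = evidence_scores(values, cuts)
        ordered = [scores[pid] for pid in female_ids] + [scores[pid] for pid in male_ids]
        predicted = combine_evidence(ordered, n_female=len(female_ids))
        evidence.append(EvidenceVector(scores=scores, predicted_sex=predicted))
        verdicts.append(make_verdict(sample_id, predicted, labels[j]))

    report = CohortReport.from_verdicts(cohort_id, verdicts)
    return CohortClassification(
        report=report, normalized=normalized, cuts=cuts, evidence=tuple(evidence)
    )


def classify_cohort(
    matrix: ExpressionMatrix,
    annotation: SexAnnotation,
    panel: MarkerPanel = DEFAULT_PANEL,
    config: PipelineConfig | None = None,
    cohort_id: str = "cohort",
    reference_scales: Mapping[str, float] | None = None,
    pooled_cuts: Mapping[str, float] | None = None,
) -> CohortReport:
    """As :func:`classify_cohort_detailed`, returning only the report."""
    return classify_cohort_detailed(
        matrix,
        annotation,
        panel,
        config,
        cohort_id,
        reference_scales,
        pooled_cuts,
    ).report


def pooled_references(
    cohorts: Sequence[tuple[str, ExpressionMatrix, SexAnnotation]],
    panel: MarkerPanel = DEFAULT_PANEL,
    config: PipelineConfig | None = None,
) -> tuple[dict[str, float], dict[str, float]]:
    """Pool per-probe scale and cut information over bimodal cohorts.

    For every panel probe, collects the high-minus-low median span and the
    normalized-scale cut point from each cohort where the probe splits
    bimodally, and returns the medians of both as
    ``(reference_scales, pooled_cuts)``.
    """
    cfg = config or DEFAULT_CONFIG
    from scipy.stats import norm as _norm

    z = _norm.ppf(cfg.quantile_level)
    spans: dict[str, list[float]] = {pid: [] for pid in panel.probe_ids}
    cut_values: dict[str, list[float]] = {pid: [] for pid in panel.probe_ids}
    for _, matrix, _annotation in cohorts:
        for probe in panel:
            if probe.probe_id not in matrix.probe_ids:
                continue
            values = matrix.probe_values(probe.probe_id)
            if np.sum(~np.isnan(values)) < 2:
                continue
            split = two_group_split(values, min_group=cfg.min_group, sep_min=cfg.sep_min)
            if split.bimodal and split.span > 0:
                spans[probe.probe_id].append(split.span)
                cut_values[probe.probe_id].append(z * split.qn_low / split.span)
    reference_scales = {
        pid: float(np.median(vals)) for pid, vals in spans.items() if vals
    }
    pooled_cuts = {
        pid: float(np.median(vals)) for pid, vals in cut_values.items() if vals
    }
    return reference_scales, pooled_cuts


def classify_cohorts(
    cohorts: Sequence[tuple[str, ExpressionMatrix, SexAnnotation]],
    panel: MarkerPanel = DEFAULT_PANEL,
    config: PipelineConfig | None = None,
) -> list[CohortReport]:
    """Classify a multi-cohort run with pooled single-sex references."""
    reference_scales, pooled_cuts = pooled_references(cohorts, panel, config)
    return [
        classify_cohort(
            matrix,
            annotation,
            panel,
            config,
            cohort_id=cohort_id,
            reference_scales=reference_scales,
            pooled_cuts=pooled_cuts,
        )
        for cohort_id, matrix, annotation in cohorts
    ]


def summarize_reports(reports: Sequence[CohortReport]) -> dict:
    """Cross-cohort summary: pooled counts, percentages and affected cohorts."""
    from .report import CATEGORIES, MISLABEL_DIRECTIONS

    total = sum(r.n_samples for r in reports)
    counts = {c: sum(r.counts[c] for r in reports) for c in CATEGORIES}
    directions = {
        d: sum(r.mislabel_directions[d] for r in reports) for d in MISLABEL_DIRECTIONS
    }
    affected = sum(1 for r in reports if r.counts["misclassified"] > 0)
    return {
        "n_cohorts": len(reports),
        "n_samples": total,
        "counts": counts,
        "percentages": {c: percentage(counts[c], total) for c in CATEGORIES},
        "mislabel_directions": directions,
        "cohorts_with_misclassified": affected,
        "pct_cohorts_with_misclassified": percentage(affected, len(reports), 0)
        if reports
        else 0.0,
    }
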