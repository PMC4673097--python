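import itertools

import numpy as np
import pytest

from exprqc import (
    DEFAULT_FIXED_CUTS,
    DEFAULT_PANEL,
    PipelineConfig,
    SexAnnotation,
    SyntheticConfig,
    classify_cohort,
    classify_cohort_detailed,
    classify_cohorts,
    combine_evidence,
    evidence_scores,
    simulate_cohort,
    summarize_reports,
    verdict_category,
)
from exprqc.classifier import make_verdict
from exprqc.robust import CutPoint


def _cut(value, informative=True):
    return CutPoint(level=0.999, cut=value, informative=informative)


class TestEvidenceScores:
    def test_above_cut_scores_one(self):
        scores = evidence_scores({"221728_x_at": 0.9}, {"221728_x_at": _cut(0.389)})
        assert scores == {"221728_x_at": 1}

    def test_tie_scores_zero(self):
        scores = evidence_scores({"p": 0.389}, {"p": _cut(0.389)})
        assert scores == {"p": 0}

    def test_missing_value_scores_zero(self):
        assert evidence_scores({"p": np.nan}, {"p": _cut(0.0)}) == {"p": 0}

    def test_non_informative_cut_scores_zero(self):
        assert evidence_scores({"p": 5.0}, {"p": _cut(0.0, informative=False)}) == {
            "p": 0
        }

    def test_absent_cut_scores_zero(self):
        assert evidence_scores({"p": 5.0}, {}) == {"p": 0}


class TestCombineEvidence:
    def test_single_female_evidence(self):
        assert combine_evidence([1, 0, 0, 0]) == "female"

    def test_conflicting_evidence_unconfident(self):
        assert combine_evidence([1, 0, 0, 1]) == "unconfident"

    def test_no_evidence_unconfident(self):
        assert combine_evidence([0, 0, 0, 0]) == "unconfident"

    def test_truth_table_counts(self):
        outcomes = [
            combine_evidence(list(bits)) for bits in itertools.product((0, 1), repeat=4)
        ]
        assert outcomes.count("male") == 3
        assert outcomes.count("female") == 3
        assert outcomes.count("unconfident") == 10

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            combine_evidence([0, 2, 0, 0])


class TestVerdict:
    @pytest.mark.parametrize(
        "predicted,annotated,expected",
        [
            ("female", "male", "misclassified"),
            ("female", "female", "correct"),
            ("unconfident", "male", "unconfident"),
            ("male", "unknown", "unannotated"),
            ("unconfident", "unknown", "unconfident"),
        ],
    )
    def test_categories(self, predicted, annotated, expected):
        assert verdict_category(predicted, annotated) == expected
        assert make_verdict("s", predicted, annotated).category == expected


class TestClassifyCohort:
    def test_single_injected_mislabel_found(self, mixed_cohort):
        matrix, annotation, truth = mixed_cohort
        assert len(truth.mislabeled) == 1
        report = classify_cohort(matrix, annotation, cohort_id="m")
        flagged = {
            v.sample_id for v in report.verdicts if v.category == "misclassified"
        }
        assert flagged == set(truth.mislabeled)

    def test_clean_cohort_all_correct(self, clean_cohort):
        matrix, annotation, _ = clean_cohort
        report = classify_cohort(matrix, annotation)
        assert report.counts["correct"] == report.n_samples

    def test_all_female_with_male_sample(self):
        # A male-generated sample labelled female in an all-female cohort is
        # flagged through Y-probe evidence.
        config = SyntheticConfig(n_samples=100, female_fraction=1.0, seed=13)
        matrix, annotation, _ = simulate_cohort(config)
        values = matrix.values.copy()
        rng = np.random.default_rng(0)
        for i, probe in enumerate(DEFAULT_PANEL):
            mu = 6.0 if probe.evidence_sex == "female" else 10.0
            values[i, 0] = rng.normal(mu, 0.4)
        from exprqc import ExpressionMatrix

        matrix = ExpressionMatrix(matrix.probe_ids, matrix.sample_ids, values)
        report = classify_cohort(matrix, annotation, cohort_id="bc")
        flagged = [v for v in report.verdicts if v.category == "misclassified"]
        assert [v.sample_id for v in flagged] == [matrix.sample_ids[0]]
        assert flagged[0].predicted_sex == "male"

    def test_deterministic(self, mixed_cohort):
        matrix, annotation, _ = mixed_cohort
        assert classify_cohort(matrix, annotation) == classify_cohort(
            matrix, annotation
        )

    def test_unknown_annotation_becomes_unannotated(self, clean_cohort):
        matrix, annotation, _ = clean_cohort
        labels = dict(annotation.labels)
        some = matrix.sample_ids[0]
        labels[some] = "unknown"
        report = classify_cohort(matrix, SexAnnotation(labels=labels))
        verdict = next(v for v in report.verdicts if v.sample_id == some)
        assert verdict.category == "unannotated"
        assert verdict.predicted_sex in ("female", "male")

    def test_no_panel_probe_is_hard_error(self, clean_cohort):
        matrix, annotation, _ = clean_cohort
        background_only = matrix.subset_probes(
            [p for p in matrix.probe_ids if p.startswith("bg_")]
        )
        with pytest.raises(ValueError, match="221728_x_at"):
            classify_cohort(background_only, annotation)

    def test_partial_panel_still_works(self, clean_cohort):
        matrix, annotation, _ = clean_cohort
        kept = [p for p in matrix.probe_ids if p != "221728_x_at"]
        report = classify_cohort(matrix.subset_probes(kept), annotation)
        assert report.counts["correct"] == report.n_samples

    def test_fixed_cut_deployment_mode(self, clean_cohort):
        matrix, annotation, _ = clean_cohort
        cfg = PipelineConfig(fixed_cuts=dict(DEFAULT_FIXED_CUTS))
        report = classify_cohort(matrix, annotation, config=cfg)
        assert report.counts["correct"] == report.n_samples

    def test_scatter_geometry(self, clean_cohort):
        matrix, annotation, _ = clean_cohort
        detail = classify_cohort_detailed(matrix, annotation)
        x, y = detail.scatter_coordinates(DEFAULT_PANEL)
        for j, verdict in enumerate(detail.report.verdicts):
            if verdict.annotated_sex == "female":
                assert x[j] > 0.7 and y[j] < 0.3  # near (1, 0)
            else:
                assert x[j] < 0.3 and y[j] > 0.7  # near (0, 1)


class TestMultiCohort:
    def test_pooled_single_sex_cohorts(self):
        # One mixed cohort provides the pooled scale; the all-female cohort
        # is then classifiable.
        mixed_cfg = SyntheticConfig(n_samples=120, seed=21, cohort_id="MIX")
        female_cfg = SyntheticConfig(
            n_samples=80, female_fraction=1.0, seed=22, cohort_id="FEM",
            mislabel_rate=1 / 80,
        )
        cohorts = []
        truths = {}
        for cfg in (mixed_cfg, female_cfg):
            matrix, annotation, truth = simulate_cohort(cfg)
            cohorts.append((cfg.cohort_id, matrix, annotation))
            truths[cfg.cohort_id] = truth
        reports = {r.cohort_id: r for r in classify_cohorts(cohorts)}
        fem = reports["FEM"]
        flagged = {v.sample_id for v in fem.verdicts if v.category == "misclassified"}
        assert flagged == set(truths["FEM"].mislabeled)
        assert reports["MIX"].counts["misclassified"] == 0

    def test_summary_arithmetic(self):
        cohorts = []
        for seed in (31, 32):
            cfg = SyntheticConfig(n_samples=60, seed=seed, cohort_id=f"C{seed}")
            matrix, annotation, _ = simulate_cohort(cfg)
            cohorts.append((cfg.cohort_id, matrix, annotation))
        reports = classify_cohorts(cohorts)
        summary = summarize_reports(reports)
        assert summary["n_samples"] == sum(r.n_samples for r in reports)
        assert summary["counts"]["correct"] == sum(
            r.counts["correct"] for r in reports
        )
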