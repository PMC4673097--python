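import numpy as np
import pytest

from exprqc import (
    SampleVerdict,
    SyntheticConfig,
    cross_check_duplicates,
    find_duplicates,
    gap_split,
    pairwise_correlations,
    simulate_cohort,
    top_variance_probes,
)
from exprqc.duplicates import duplicate_groups
from tests.conftest import make_matrix


class TestTopVarianceProbes:
    def test_k_at_least_probe_count_returns_all(self, small_matrix):
        assert set(top_variance_probes(small_matrix, 10)) == set(small_matrix.probe_ids)

    def test_constant_probe_ranked_last(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(4, 10))
        values[2] = 3.14
        matrix = make_matrix(values)
        ranked = top_variance_probes(matrix, 4)
        assert ranked[-1] == "p2"

    def test_constructed_variances(self):
        rng = np.random.default_rng(1)
        n = 50
        values = np.vstack([
            np.sqrt(v) * rng.standard_normal(n) for v in [1.0, 4.0, 9.0, 16.0]
        ])
        matrix = make_matrix(values)
        assert top_variance_probes(matrix, 2) == ["p3", "p2"]

    def test_missing_value_probe_excluded(self):
        values = np.array([[1.0, 2.0, 3.0], [np.nan, 100.0, -100.0]])
        matrix = make_matrix(values)
        assert top_variance_probes(matrix, 2) == ["p0"]

    def test_invalid_k(self, small_matrix):
        with pytest.raises(ValueError):
            top_variance_probes(small_matrix, 0)


class TestPairwiseCorrelations:
    def test_duplicate_column_high_r(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=500)
        values = np.column_stack([base, base + rng.normal(0, 0.01, 500),
                                  rng.normal(size=500)])
        matrix = make_matrix(values)
        pairs = {(a, b): r for a, b, r in pairwise_correlations(matrix)}
        assert pairs[("s0", "s1")] > 0.99
        assert abs(pairs[("s0", "s2")]) < 0.2

    def test_inverted_vector(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        matrix = make_matrix(np.column_stack([base, -base]))
        (_, _, r), = pairwise_correlations(matrix)
        assert r == pytest.approx(-1.0)

    def test_independent_vectors_mostly_uncorrelated(self):
        rng = np.random.default_rng(3)
        matrix = make_matrix(rng.normal(size=(1000, 12)))
        rs = [abs(r) for _, _, r in pairwise_correlations(matrix)]
        assert np.mean(np.array(rs) < 0.1) >= 0.99

    def test_zero_variance_sample_excluded(self, caplog):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(10, 3))
        values[:, 1] = 7.0
        matrix = make_matrix(values)
        with caplog.at_level("WARNING"):
            pairs = pairwise_correlations(matrix)
        names = {s for a, b, _ in pairs for s in (a, b)}
        assert "s1" not in names

    def test_pair_count(self):
        rng = np.random.default_rng(5)
        matrix = make_matrix(rng.normal(size=(5, 6)))
        assert len(pairwise_correlations(matrix)) == 6 * 5 // 2

    def test_requires_enough_probes(self):
        with pytest.raises(ValueError):
            pairwise_correlations(make_matrix(np.ones((2, 4))))


class TestGapSplit:
    def test_dominant_gap(self):
        index, threshold = gap_split([0.99, 0.50, 0.45, 0.40], r_min=0.95)
        assert index == 1
        assert 0.5 < threshold < 0.99

    def test_all_below_r_min(self):
        assert gap_split([0.9, 0.5, 0.3], r_min=0.95) == (None, None)

    def test_reconstructed_duplicate_vs_control_levels(self):
        # Duplicates around 0.990-0.993 against dense re-run controls in
        # 0.910-0.987 and lower background correlations.
        controls = np.linspace(0.986, 0.910, 40)
        background = np.linspace(0.6, 0.2, 100)
        ordered = np.concatenate([[0.993, 0.990], controls, background])
        index, threshold = gap_split(ordered, r_min=0.95, max_frac=0.1)
        assert index == 2
        assert 0.986 < threshold < 0.990

    def test_max_frac_still_allows_one_pair(self):
        # 4 pairs with max_frac 0.1 -> the limit max(1, 0.4) keeps the
        # single top pair admissible.
        index, _ = gap_split([0.99, 0.50, 0.45, 0.40], r_min=0.95, max_frac=0.1)
        assert index == 1

    def test_literal_rule_recovered(self):
        ordered = [0.8, 0.3, 0.25, 0.2]
        assert gap_split(ordered, r_min=0.95)[0] is None
        index, _ = gap_split(ordered, r_min=-1.0, max_frac=1.0)
        assert index == 1

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            gap_split([0.1, 0.9])

    def test_requires_two_values(self):
        with pytest.raises(ValueError):
            gap_split([0.5])


class TestFindDuplicates:
    def test_injected_duplicates_recovered(self):
        config = SyntheticConfig(
            n_samples=40, n_background_probes=300, n_duplicates=2, seed=17
        )
        matrix, _, truth = simulate_cohort(config)
        report = find_duplicates(matrix, k=300)
        found = {frozenset(p[:2]) for p in report.pairs}
        assert found == {frozenset(p) for p in truth.duplicate_pairs}

    def test_no_duplicates_empty(self):
        config = SyntheticConfig(n_samples=40, n_background_probes=300, seed=18)
        matrix, _, _ = simulate_cohort(config)
        report = find_duplicates(matrix, k=300)
        assert report.pairs == ()

    def test_sample_order_invariance(self):
        config = SyntheticConfig(
            n_samples=30, n_background_probes=200, n_duplicates=1, seed=19
        )
        matrix, _, _ = simulate_cohort(config)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(matrix.sample_ids))
        shuffled = matrix.subset_samples([matrix.sample_ids[j] for j in perm])
        a = find_duplicates(matrix, k=200)
        b = find_duplicates(shuffled, k=200)
        assert {p[:2] for p in a.pairs} == {p[:2] for p in b.pairs}

    def test_pairs_sorted_descending(self):
        config = SyntheticConfig(
            n_samples=40, n_background_probes=200, n_duplicates=3, seed=20
        )
        matrix, _, _ = simulate_cohort(config)
        report = find_duplicates(matrix, k=200)
        rs = [p[2] for p in report.pairs]
        assert rs == sorted(rs, reverse=True)


class TestCrossCheck:
    @staticmethod
    def _verdicts(n_mis, prefix="s"):
        return [
            SampleVerdict(f"{prefix}{i}", "male", "female", "misclassified")
            for i in range(n_mis)
        ]

    def test_headline_arithmetic(self):
        verdicts = self._verdicts(54)
        pairs = [(f"s{i}", f"x{i}", 0.99) for i in range(9)]
        result = cross_check_duplicates(pairs, verdicts)
        assert result["n_misclassified"] == 54
        assert result["n_explained_by_duplicates"] == 9
        assert result["pct_explained"] == 16.7

    def test_no_duplicates(self):
        result = cross_check_duplicates([], self._verdicts(5))
        assert result["pct_explained"] == 0.0

    def test_all_explained(self):
        verdicts = self._verdicts(3)
        pairs = [(f"s{i}", f"y{i}", 0.995) for i in range(3)]
        assert cross_check_duplicates(pairs, verdicts)["pct_explained"] == 100.0


def test_duplicate_groups_components():
    pairs = [("a", "b", 0.99), ("b", "c", 0.99), ("x", "y", 0.99)]
    assert duplicate_groups(pairs) == [("a", "b", "c"), ("x", "y")]
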