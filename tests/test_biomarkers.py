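import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from tscpath import (
    CohortConfig,
    DeltaTscProfile,
    ResponseTable,
    biomarker_profile_matrix,
    cluster_biomarker_profiles,
    compare_biomarker_profiles,
    concordance_index,
    generate_cohort,
    is_defined,
    pathway_biomarkers,
    permutation_significance,
    univariate_gene_biomarkers,
)

from conftest import make_expression


def brute_force_cindex(scores, labels):
    """Direct enumeration over all (positive, negative) pairs."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConcordanceIndex:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.1, 0.2, 0.9], [0, 0, 1], 1.0),
            ([0.9, 0.2, 0.1], [0, 0, 1], 0.0),
            ([1, 2, 2, 3], [0, 1, 0, 1], 0.875),  # tied pair counts 0.5
        ],
    )
    def test_hand_examples(self, scores, labels, expected):
        assert concordance_index(scores, labels) == pytest.approx(expected)

    def test_empty_class_returns_undefined(self):
        assert not is_defined(concordance_index([1.0, 2.0], [1, 1]))

    def test_matches_brute_force_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 60))
            scores = rng.choice([0.0, 0.5, 1.0, 2.0, 3.7], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            assert concordance_index(scores, labels) == pytest.approx(
                brute_force_cindex(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_auc(self, rng):
        scores = rng.standard_normal(80)
        labels = rng.integers(0, 2, size=80)
        assert concordance_index(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        scores=st.lists(
            st.floats(-100, 100, allow_nan=False).map(lambda x: round(x, 3)),
            min_size=4,
            max_size=40,
        ),
        data=st.data(),
    )
    def test_complement_and_monotone_invariance(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n)
        )
        if sum(labels) in (0, n):
            return
        scores = np.asarray(scores)
        c = concordance_index(scores, labels)
        if len(np.unique(scores)) == n:  # complement identity needs no ties
            assert concordance_index(-scores, labels) == pytest.approx(
                1 - c, abs=1e-12
            )
        # any strictly increasing transform preserves the pair ordering
        assert concordance_index(
            np.exp(scores / 50) + 3 * scores, labels
        ) == pytest.approx(c, abs=1e-12)


class TestPermutationSignificance:
    def test_exhaustive_perfect_separation_is_zero(self):
        # all 6 labelings of 2 positives among 4; none beats observed C = 1
        value = permutation_significance(
            [1, 2, 3, 4], [0, 0, 1, 1], mode="exhaustive"
        )
        assert value == 0.0

    def test_degenerate_equal_scores_is_zero(self):
        # every labeling gives C = 0.5; strict inequality never holds
        value = permutation_significance([2.0] * 6, [0, 0, 0, 1, 1, 1], seed=0)
        assert value == 0.0

    def test_monte_carlo_tracks_exhaustive(self, rng):
        scores = rng.standard_normal(8)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        exact = permutation_significance(scores, labels, mode="exhaustive")
        mc = permutation_significance(
            scores, labels, n_perm=4000, seed=1, mode="montecarlo"
        )
        assert mc == pytest.approx(exact, abs=0.05)

    def test_rejects_bad_nperm(self):
        with pytest.raises(ValueError):
            permutation_significance([1, 2], [0, 1], n_perm=0)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            permutation_significance([1, 2], [1, 1])


def labels_for(n, response, arm="combination", er="ER+"):
    return ResponseTable(
        tuple(f"S{i + 1}" for i in range(n)),
        np.asarray(response),
        (arm,) * n,
        (er,) * n,
    )


class TestUnivariateGeneBiomarkers:
    def test_single_gene_matrix_gives_one_result(self, rng):
        expr = make_expression(rng.standard_normal((1, 10)))
        labels = labels_for(10, [1, 0] * 5)
        res = univariate_gene_biomarkers(expr, labels, n_perm=50, seed=0)
        assert len(res) == 1
        assert res[0].n_samples == 10

    def test_mean_shifted_gene_ranks_first(self, rng):
        n = 40
        values = rng.standard_normal((20, n))
        response = np.array([1] * 20 + [0] * 20)
        values[7, response == 1] += 3.0  # strong shift on one gene
        expr = make_expression(values)
        res = univariate_gene_biomarkers(
            expr, labels_for(n, response), n_perm=100, seed=0
        )
        assert res[0].feature_name == "G8"
        assert res[0].cindex > 0.9
        assert res[0].perm_significance <= 0.05

    def test_sorted_descending_with_bh_column(self, rng):
        expr = make_expression(rng.standard_normal((15, 20)))
        res = univariate_gene_biomarkers(
            expr, labels_for(20, [1, 0] * 10), n_perm=50, seed=1
        )
        cs = [r.cindex for r in res]
        assert cs == sorted(cs, reverse=True)
        assert all(0 <= r.bh_adjusted <= 1 for r in res)
        assert all(r.bh_adjusted >= r.perm_significance - 1e-12 for r in res)

    def test_group_with_empty_class_skipped_with_warning(self, rng, caplog):
        expr = make_expression(rng.standard_normal((5, 6)))
        labels = labels_for(6, [1] * 6)
        with caplog.at_level(logging.WARNING):
            res = univariate_gene_biomarkers(
                expr, labels, group=("combination", "ER+"), n_perm=50
            )
        assert res == []
        assert any("skipped" in rec.message for rec in caplog.records)


class TestPathwayBiomarkers:
    def make_profile(self, delta, n):
        return DeltaTscProfile(
            tuple(f"S{i + 1}" for i in range(n)),
            tuple(f"PW{j}" for j in range(np.asarray(delta).shape[1])),
            np.asarray(delta, float),
        )

    def test_constant_column_gives_half(self):
        n = 8
        response = [1, 0] * 4
        delta = np.zeros((n, 1)) + 0.3
        res = pathway_biomarkers(
            self.make_profile(delta, n), labels_for(n, response), n_perm=20
        )
        assert res[0].cindex == pytest.approx(0.5)

    def test_label_matching_column_gives_one(self):
        n = 8
        response = [1, 0] * 4
        delta = np.asarray(response, float)[:, None]
        res = pathway_biomarkers(
            self.make_profile(delta, n), labels_for(n, response), n_perm=20
        )
        assert res[0].cindex == pytest.approx(1.0)

    def test_undefined_column_excluded_with_warning(self, caplog):
        n = 6
        response = [1, 0] * 3
        delta = np.column_stack(
            [np.full(n, np.nan), np.linspace(-1, 1, n)]
        )
        with caplog.at_level(logging.WARNING):
            res = pathway_biomarkers(
                self.make_profile(delta, n), labels_for(n, response), n_perm=20
            )
        assert [r.feature_name for r in res] == ["PW1"]
        assert any("undefined" in rec.message for rec in caplog.records)

    def test_undefined_entries_pairwise_dropped(self):
        n = 8
        response = [1, 1, 1, 1, 0, 0, 0, 0]
        col = np.array([0.9, 0.8, np.nan, 0.7, 0.1, np.nan, 0.2, 0.0])
        res = pathway_biomarkers(
            self.make_profile(col[:, None], n), labels_for(n, response), n_perm=20
        )
        assert res[0].cindex == pytest.approx(1.0)
        assert res[0].n_samples == n


class TestCompareBiomarkerProfiles:
    def test_self_correlation_is_one(self):
        vec = {f"P{i}": v for i, v in enumerate([0.3, 0.9, 0.1, 0.7, 0.5])}
        assert compare_biomarker_profiles(vec, vec) == pytest.approx(1.0)

    def test_reversed_ranking_is_minus_one(self):
        keys = [f"P{i}" for i in range(6)]
        a = {k: float(i) for i, k in enumerate(keys)}
        b = {k: float(-i) for i, k in enumerate(keys)}
        assert compare_biomarker_profiles(a, b) == pytest.approx(-1.0)

    def test_too_few_shared_pathways_undefined(self):
        a = {"P1": 0.5, "P2": 0.6, "P3": 0.7}
        b = {"P3": 0.1, "P4": 0.2}
        assert not is_defined(compare_biomarker_profiles(a, b))

    def test_independent_null_profiles_weakly_correlated(self, rng):
        hits = 0
        reps = 60
        for _ in range(reps):
            keys = [f"P{i}" for i in range(100)]
            a = dict(zip(keys, rng.uniform(0, 1, 100)))
            b = dict(zip(keys, rng.uniform(0, 1, 100)))
            if abs(compare_biomarker_profiles(a, b)) < 0.3:
                hits += 1
        assert hits >= 0.95 * reps

    def test_profile_matrix_and_clustering(self, rng):
        keys = [f"P{i}" for i in range(30)]
        profiles = {
            f"group{k}": dict(zip(keys, rng.uniform(0, 1, 30))) for k in range(4)
        }
        names, mat = biomarker_profile_matrix(profiles)
        assert mat.shape == (4, 4)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        np.testing.assert_allclose(mat, mat.T)
        names2, mat2, newick = cluster_biomarker_profiles(profiles)
        assert newick.endswith(";")
        assert all(name in newick for name in names2)


def test_injected_pathways_outrank_null_pathways():
    """Covariance signal planted by the generator must surface at the top of
    the pathway biomarker ranking."""
    cfg = CohortConfig(
        n_per_arm=40,
        pcr_rate_by_arm={"combination": 0.5},
        n_genes=600,
        n_pathways=30,
        n_signal_pathways=6,
        effect_size=3.0,
        seed=17,
    )
    from tscpath import delta_tsc_profile

    expr, labels, sets, truth = generate_cohort(cfg)
    profile = delta_tsc_profile(expr, labels, sets)
    res = pathway_biomarkers(profile, labels, n_perm=30, seed=2)
    rank = {r.feature_name: i for i, r in enumerate(res)}
    signal = [rank[n] for n in truth.signal_pathway_names]
    null = [rank[r.feature_name] for r in res
            if r.feature_name not in truth.signal_pathway_names]
    assert np.mean(signal) < np.mean(null)
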