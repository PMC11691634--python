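"""Cargo statistics: Venn algebra, ORA against enumeration oracles, BH,
the miRNA count stack and the PCA projection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from evseek.cargo import (
    bh_adjust,
    cpm_normalize,
    differential_test,
    filter_low_expression,
    hypergeom_enrichment,
    pca_projection,
    sharing_percentage,
    venn_partition,
)
from evseek.fixtures import load_fixture
from evseek.simulate import CargoTruth, generate_mirna_counts


class TestVennPartition:
    def test_reference_fixture_counts(self):
        set_a, set_b = load_fixture("proteome_overlap")
        part = venn_partition(set_a, set_b)
        assert (part.only_a, part.shared, part.only_b) == (239, 285, 127)

    def test_identical_sets(self):
        part = venn_partition({"a", "b"}, {"a", "b"})
        assert (part.only_a, part.shared, part.only_b) == (0, 2, 0)

    def test_disjoint_sets(self):
        part = venn_partition({"a", "b", "c"}, {"d", "e", "f", "g"})
        assert (part.only_a, part.shared, part.only_b) == (3, 0, 4)

    @given(
        st.sets(st.integers(0, 50)).map(lambda s: {str(x) for x in s}),
        st.sets(st.integers(0, 50)).map(lambda s: {str(x) for x in s}),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_cells_disjoint_and_cover_union(self, a, b):
        part = venn_partition(a, b)
        cells = [set(part.ids_only_a), set(part.ids_shared), set(part.ids_only_b)]
        assert cells[0] | cells[1] | cells[2] == a | b
        for x, y in itertools.combinations(cells, 2):
            assert not x & y
        assert (part.only_a, part.shared, part.only_b) == tuple(len(c) for c in cells)


class TestSharingPercentage:
    def test_reference_fixture_sharing(self):
        part = venn_partition(*load_fixture("proteome_overlap"))
        assert sharing_percentage(part, "b") == pytest.approx(100 * 285 / 412, abs=1e-9)
        assert round(sharing_percentage(part, "b")) == 69

    def test_nothing_shared(self):
        assert sharing_percentage(venn_partition({"a"}, {"b"}), "b") == 0.0

    def test_everything_shared(self):
        assert sharing_percentage(venn_partition({"a"}, {"a"}), "a") == 100.0

    def test_empty_side_errors(self):
        with pytest.raises(ValueError):
            sharing_percentage(venn_partition({"a"}, set()), "b")


class TestHypergeomEnrichment:
    def test_study_equals_population_gives_p_one(self):
        population = {f"g{i}" for i in range(10)}
        result, _ = hypergeom_enrichment(
            population, population, {"t": {f"g{i}" for i in range(4)}}
        )
        assert result.loc["t", "p_value"] == pytest.approx(1.0)
        assert result.loc["t", "k"] == result.loc["t", "K"]

    def test_known_small_case(self):
        # N=10, K=4, n=5, k=3 -> (C(4,3)C(6,2)+C(4,4)C(6,1))/C(10,5) = 66/252
        population = {f"g{i}" for i in range(10)}
        term = {"g0", "g1", "g2", "g3"}
        study = {"g0", "g1", "g2", "g4", "g5"}
        result, _ = hypergeom_enrichment(study, population, {"t": term})
        assert result.loc["t", "p_value"] == pytest.approx(66 / 252, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_enumeration(self, seed):
        """p equals the fraction of all C(N, n) draws with >= k term members."""
        rng = np.random.default_rng(seed)
        N = int(rng.integers(5, 13))
        population = [f"g{i}" for i in range(N)]
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        term = set(population[:K])
        study = set(rng.choice(population, size=n, replace=False))
        k = len(term & study)
        hits = sum(
            1 for draw in itertools.combinations(population, n)
            if len(term & set(draw)) >= k
        )
        expected = hits / math.comb(N, n)
        result, _ = hypergeom_enrichment(study, set(population), {"t": term})
        assert result.loc["t", "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_p_decreases_in_k(self):
        # fix N, K, n; larger observed overlap must shrink the upper-tail p
        ps = [float(stats.hypergeom.sf(k - 1, 20, 8, 10)) for k in range(0, 9)]
        assert all(b < a for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_empty_terms_skipped_and_reported(self):
        population = {"g1", "g2"}
        result, skipped = hypergeom_enrichment({"g1"}, population, {"t": {"zz"}})
        assert skipped == ["t"]
        assert result.empty

    def test_study_outside_population_is_hard_error(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeom_enrichment({"x"}, {"g1"}, {"t": {"g1"}})


class TestBHAdjust:
    def _stepup_oracle(self, p):
        """Literal BH definition: q_(i) = min_{j>=i} (m/j) p_(j), capped at 1."""
        p = np.asarray(p, float)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        q_sorted = np.empty(m)
        running = math.inf
        for rank in range(m, 0, -1):
            running = min(running, m / rank * p[order[rank - 1]])
            q_sorted[rank - 1] = min(running, 1.0)
        q = np.empty(m)
        q[order] = q_sorted
        return q

    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_all_equal_ps(self):
        assert bh_adjust([0.2] * 5) == pytest.approx([0.2] * 5)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_stepup_definition(self, p):
        assert bh_adjust(p) == pytest.approx(self._stepup_oracle(p), rel=1e-12, abs=1e-12)

    def test_rejection_set_matches_classic_stepup(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.uniform(size=30)
            alpha = 0.1
            q = bh_adjust(p)
            # classic step-up: largest i with p_(i) <= i/m * alpha; reject 1..i
            order = np.argsort(p)
            thresholds = (np.arange(1, 31) / 30) * alpha
            below = np.nonzero(p[order] <= thresholds)[0]
            classic = set(order[: below.max() + 1]) if below.size else set()
            assert set(np.nonzero(q <= alpha)[0]) == classic

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCountStack:
    def _counts(self):
        return pd.DataFrame(
            {"s1": [1, 1], "s2": [10, 30]}, index=["m1", "m2"]
        )

    def test_cpm_hand_case_and_column_sum(self):
        cpm = cpm_normalize(self._counts())
        assert cpm["s1"].tolist() == [5e5, 5e5]
        assert cpm.sum(axis=0).tolist() == pytest.approx([1e6, 1e6])

    def test_cpm_matches_per_entry_oracle(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 100, size=(20, 6)))
        counts.iloc[0] += 1  # no zero library
        cpm = cpm_normalize(counts)
        for j in counts.columns:
            lib = counts[j].sum()
            assert cpm[j].to_numpy() == pytest.approx(1e6 * counts[j].to_numpy() / lib)

    def test_zero_library_errors(self):
        counts = pd.DataFrame({"s1": [0, 0], "s2": [1, 2]})
        with pytest.raises(ValueError):
            cpm_normalize(counts)

    def test_all_zero_feature_filtered(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [0, 7], "s3": [0, 2], "s4": [0, 9]})
        keep = filter_low_expression(counts, min_cpm=1.0, min_samples=2)
        assert not keep.iloc[0]

    def test_min_cpm_zero_retains_everything(self):
        counts = pd.DataFrame({"s1": [0, 5], "s2": [1, 7]})
        assert filter_low_expression(counts, min_cpm=0.0, min_samples=2).all()

    def test_filter_matches_row_scan_oracle(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.poisson(3, size=(50, 8)))
        counts.iloc[0] += 1
        keep = filter_low_expression(counts, min_cpm=50_000, min_samples=3)
        cpm = 1e6 * counts / counts.sum(axis=0)
        for i in counts.index:
            assert keep[i] == ((cpm.loc[i] >= 50_000).sum() >= 3)


class TestDifferentialTest:
    def _frame(self, rows, samples=("a1", "a2", "a3", "b1", "b2", "b3")):
        counts = pd.DataFrame(rows, columns=samples)
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
        return counts, groups

    def test_identical_groups_give_zero_stat_p_one(self):
        counts, groups = self._frame([[50, 50, 50, 50, 50, 50], [9, 9, 9, 9, 9, 9]])
        result = differential_test(counts, groups, min_samples=3)
        assert result["statistic"].tolist() == pytest.approx([0.0, 0.0])
        assert result["p_value"].tolist() == pytest.approx([1.0, 1.0])

    def test_matches_welch_closed_form(self):
        counts, groups = self._frame(
            [[40, 55, 62, 10, 14, 9], [100, 100, 100, 100, 100, 100]]
        )
        result = differential_test(counts, groups, min_samples=3, pseudocount=0.5)
        log_cpm = np.log2(1e6 * counts / counts.sum(axis=0) + 0.5)
        a, b = log_cpm.iloc[0, :3].to_numpy(), log_cpm.iloc[0, 3:].to_numpy()
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert result.iloc[0]["statistic"] == pytest.approx(t, rel=1e-12)
        assert result.iloc[0]["p_value"] == pytest.approx(p, rel=1e-12)
        assert result.iloc[0]["log2_fold_change"] == pytest.approx(b.mean() - a.mean())

    def test_filtered_features_carry_no_p(self):
        counts, groups = self._frame([[0, 0, 0, 0, 0, 1], [50, 60, 70, 40, 50, 60]])
        result = differential_test(counts, groups, min_cpm=1000.0, min_samples=3)
        assert not result.iloc[0]["passed_filter"]
        assert math.isnan(result.iloc[0]["p_value"])

    def test_label_permutation_keeps_p_uniform(self):
        """Permuting group labels on null data leaves p-values ~ U(0,1)."""
        truth = CargoTruth(
            de_mirna_ids=[], log2_fold_changes=[], dispersion=0.1,
            library_sizes=[1_000_000] * 10, seed=77,
        )
        counts, groups = generate_mirna_counts(400, 5, truth)
        rng = np.random.default_rng(7)
        permuted = pd.Series(
            rng.permutation(groups.to_numpy()), index=groups.index, name="group"
        )
        result = differential_test(counts, permuted)
        p = result["p_value"].dropna().to_numpy()
        ks = stats.kstest(p, "uniform")
        assert ks.pvalue > 0.01

    def test_single_sample_group_rejected(self):
        counts = pd.DataFrame({"a1": [5], "a2": [6], "b1": [7]})
        groups = pd.Series(["A", "A", "B"], index=counts.columns)
        with pytest.raises(ValueError):
            differential_test(counts, groups)


class TestPCAProjection:
    def test_pc1_separates_two_clusters(self):
        rng = np.random.default_rng(0)
        cluster = rng.normal(0, 0.1, size=(4, 20))
        X = pd.DataFrame(np.vstack([cluster, cluster + 5.0]))
        scores, fractions = pca_projection(X, n_components=2)
        first_half, second_half = scores.iloc[:4, 0], scores.iloc[4:, 0]
        assert first_half.max() < second_half.min() or second_half.max() < first_half.min()
        assert fractions[0] == max(fractions)
        assert fractions.sum() <= 1.0 + 1e-12

    def test_rotation_invariant_variance_fractions(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 6)) @ np.diag([5, 4, 3, 2, 1, 0.5])
        Q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
        _, f1 = pca_projection(pd.DataFrame(X), n_components=3)
        _, f2 = pca_projection(pd.DataFrame(X @ Q), n_components=3)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_duplicating_samples_keeps_fractions(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(6, 5))
        _, f1 = pca_projection(pd.DataFrame(X), n_components=2)
        _, f2 = pca_projection(pd.DataFrame(np.vstack([X, X])), n_components=2)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(8, 4)))
        s1, _ = pca_projection(X, 2)
        s2, _ = pca_projection(X.copy(), 2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pca_projection(pd.DataFrame(np.ones((4, 3))), 1)
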