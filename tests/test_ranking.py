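"""Final loading-based ranking and the univariate / enrichment comparators."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snvda.ranking import (
    allele_count_table,
    ase_enrichment,
    final_rank,
    fisher_exact_2x4,
    friedman_compare,
    wilcoxon_af,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# final_rank
# ---------------------------------------------------------------------------


class TestFinalRank:
    def test_separable_feature_ranks_first(self, separable_matrix):
        r = final_rank(separable_matrix, 3, with_univariate=False)
        assert len(r) == 3
        assert r.iloc[0]["snv_key"] == separable_matrix.values.index[0]
        assert list(r["rank"]) == [1, 2, 3]

    def test_abs_loading_nonincreasing(self, random_na_matrix):
        r = final_rank(random_na_matrix, 8, with_univariate=False)
        seq = r["abs_loading"].to_numpy()
        assert np.all(np.diff(seq) <= 1e-15)

    def test_sample_order_invariance(self, separable_matrix):
        m = separable_matrix
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_samples)
        m2 = make_matrix(
            m.values.to_numpy()[:, perm],
            labels=[m.labels.iloc[i] for i in perm],
        )
        r1 = final_rank(m, 5, with_univariate=False)
        r2 = final_rank(m2, 5, with_univariate=False)
        assert list(r1["snv_key"]) == list(r2["snv_key"])
        assert r1["abs_loading"].to_numpy() == pytest.approx(
            r2["abs_loading"].to_numpy()
        )

    def test_univariate_columns_do_not_reorder(self, separable_matrix):
        r1 = final_rank(separable_matrix, 4, with_univariate=False)
        r2 = final_rank(separable_matrix, 4, with_univariate=True)
        assert list(r1["snv_key"]) == list(r2["snv_key"])
        assert {"fisher_p", "wilcoxon_p"} <= set(r2.columns)


# ---------------------------------------------------------------------------
# Fisher 2 x 4
# ---------------------------------------------------------------------------


def _fisher_bruteforce_2xc(table):
    """Enumerate every margin-preserving 2 x c table by brute force."""
    t = np.asarray(table, dtype=int)
    col = t.sum(axis=0)
    r1 = t[0].sum()
    idx = [range(c + 1) for c in col]
    obs_num = 1
    for j in range(len(col)):
        obs_num *= comb(int(col[j]), int(t[0, j]))
    total = 0
    for x in itertools.product(*idx):
        if sum(x) != r1:
            continue
        num = 1
        for j, xj in enumerate(x):
            num *= comb(int(col[j]), xj)
        if num <= obs_num:
            total += num
    return total / comb(int(col.sum()), int(r1))


class TestFisher2x4:
    def test_identical_rows_give_p_one(self):
        assert fisher_exact_2x4([[3, 2, 1, 0], [3, 2, 1, 0]]) == pytest.approx(1.0)

    def test_disjoint_alleles_match_enumeration(self):
        t = [[5, 0, 0, 0], [0, 5, 0, 0]]
        assert fisher_exact_2x4(t) == pytest.approx(_fisher_bruteforce_2xc(t), abs=1e-12)

    def test_two_column_tables_match_classical_2x2(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            t22 = rng.integers(0, 8, size=(2, 2))
            if t22.sum() == 0:
                continue
            t = np.zeros((2, 4), dtype=int)
            t[:, :2] = t22
            _or, p = stats.fisher_exact(t22, alternative="two-sided")
            assert fisher_exact_2x4(t) == pytest.approx(p, abs=1e-10)

    def test_random_2x4_matches_bruteforce(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            t = rng.integers(0, 4, size=(2, 4))
            if t.sum() == 0:
                continue
            assert fisher_exact_2x4(t) == pytest.approx(
                _fisher_bruteforce_2xc(t), abs=1e-12
            )

    def test_all_zero_table_raises(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_2x4([[0, 0, 0, 0], [0, 0, 0, 0]])

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            t = rng.integers(0, 6, size=(2, 4))
            if t.sum() == 0:
                continue
            p = fisher_exact_2x4(t)
            assert 0.0 < p <= 1.0


class TestAlleleCountTable:
    def test_detectability_rules(self):
        # AF 0 -> ref only; AF 1 -> alt only; 0<AF<1 -> both; NA -> neither
        vals = np.array([[0.0, 1.0, 0.5, np.nan]])
        m = make_matrix(vals, labels=["group_A", "group_A", "group_B", "group_B"])
        t = allele_count_table(m, m.values.index[0])  # ref C, alt T
        assert t.loc["group_A", "C"] == 1  # AF 0 sample
        assert t.loc["group_A", "T"] == 1  # AF 1 sample
        assert t.loc["group_B", "C"] == 1 and t.loc["group_B", "T"] == 1
        assert t.to_numpy().sum() == 4
        assert t[["A", "G"]].to_numpy().sum() == 0


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------


def _ranksum_exact_bruteforce(a, b):
    """Two-sided p by enumerating all assignments of the pooled values."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n_a].sum()
    ws = []
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ws.append(ranks[list(idx)].sum())
    ws = np.asarray(ws)
    mu = ws.mean()
    p = np.mean(np.abs(ws - mu) >= abs(w_obs - mu) - 1e-12)
    return float(p)


class TestWilcoxon:
    def test_identical_distributions_give_p_one(self):
        assert wilcoxon_af([0.3, 0.3, 0.3], [0.3, 0.3]) == 1.0

    def test_small_sample_matches_enumeration(self):
        a = [0.9, 0.8, 0.85]
        b = [0.1, 0.2, 0.15]
        expected = _ranksum_exact_bruteforce(np.array(a), np.array(b))
        assert wilcoxon_af(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(2 / 20)  # 2 of C(6,3)=20 assignments

    def test_zeros_included_na_excluded(self):
        a = [0.0, 0.0, 0.5, np.nan]
        b = [0.0, 0.6, 0.7]
        p = wilcoxon_af(a, b)
        # same as dropping the NA by hand
        assert p == wilcoxon_af([0.0, 0.0, 0.5], b)

    def test_fully_na_group_raises(self):
        with pytest.raises(ValueError, match="no observed"):
            wilcoxon_af([np.nan, np.nan], [0.1, 0.2])

    def test_random_exact_cases_match_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a = rng.normal(size=rng.integers(3, 6))
            b = rng.normal(size=rng.integers(3, 6))
            expected = _ranksum_exact_bruteforce(a, b)
            assert wilcoxon_af(a, b) == pytest.approx(expected, abs=1e-9)


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------


class TestFriedman:
    def test_identical_rankings_give_zero(self):
        stat, p = friedman_compare([[1, 2, 3, 4]] * 3)
        assert stat == 0.0 and p == 1.0

    def test_closed_form_on_toy_table(self):
        rankings = [[1, 2, 3, 4], [2, 1, 4, 3], [1, 3, 2, 4]]
        stat, p = friedman_compare(rankings)
        data = np.asarray(rankings).T
        ranks = np.apply_along_axis(stats.rankdata, 1, data.astype(float))
        n, k = ranks.shape
        rj = ranks.sum(axis=0)
        expected = 12.0 / (n * k * (k + 1)) * (rj**2).sum() - 3 * n * (k + 1)
        assert stat == pytest.approx(expected)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            data = rng.permuted(
                np.tile(np.arange(1, 9), (3, 1)), axis=1
            )  # 3 methods x 8 features
            expected = stats.friedmanchisquare(*data)
            stat, p = friedman_compare(data)
            assert stat == pytest.approx(expected.statistic)
            assert p == pytest.approx(expected.pvalue)

    def test_block_relabeling_invariance(self):
        rng = np.random.default_rng(5)
        rankings = np.array([[1, 2, 3, 4, 5], [2, 1, 5, 3, 4], [3, 1, 2, 5, 4]])
        perm = rng.permutation(5)
        s1, _ = friedman_compare(rankings)
        s2, _ = friedman_compare(rankings[:, perm])
        assert s1 == pytest.approx(s2)

    def test_too_small_inputs_raise(self):
        with pytest.raises(ValueError):
            friedman_compare([[1, 2, 3]])
        with pytest.raises(ValueError):
            friedman_compare([[1], [1]])


# ---------------------------------------------------------------------------
# ASE enrichment
# ---------------------------------------------------------------------------


def _ase_calls(sig_map, samples=("s1", "s2")):
    rows = []
    for gene, sigs in sig_map.items():
        for s, flag in zip(samples, sigs):
            rows.append({"gene": gene, "sample": s, "testable": True, "significant": flag})
    return pd.DataFrame(rows)


class TestAseEnrichment:
    def test_selected_equals_universe(self):
        calls = _ase_calls({"g1": (True, False), "g2": (False, False)})
        r = ase_enrichment(["g1", "g2"], ["g1", "g2"], calls, n_subsets=50, seed=0)
        assert r.fold == pytest.approx(1.0)
        assert r.p_value == 1.0

    def test_sampled_null_converges_to_exhaustive(self):
        # 6-gene universe, 2 selected: 15 possible subsets
        genes = [f"g{i}" for i in range(6)]
        sig = {g: (i < 2, i < 1) for i, g in enumerate(genes)}
        calls = _ase_calls(sig)
        fracs = []
        for pair in itertools.combinations(genes, 2):
            n_sig = sum(sig[g][0] + sig[g][1] for g in pair)
            fracs.append(n_sig / 4.0)
        exhaustive_mean = np.mean(fracs)
        r = ase_enrichment(["g0", "g1"], genes, calls, n_subsets=20000, seed=1)
        assert r.null_fractions.mean() == pytest.approx(exhaustive_mean, abs=0.01)
        observed = 3 / 4.0
        exhaustive_p = np.mean(np.asarray(fracs) >= observed)
        assert r.p_value == pytest.approx(exhaustive_p, abs=0.01)

    def test_seeded_reproducibility_and_antitone_p(self):
        genes = [f"g{i}" for i in range(8)]
        sig = {g: (i % 2 == 0, i % 3 == 0) for i, g in enumerate(genes)}
        calls = _ase_calls(sig)
        r1 = ase_enrichment(["g0", "g2"], genes, calls, n_subsets=200, seed=9)
        r2 = ase_enrichment(["g0", "g2"], genes, calls, n_subsets=200, seed=9)
        assert np.array_equal(r1.null_fractions, r2.null_fractions)
        # higher observed fraction cannot raise p for the same null
        r_low = ase_enrichment(["g1", "g5"], genes, calls, n_subsets=200, seed=9)
        assert (r1.observed_fraction >= r_low.observed_fraction) == (
            r1.p_value <= r_low.p_value
        )

    def test_selection_outside_universe_raises(self):
        calls = _ase_calls({"g1": (True, False)})
        with pytest.raises(ValueError, match="subset"):
            ase_enrichment(["gX"], ["g1"], calls, n_subsets=10, seed=0)
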