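"""Community statistics against hand computations and independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from reefpipe import stats


def _matrix(values, **meta):
    df = pd.DataFrame(np.asarray(values, dtype=float))
    df.columns = [f"otu{i}" for i in range(df.shape[1])]
    for k, v in meta.items():
        df.insert(0, k, v)
    return df


class TestArcsine:
    @pytest.mark.parametrize("v, expected", [(0.0, 0.0), (1.0, np.pi / 2),
                                             (0.5, np.pi / 4)])
    def test_known_points(self, v, expected):
        out = stats.arcsine_transform(_matrix([[v]]))
        assert out.iloc[0, 0] == pytest.approx(expected)

    def test_round_trip(self, rng):
        x = rng.random((10, 5))
        out = stats.arcsine_transform(_matrix(x))
        assert np.allclose(np.sin(out.to_numpy()) ** 2, x, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.arcsine_transform(_matrix([[1.2]]))

    def test_metadata_columns_untouched(self):
        m = _matrix([[0.5]], area="west_coast")
        out = stats.arcsine_transform(m)
        assert (out["area"] == "west_coast").all()


class TestRareFilter:
    def test_strict_boundary_at_five_percent(self):
        x = np.zeros((100, 2))
        x[:5, 0] = 0.1  # prevalence exactly 0.05 -> kept
        x[:4, 1] = 0.1  # prevalence 0.04 -> dropped
        out = stats.filter_rare_otus(_matrix(x))
        assert list(out.columns) == ["otu0"]

    def test_matches_bruteforce_prevalence_scan(self, rng):
        x = (rng.random((40, 12)) < 0.08) * rng.random((40, 12))
        m = _matrix(x)
        out = stats.filter_rare_otus(m, 0.05)
        expected = [c for c in m.columns if (m[c] > 0).sum() / 40 >= 0.05]
        assert list(out.columns) == expected

    def test_all_dropped_rejected(self):
        x = np.zeros((100, 1))
        x[0, 0] = 1.0
        with pytest.raises(ValueError):
            stats.filter_rare_otus(_matrix(x))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = stats.bray_curtis(_matrix([[1, 2, 3], [1, 2, 3]]))
        assert d[0, 1] == pytest.approx(0.0)

    def test_disjoint_supports_one(self):
        d = stats.bray_curtis(_matrix([[1, 0], [0, 1]]))
        assert d[0, 1] == pytest.approx(1.0)

    def test_hand_computed_half(self):
        d = stats.bray_curtis(_matrix([[1, 1, 0], [0, 1, 1]]))
        assert d[0, 1] == pytest.approx(0.5)

    def test_matches_scipy_to_1e12(self, rng):
        x = rng.random((15, 8))
        mine = stats.bray_curtis(_matrix(x))
        ref = squareform(pdist(x, metric="braycurtis"))
        assert np.allclose(mine, ref, atol=1e-12)
        assert np.allclose(mine, mine.T)
        assert np.allclose(np.diag(mine), 0.0)

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            stats.bray_curtis(_matrix([[1, 2], [0, 0]]))


class TestPermanova:
    def test_exact_enumeration_two_groups_of_three(self, rng):
        x = rng.random((6, 4))
        d = stats.bray_curtis(_matrix(x))
        labels = ["a"] * 3 + ["b"] * 3
        res = stats.permanova(d, labels, exact=True)
        assert res.n_permutations == 20
        # independent oracle: enumerate the 20 label splits directly
        d2 = d**2
        n = 6

        def pseudo_f(lab):
            lab = np.asarray(lab)
            ss_t = d2.sum() / (2 * n)
            ss_w = sum(d2[np.ix_(lab == g, lab == g)].sum() / (2 * 3) for g in "ab")
            return ((ss_t - ss_w) / 1) / (ss_w / 4)

        f_obs = pseudo_f(labels)
        fs = [pseudo_f(p) for p in set(itertools.permutations(labels))]
        expected_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res.pseudo_f == pytest.approx(f_obs)
        assert res.p_value == pytest.approx(expected_p)

    def test_matches_scikit_bio_statistic(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        x = rng.random((12, 6))
        d = stats.bray_curtis(_matrix(x))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = stats.permanova(d, labels, n_perm=99, seed=0)
        ref = skbio_distance.permanova(skbio_distance.DistanceMatrix(d),
                                       grouping=labels, permutations=0)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_two_near_identical_blocks_hit_p_floor(self, rng):
        x = np.vstack([np.tile([1.0, 0.0, 0.0], (4, 1)),
                       np.tile([0.0, 0.0, 1.0], (4, 1))])
        x += rng.uniform(0, 1e-4, x.shape)  # break exact within-block ties
        d = stats.bray_curtis(_matrix(x))
        res = stats.permanova(d, ["a"] * 4 + ["b"] * 4, n_perm=199, seed=3)
        assert res.pseudo_f > 100
        # only permutations reproducing the block partition (prob 2/70 each)
        # can match F, so p sits just above the 1/(n_perm+1) floor
        assert 1 / 200 <= res.p_value <= 0.06

    def test_reproducible_under_seed(self, rng):
        x = rng.random((10, 5))
        d = stats.bray_curtis(_matrix(x))
        labels = ["a"] * 5 + ["b"] * 5
        r1 = stats.permanova(d, labels, n_perm=199, seed=42)
        r2 = stats.permanova(d, labels, n_perm=199, seed=42)
        assert r1.p_value == r2.p_value

    def test_invariant_to_relabeling_and_row_order(self, rng):
        x = rng.random((9, 5))
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        d = stats.bray_curtis(_matrix(x))
        f1 = stats.permanova(d, labels, n_perm=9, seed=0).pseudo_f
        renamed = np.array([{"a": "z", "b": "y", "c": "x"}[l] for l in labels])
        f2 = stats.permanova(d, renamed, n_perm=9, seed=0).pseudo_f
        perm = rng.permutation(9)
        f3 = stats.permanova(d[np.ix_(perm, perm)], labels[perm], n_perm=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2)
        assert f1 == pytest.approx(f3)

    def test_null_p_distribution_uniform(self):
        """Under exchangeable labels the permutation p is ~uniform (KS, alpha=0.01)."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(400):
            x = rng.random((12, 5))
            d = stats.bray_curtis(_matrix(x))
            labels = rng.permutation(["a"] * 6 + ["b"] * 6)
            pvals.append(stats.permanova(d, labels, n_perm=199,
                                         seed=int(rng.integers(2**31))).p_value)
        # compare against the discrete uniform on {1/200, ..., 200/200}
        ks = sps.kstest(np.round(np.array(pvals) * 200).astype(int),
                        sps.randint(1, 201).cdf)
        assert ks.pvalue > 0.01

    def test_singletons_rejected(self):
        d = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(ValueError):
            stats.permanova(d, ["a", "b"], n_perm=9)


class TestPairwisePermanova:
    def test_displaced_group_has_smallest_pairs(self, rng):
        base = rng.random((12, 5)) * 0.1
        base[8:] += 2.0  # group c displaced
        d = stats.bray_curtis(_matrix(base + 0.01))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        pw = stats.pairwise_permanova(d, labels, n_perm=199, seed=5)
        t = pw.table.sort_values("p_raw")
        top_pairs = {frozenset((r.group_a, r.group_b)) for r in t.head(2).itertuples()}
        assert top_pairs == {frozenset(("a", "c")), frozenset(("b", "c"))}

    def test_adjust_none_keeps_raw(self, rng):
        x = rng.random((9, 4))
        d = stats.bray_curtis(_matrix(x))
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        pw = stats.pairwise_permanova(d, labels, n_perm=49, seed=1, adjust="none")
        assert (pw.table["p_adjusted"] == pw.table["p_raw"]).all()

    def test_bh_adjustment_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        x = rng.random((12, 4))
        d = stats.bray_curtis(_matrix(x))
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        pw = stats.pairwise_permanova(d, labels, n_perm=49, seed=1, adjust="BH")
        expected = multipletests(pw.table["p_raw"], method="fdr_bh")[1]
        assert np.allclose(pw.table["p_adjusted"], expected)


def _dunn_bruteforce(groups):
    """Independent Dunn z computation from first principles."""
    names = list(groups)
    pooled = np.concatenate([groups[k] for k in names])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    sizes = {k: len(groups[k]) for k in names}
    start, mean_rank = 0, {}
    for k in names:
        mean_rank[k] = ranks[start : start + sizes[k]].mean()
        start += sizes[k]
    _, t = np.unique(pooled, return_counts=True)
    tie = (t**3 - t).sum() / (12 * (n - 1))
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = np.sqrt((n * (n + 1) / 12 - tie) * (1 / sizes[a] + 1 / sizes[b]))
            out[(a, b)] = (mean_rank[a] - mean_rank[b]) / se
    return out


class TestKruskalWallisDunn:
    def test_hand_computed_no_ties(self):
        res = stats.kruskal_wallis_dunn({"g1": [1, 2, 3], "g2": [4, 5, 6]})
        assert res.h_statistic == pytest.approx(3.857142857, abs=1e-6)
        assert res.p_value == pytest.approx(0.0495, abs=1e-3)
        assert res.df == 1

    def test_identical_groups_h_zero(self):
        res = stats.kruskal_wallis_dunn({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        groups = {k: rng.integers(0, 5, size=8).astype(float) for k in "abc"}
        res = stats.kruskal_wallis_dunn(groups)
        ref = sps.kruskal(*groups.values())
        assert res.h_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_dunn_z_matches_bruteforce_with_ties(self, rng):
        groups = {k: rng.integers(0, 4, size=6).astype(float) for k in "abc"}
        res = stats.kruskal_wallis_dunn(groups)
        expected = _dunn_bruteforce(groups)
        for row in res.pairwise.itertuples():
            assert row.z == pytest.approx(expected[(row.group_a, row.group_b)],
                                          rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.kruskal_wallis_dunn({"a": [1.0], "b": []})


class TestSignTest:
    def test_four_of_five_positive(self):
        res = stats.sign_test([1, 1, 1, 1, 0], [0, 0, 0, 0, 1])
        assert (res.s, res.n_effective) == (4, 5)
        assert res.p_value == pytest.approx(0.375)

    def test_all_positive_n10(self):
        res = stats.sign_test(np.arange(10) + 1.0, np.zeros(10))
        assert res.s == 10
        assert res.p_value == pytest.approx(2 * 0.5**10)

    def test_all_ties_rejected(self):
        with pytest.raises(ValueError, match="tied"):
            stats.sign_test([1.0, 2.0], [1.0, 2.0])

    def test_ties_dropped_from_n(self):
        res = stats.sign_test([1, 2, 3, 4], [1, 0, 0, 0])
        assert res.n_effective == 3
        assert res.s == 3

    def test_direction_flips_s_not_p(self):
        x, y = [3, 4, 5, 1.0], [1, 1, 1, 2.0]
        a = stats.sign_test(x, y)
        b = stats.sign_test(x, y, direction="y_minus_x")
        assert a.s + b.s == a.n_effective
        assert a.p_value == pytest.approx(b.p_value)

    @pytest.mark.parametrize("n, s", [(5, 4), (8, 2), (12, 6), (12, 11)])
    def test_matches_exact_sign_pattern_enumeration(self, n, s):
        """p equals enumeration over all 2^n equally likely sign patterns."""
        x = np.r_[np.ones(s), -np.ones(n - s)]
        res = stats.sign_test(x, np.zeros(n))
        counts = [sum(bin(m).count("1") == k for m in range(2**n)) for k in range(n + 1)]
        probs = np.array(counts) / 2**n
        lo = probs[: s + 1].sum()
        hi = probs[s:].sum()
        assert res.p_value == pytest.approx(min(1.0, 2 * min(lo, hi)), abs=1e-12)
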