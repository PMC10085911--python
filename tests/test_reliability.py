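"""Agreement coefficients against brute-force hand-formula oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from claviage.reliability import (
    DegenerateAgreement,
    cohen_kappa,
    fleiss_kappa,
    intra_rater,
    krippendorff_alpha,
)

# ---------------------------------------------------------------------------
# independent oracles (definition-level, no shared code with the implementation)


def oracle_cohen(r1, r2, cats, weights):
    k = len(cats)
    w = np.eye(k) if weights == "none" else (
        1 - np.abs(np.subtract.outer(range(k), range(k))) / (k - 1))
    n = len(r1)
    po = sum(w[cats.index(a), cats.index(b)] for a, b in zip(r1, r2)) / n
    pe = sum(
        w[i, j] * (list(r1).count(cats[i]) / n) * (list(r2).count(cats[j]) / n)
        for i in range(k) for j in range(k)
    )
    return (po - pe) / (1 - pe)


def oracle_fleiss(table, cats, weights):
    """Mean pairwise weighted agreement over items vs pooled-marginal chance."""
    k = len(cats)
    w = np.eye(k) if weights == "none" else (
        1 - np.abs(np.subtract.outer(range(k), range(k))) / (k - 1))
    n_items, m = len(table), len(table[0])
    po = 0.0
    for row in table:
        pairs = list(itertools.combinations(row, 2))
        po += sum(w[cats.index(a), cats.index(b)] for a, b in pairs) / len(pairs)
    po /= n_items
    pooled = [v for row in table for v in row]
    p = [pooled.count(c) / len(pooled) for c in cats]
    pe = sum(w[i, j] * p[i] * p[j] for i in range(k) for j in range(k))
    return (po - pe) / (1 - pe)


def oracle_alpha(table, cats, metric):
    """Krippendorff's alpha straight from the coincidence-matrix definition."""
    k = len(cats)
    units = [[v for v in row if v is not None] for row in table]
    units = [u for u in units if len(u) >= 2]
    o = np.zeros((k, k))
    for u in units:
        for a, b in itertools.permutations(range(len(u)), 2):
            o[cats.index(u[a]), cats.index(u[b])] += 1 / (len(u) - 1)
    nc = o.sum(1)
    n = nc.sum()
    if metric == "nominal":
        d = 1 - np.eye(k)
    elif metric == "interval":
        d = np.subtract.outer(range(k), range(k)) ** 2.0
    else:  # ordinal
        d = np.zeros((k, k))
        for c in range(k):
            for e in range(k):
                lo, hi = sorted((c, e))
                d[c, e] = (nc[lo:hi + 1].sum() - (nc[c] + nc[e]) / 2) ** 2
    do = (o * d).sum() / n
    de = sum(nc[c] * nc[e] * d[c, e] for c in range(k) for e in range(k)) / (n * (n - 1))
    return 1 - do / de


# ---------------------------------------------------------------------------


class TestCohenKappa:
    def test_identical_vectors_give_one(self):
        r = ["1", "3a", "4", "3a", "5"] * 2
        assert cohen_kappa(r, r).estimate == pytest.approx(1.0)
        assert cohen_kappa(r, r, weights="linear").estimate == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        # confusion [[45, 5], [5, 45]]: p_o = 0.9, p_e = 0.5, kappa = 0.8
        r1 = ["a"] * 50 + ["b"] * 50
        r2 = ["a"] * 45 + ["b"] * 5 + ["a"] * 5 + ["b"] * 45
        res = cohen_kappa(r1, r2)
        assert res.estimate == pytest.approx(0.8)
        assert res.p_value < 1e-6

    def test_maximally_discordant_ordinal_is_negative(self):
        r1 = ["1", "1", "1", "5", "5", "5"]
        r2 = ["5", "5", "5", "1", "1", "1"]
        assert cohen_kappa(r1, r2, weights="linear").estimate < 0

    def test_degenerate_single_category(self):
        with pytest.raises(DegenerateAgreement):
            cohen_kappa(["1"] * 5, ["1"] * 5)

    @pytest.mark.parametrize("weights", ["none", "linear"])
    def test_matches_definition_oracle_on_random_tables(self, weights, rng):
        cats = ["1", "2a", "3a", "4"]
        for _ in range(20):
            r1 = rng.choice(cats, size=30)
            r2 = rng.choice(cats, size=30)
            got = cohen_kappa(r1, r2, weights=weights, categories=cats).estimate
            assert got == pytest.approx(oracle_cohen(r1, r2, cats, weights))

    @given(st.randoms(use_true_random=False))
    def test_item_permutation_invariance(self, pyrng):
        cats = ["1", "3a", "4"]
        base = [(cats[i % 3], cats[(i * 2 + 1) % 3]) for i in range(12)]
        est0 = cohen_kappa(*zip(*base), weights="linear", categories=cats).estimate
        pyrng.shuffle(base)
        assert cohen_kappa(
            *zip(*base), weights="linear", categories=cats
        ).estimate == pytest.approx(est0)


class TestFleissKappa:
    def test_perfect_agreement(self):
        table = [["3a"] * 3, ["1"] * 3, ["4"] * 3, ["2b"] * 3]
        assert fleiss_kappa(table).estimate == pytest.approx(1.0)
        assert fleiss_kappa(table, weights="linear").estimate == pytest.approx(1.0)

    def test_hand_sized_table_matches_pairwise_oracle(self):
        cats = ["1", "2a", "3a"]
        table = [
            ["1", "1", "2a"],
            ["2a", "3a", "3a"],
            ["1", "2a", "3a"],
            ["3a", "3a", "3a"],
        ]
        for weights in ("none", "linear"):
            got = fleiss_kappa(table, weights=weights, categories=cats).estimate
            assert got == pytest.approx(oracle_fleiss(table, cats, weights))

    def test_independent_uniform_raters_near_zero(self, rng):
        cats = ["1", "2a", "3a", "4"]
        table = rng.choice(cats, size=(4000, 3))
        res = fleiss_kappa(table)
        # null kappa has SE ~ 1/sqrt(N m(m-1)/2); 4 sigma band around 0
        assert abs(res.estimate) < 4 / np.sqrt(4000 * 3)

    def test_unweighted_equals_identity_weighted(self, rng):
        cats = ["1", "2b", "3c", "5"]
        table = rng.choice(cats, size=(40, 3))
        unw = fleiss_kappa(table, weights="none", categories=cats).estimate
        # identity weights are exactly what weights="none" builds; cross-check
        # against the classic Fleiss computation on the count matrix
        counts = np.array([[list(row).count(c) for c in cats] for row in table])
        m = 3
        p_i = ((counts**2).sum(1) - m) / (m * (m - 1))
        pj = counts.sum(0) / counts.sum()
        classic = (p_i.mean() - (pj**2).sum()) / (1 - (pj**2).sum())
        assert unw == pytest.approx(classic)

    def test_estimates_within_bounds(self, rng):
        for _ in range(10):
            table = rng.choice(["a", "b", "c"], size=(15, 4))
            for weights in ("none", "linear"):
                est = fleiss_kappa(table, weights=weights).estimate
                assert -1.0 <= est <= 1.0


class TestKrippendorffAlpha:
    def test_perfect_agreement(self):
        table = [["1", "1", "1"], ["3a", "3a", "3a"], ["4", "4", "4"]]
        assert krippendorff_alpha(table) == pytest.approx(1.0)

    def test_one_item_two_raters_disagreeing(self):
        assert krippendorff_alpha([["1", "3a"]]) <= 0

    @pytest.mark.parametrize("metric", ["nominal", "ordinal", "interval"])
    def test_matches_coincidence_oracle_with_missing(self, metric, rng):
        cats = ["1", "2a", "3a", "4"]
        for _ in range(10):
            table = rng.choice(cats, size=(12, 4)).astype(object)
            mask = rng.random((12, 4)) < 0.25
            table[mask] = None
            got = krippendorff_alpha(table, metric=metric, categories=cats)
            assert got == pytest.approx(oracle_alpha(table.tolist(), cats, metric))

    def test_no_corated_item_is_degenerate(self):
        with pytest.raises(DegenerateAgreement):
            krippendorff_alpha([["1", None, None], [None, "3a", None]])

    def test_item_permutation_invariance(self, rng):
        cats = ["1", "2a", "3b"]
        table = rng.choice(cats, size=(20, 3)).astype(object)
        a0 = krippendorff_alpha(table, categories=cats)
        perm = rng.permutation(20)
        assert krippendorff_alpha(table[perm], categories=cats) == pytest.approx(a0)


class TestCrossSchemeBehaviour:
    def test_permutation_p_agrees_with_normal_for_strong_agreement(self):
        r1 = ["a"] * 20 + ["b"] * 20
        r2 = ["a"] * 18 + ["b"] * 2 + ["a"] * 2 + ["b"] * 18
        exact = cohen_kappa(r1, r2, p_method="permutation", n_permutations=999)
        normal = cohen_kappa(r1, r2)
        assert exact.p_value < 0.01 and normal.p_value < 0.01

    def test_permutation_p_near_one_for_chance_agreement(self, rng):
        r1 = rng.choice(["a", "b", "c"], 24)
        r2 = np.array(r1, dtype=object)
        rng.shuffle(r2)
        res = cohen_kappa(r1, r2, p_method="permutation", n_permutations=499)
        assert res.p_value > 0.05

    def test_nominal_alpha_tracks_fleiss_on_large_balanced_tables(self, rng):
        # regression property: on complete data the two chance corrections
        # converge; asserted as closeness, not equality
        cats = ["1", "2a", "3a", "4"]
        truth = rng.choice(cats, size=1500)
        table = np.stack(
            [np.where(rng.random(1500) < 0.3, rng.choice(cats, 1500), truth)
             for _ in range(3)], axis=1).astype(object)
        alpha = krippendorff_alpha(table, metric="nominal", categories=cats)
        kappa = fleiss_kappa(table, categories=cats).estimate
        assert alpha == pytest.approx(kappa, abs=0.02)


class TestIntraRater:
    def test_identical_passes(self):
        r = ["1", "3a", "NE", "4", "2a"]
        assert intra_rater(r, r).estimate == pytest.approx(1.0)

    def test_ne_rows_dropped_when_flag_off(self):
        first = ["3a", "3b", "NE", "4", "1"]
        second = ["3a", "3b", "2a", "4", "1"]  # differ only where a pass is NE
        assert intra_rater(first, second, include_not_evaluable=False
                           ).estimate == pytest.approx(1.0)

    def test_ne_participates_when_flag_on(self):
        first = ["3a", "3b", "NE", "4", "1", "2a"]
        second = ["3a", "3b", "2a", "4", "1", "2a"]
        res = intra_rater(first, second, include_not_evaluable=True)
        assert res.estimate < 1.0
        assert res.n_items == 6

    def test_noisy_reread_matches_direct_formula(self, rng):
        cats = ["1", "2a", "2b", "3a", "3b", "3c", "4", "5"]
        first = rng.choice(cats, size=50)
        shift = rng.integers(-1, 2, size=50)
        second = np.array(
            [cats[min(max(cats.index(a) + s, 0), 7)] for a, s in zip(first, shift)],
            dtype=object,
        )
        used = sorted(set(first) | set(second), key=cats.index)
        got = intra_rater(first, second, include_not_evaluable=False)
        assert got.estimate == pytest.approx(
            oracle_cohen(first, second, used, "linear"))
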