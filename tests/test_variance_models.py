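"""ANOVA decomposition, studentized-range procedures and letter displays
checked against definitional oracles and independent library implementations."""

import itertools
import math
import random

import numpy as np
import pytest
from scipy import stats

from cdmas.variance_models import (
    PairwiseComparisons,
    compact_letter_display,
    effect_share,
    one_way_anova,
    snk_test,
    tukey_hsd,
    two_way_anova,
)


def balanced_dataset(rng, a_levels, b_levels, reps, mu=0.3, spread=0.1):
    values, fa, fb = [], [], []
    for a in range(a_levels):
        for b in range(b_levels):
            for _ in range(reps):
                values.append(mu + rng.gauss(0, spread)
                              + 0.2 * a - 0.15 * b + 0.05 * a * b)
                fa.append(f"a{a}")
                fb.append(f"b{b}")
    return values, fa, fb


def definitional_two_way(values, fa, fb):
    """Brute-force balanced two-way SS from cell/marginal means."""
    y = np.asarray(values)
    la, lb = sorted(set(fa)), sorted(set(fb))
    grand = y.mean()
    cell = {(a, b): y[[i for i in range(len(y)) if fa[i] == a and fb[i] == b]]
            for a, b in itertools.product(la, lb)}
    n_cell = len(next(iter(cell.values())))
    mean_a = {a: np.mean([v for arr in (cell[(a, b)] for b in lb) for v in arr])
              for a in la}
    mean_b = {b: np.mean([v for arr in (cell[(a, b)] for a in la) for v in arr])
              for b in lb}
    ss_a = n_cell * len(lb) * sum((mean_a[a] - grand) ** 2 for a in la)
    ss_b = n_cell * len(la) * sum((mean_b[b] - grand) ** 2 for b in lb)
    ss_ab = n_cell * sum(
        (cell[(a, b)].mean() - mean_a[a] - mean_b[b] + grand) ** 2
        for a, b in itertools.product(la, lb))
    ss_e = sum(float(((arr - arr.mean()) ** 2).sum()) for arr in cell.values())
    return ss_a, ss_b, ss_ab, ss_e


class TestTwoWayAnova:
    def test_balanced_toy_matches_definitional_oracle(self):
        rng = random.Random(1)
        values, fa, fb = balanced_dataset(rng, 2, 2, 3)
        rows = two_way_anova(values, fa, fb)
        oracle = definitional_two_way(values, fa, fb)
        for row, expected in zip(rows, oracle):
            assert row.ss == pytest.approx(expected, abs=1e-10)

    def test_zero_factor_effect_gives_zero_ss(self):
        # identical level means, no noise
        values = [0.1, 0.2, 0.1, 0.2] * 3
        fa = (["a1"] * 4 + ["a2"] * 4 + ["a1", "a2"] * 2)[:12]
        fa = ["a1", "a1", "a2", "a2"] * 3
        fb = ["b1", "b2", "b1", "b2"] * 3
        rows = two_way_anova(values, fa, fb)
        assert rows[0].ss == pytest.approx(0.0, abs=1e-12)

    def test_balanced_components_sum_to_total(self, early_panel):
        values = [m.grain_cd for m in early_panel.measurements]
        # genotype at the common-allele marker x field: balanced replicates
        fa = [m.field_id for m in early_panel.measurements]
        fb = [m.replicate <= 1 for m in early_panel.measurements]
        rows = two_way_anova(values, fa, fb, "Field", "FirstRep")
        y = np.asarray(values)
        ss_total = float(((y - y.mean()) ** 2).sum())
        assert sum(r.ss for r in rows) == pytest.approx(ss_total, rel=1e-10)

    def test_matches_statsmodels_sequential_on_unbalanced_data(self):
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        rng = random.Random(7)
        rows_data = []
        for a in ("x", "y", "z"):
            for b in ("u", "v"):
                for _ in range(rng.randint(2, 6)):  # unbalanced cells
                    rows_data.append((a, b, rng.gauss(0.3 + (a == "x") * 0.2
                                                      - (b == "v") * 0.1, 0.05)))
        frame = pd.DataFrame(rows_data, columns=["A", "B", "y"])
        ours = two_way_anova(frame["y"], frame["A"], frame["B"], "A", "B")
        theirs = sm.stats.anova_lm(ols("y ~ C(A) * C(B)", frame).fit(), typ=1)
        for row, (_, ref) in zip(ours, theirs.iterrows()):
            assert row.ss == pytest.approx(ref["sum_sq"], rel=1e-8)
            assert row.df == int(ref["df"])

    def test_type3_equals_sequential_on_balanced_data(self):
        rng = random.Random(2)
        values, fa, fb = balanced_dataset(rng, 3, 2, 4)
        seq = two_way_anova(values, fa, fb)
        t3 = two_way_anova(values, fa, fb, ss_type="type3")
        for r1, r2 in zip(seq, t3):
            assert r1.ss == pytest.approx(r2.ss, rel=1e-8)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            two_way_anova([1, 2, 3, 4], ["a"] * 4, ["b1", "b1", "b2", "b2"])

    def test_empty_cell_names_the_cell(self):
        with pytest.raises(ValueError, match="a2.*b2"):
            two_way_anova([1, 2, 3], ["a1", "a1", "a2"], ["b1", "b2", "b1"])


class TestEffectShare:
    def test_fraction_of_effect_plus_error(self):
        assert effect_share(0.593, 3.971) == pytest.approx(0.593 / 4.564)

    def test_zero_effect_is_zero(self):
        assert effect_share(0.0, 1.7) == 0.0

    def test_zero_error_rejected(self):
        with pytest.raises(ValueError):
            effect_share(0.5, 0.0)


class TestOneWayAnova:
    def test_identical_groups_f_zero_p_one(self):
        res = one_way_anova({"g1": [1.0, 2.0, 3.0], "g2": [1.0, 2.0, 3.0]})
        assert res.f_stat == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_three_group_toy_matches_definitional_sums(self):
        groups = {"g1": [6.0, 8.0, 4.0, 5.0, 3.0, 4.0],
                  "g2": [8.0, 12.0, 9.0, 11.0, 6.0, 8.0],
                  "g3": [13.0, 9.0, 11.0, 8.0, 7.0, 12.0]}
        res = one_way_anova(groups)
        allv = [v for vs in groups.values() for v in vs]
        grand = sum(allv) / len(allv)
        ss_b = sum(len(vs) * (sum(vs) / len(vs) - grand) ** 2
                   for vs in groups.values())
        ss_w = sum((v - sum(vs) / len(vs)) ** 2
                   for vs in groups.values() for v in vs)
        expected_f = (ss_b / 2) / (ss_w / 15)
        assert res.f_stat == pytest.approx(expected_f, abs=1e-10)
        # independent implementation agrees
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(f_ref)
        assert res.p_value == pytest.approx(p_ref)

    def test_two_group_f_equals_t_squared(self):
        rng = random.Random(5)
        g1 = [rng.gauss(0.3, 0.1) for _ in range(8)]
        g2 = [rng.gauss(0.4, 0.1) for _ in range(8)]
        res = one_way_anova({"g1": g1, "g2": g2})
        t, _ = stats.ttest_ind(g1, g2)
        assert res.f_stat == pytest.approx(t ** 2, rel=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            one_way_anova({"g1": [1.0], "g2": [1.0, 2.0]})


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        groups = {g: [1.0, 2.0, 3.0] for g in "abc"}
        res = tukey_hsd(groups)
        assert not any(res.significant.values())

    def test_two_groups_match_pooled_t_test(self):
        rng = random.Random(11)
        for _ in range(50):
            n = rng.randint(3, 10)
            shift = rng.choice([0.0, 0.05, 0.15])
            g1 = [rng.gauss(0.3, 0.08) for _ in range(n)]
            g2 = [rng.gauss(0.3 + shift, 0.08) for _ in range(n)]
            tukey_sig = tukey_hsd({"g1": g1, "g2": g2}).is_significant("g1", "g2")
            _, p = stats.ttest_ind(g1, g2)
            assert tukey_sig == (p < 0.05)

    def test_extreme_separation_detected(self):
        rng = random.Random(13)
        base = [rng.gauss(0.0, 1.0) for _ in range(6)]
        groups = {"g1": base, "g2": [v + 0.1 for v in base],
                  "g3": [v + 10.0 for v in base]}  # 10 pooled SDs away
        res = tukey_hsd(groups)
        assert res.is_significant("g3", "g1")
        assert res.is_significant("g3", "g2")
        assert not res.is_significant("g1", "g2")

    def test_matches_scipy_tukey_on_random_data(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            data = [rng.normal(loc, 0.1, 6) for loc in (0.3, 0.35, 0.5)]
            ours = tukey_hsd({"g0": data[0], "g1": data[1], "g2": data[2]})
            ref = stats.tukey_hsd(*data)
            for (i, a), (j, b) in itertools.combinations(enumerate(
                    ("g0", "g1", "g2")), 2):
                assert ours.is_significant(a, b) == (ref.pvalue[i, j] < 0.05)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            tukey_hsd({"g1": [1.0, 2.0], "g2": [1.0, 2.0]}, alpha=1.5)


class TestSNK:
    def test_identical_groups_nothing_significant(self):
        groups = {g: [1.0, 2.0, 3.0] for g in "abcd"}
        assert not any(snk_test(groups).significant.values())

    def test_two_groups_coincide_with_tukey(self):
        rng = random.Random(29)
        for _ in range(30):
            g1 = [rng.gauss(0.3, 0.1) for _ in range(5)]
            g2 = [rng.gauss(0.38, 0.1) for _ in range(5)]
            groups = {"g1": g1, "g2": g2}
            assert snk_test(groups).significant == tukey_hsd(groups).significant

    def test_never_less_powerful_than_tukey(self):
        # equal-n 4-group data over 100 seeds: every Tukey-significant pair
        # must be SNK-significant
        for seed in range(100):
            rng = random.Random(seed)
            groups = {f"g{i}": [rng.gauss(0.3 + 0.05 * i, 0.08)
                                for _ in range(5)] for i in range(4)}
            tk = tukey_hsd(groups)
            snk = snk_test(groups)
            for pair, sig in tk.significant.items():
                if sig:
                    assert snk.is_significant(*pair)


class TestCompactLetterDisplay:
    @staticmethod
    def comparisons(groups, sig_pairs, alpha=0.05):
        decisions = {}
        for a, b in itertools.combinations(sorted(groups), 2):
            decisions[(a, b)] = (a, b) in sig_pairs or (b, a) in sig_pairs
        return PairwiseComparisons(tuple(sorted(groups)), decisions, alpha)

    def test_no_differences_single_letter(self):
        means = {"g1": 0.3, "g2": 0.2, "g3": 0.1}
        letters = compact_letter_display(self.comparisons(means, set()), means)
        assert all(rec.letters == "a" for rec in letters)

    def test_all_different_distinct_letters(self):
        means = {"g1": 0.3, "g2": 0.2, "g3": 0.1}
        pairs = {("g1", "g2"), ("g1", "g3"), ("g2", "g3")}
        letters = {rec.group_id: rec.letters
                   for rec in compact_letter_display(
                       self.comparisons(means, pairs), means)}
        assert letters == {"g1": "a", "g2": "b", "g3": "c"}

    def test_chain_pattern(self):
        # 1 ~ 2, 2 ~ 3, but 1 != 3  ->  a / ab / b
        means = {"g1": 0.3, "g2": 0.2, "g3": 0.1}
        letters = {rec.group_id: rec.letters
                   for rec in compact_letter_display(
                       self.comparisons(means, {("g1", "g3")}), means)}
        assert letters == {"g1": "a", "g2": "ab", "g3": "b"}

    def test_non_symmetric_matrix_rejected(self):
        comp = PairwiseComparisons(
            ("g1", "g2"), {("g1", "g2"): True, ("g2", "g1"): False}, 0.05)
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display(comp, {"g1": 0.2, "g2": 0.1})

    def test_soundness_on_random_matrices(self):
        # invariant: share a letter  <->  not significantly different
        rng = random.Random(31)
        for _ in range(200):
            k = rng.randint(2, 6)
            means = {f"g{i}": rng.random() for i in range(k)}
            pairs = {pair for pair in
                     itertools.combinations(sorted(means), 2)
                     if rng.random() < 0.4}
            comp = self.comparisons(means, pairs)
            letters = {rec.group_id: set(rec.letters) for rec in
                       compact_letter_display(comp, means)}
            for a, b in itertools.combinations(sorted(means), 2):
                share = bool(letters[a] & letters[b])
                assert share != comp.is_significant(a, b)
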