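import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from concoex.conditions import CONDITIONS, PAIR_ORDER
from concoex.concordance import (combine_deviations, concordance_index,
                                 concordance_table, condition_deviations,
                                 discretize_deviation, spearman_pair)
from tests.conftest import make_series, make_summary


def test_pair_order_enumeration_is_the_fixed_twelve():
    expected = [("DS", "DR"), ("NR", "DR"), ("NS", "DR"),
                ("DR", "DS"), ("NR", "DS"), ("NS", "DS"),
                ("DR", "NR"), ("DS", "NR"), ("NS", "NR"),
                ("DR", "NS"), ("DS", "NS"), ("NR", "NS")]
    assert list(PAIR_ORDER) == expected


class TestConditionDeviations:
    def test_equal_means_give_twelve_zeros(self):
        dv = condition_deviations(make_summary("m", [2, 2, 2, 2], [1, 1, 1, 1]))
        assert np.all(dv.d == 0)
        assert dv.valid.all()

    def test_hand_arithmetic_oracle_over_all_twelve(self):
        means = dict(zip(CONDITIONS, [0.0, 1.0, 2.0, 3.0]))
        sds = dict(zip(CONDITIONS, [1.0, 2.0, 1.0, 1.0]))
        dv = condition_deviations(make_summary("m", list(means.values()),
                                               list(sds.values())))
        for k, (j, i) in enumerate(PAIR_ORDER):
            assert dv.d[k] == pytest.approx((means[j] - means[i]) / sds[i]), (j, i)
        assert dv.d[0] == pytest.approx(1.0)    # DS|DR
        assert dv.d[3] == pytest.approx(-0.5)   # DR|DS
        assert dv.d[11] == pytest.approx(-1.0)  # NR|NS

    def test_zero_sd_with_mean_gap_hits_outermost_class(self):
        dv = condition_deviations(make_summary("m", [0, 1, 0, 0], [0, 1, 1, 1]))
        assert dv.d[0] == np.inf   # DS|DR with sd(DR)=0
        assert discretize_deviation(dv.d[0]) == 2.0

    def test_absent_condition_invalidates_touching_pairs(self):
        s = make_summary("m", [0, 1, 2, 3], [1, 1, 1, 1])
        s.n["DS"] = 0
        dv = condition_deviations(s)
        for k, (j, i) in enumerate(PAIR_ORDER):
            assert dv.valid[k] == ("DS" not in (j, i))


class TestCombineDeviations:
    @pytest.mark.parametrize("dm, dp, expected", [
        (3.8, 2.5, 2.5),    # same sign: min magnitude
        (3.8, -2.5, -2.5),  # opposite signs
        (0.0, 7.0, 0.0),    # zero factor
        (-4.0, -1.5, 1.5),  # both negative -> positive
    ])
    def test_signed_minimum_combination(self, dm, dp, expected):
        a = make_summary("a", [0, dm, 0, 0], [1, 1, 1, 1])
        # build deviation vectors directly
        dva = condition_deviations(a)
        dvb = condition_deviations(make_summary("b", [0, dp, 0, 0], [1, 1, 1, 1]))
        z = combine_deviations(dva, dvb)
        assert z[0] == pytest.approx(expected)

    def test_invalid_side_contributes_zero(self):
        a = make_summary("a", [0, 5, 0, 0], [1, 1, 1, 1])
        b = make_summary("b", [0, 5, 0, 0], [1, 1, 1, 1])
        b.n["DS"] = 0
        z = combine_deviations(condition_deviations(a), condition_deviations(b))
        assert z[0] == 0.0


class TestDiscretize:
    @pytest.mark.parametrize("z, expected", [
        (0.99, 0.0), (1.0, 0.25), (1.99, 0.25), (2.0, 1.0), (2.99, 1.0),
        (3.0, 1.5), (3.8, 1.5), (4.99, 1.5), (5.0, 1.75), (9.99, 1.75),
        (10.0, 2.0), (50.0, 2.0), (np.inf, 2.0), (0.0, 0.0),
    ])
    def test_class_boundaries(self, z, expected):
        assert discretize_deviation(z) == expected
        assert discretize_deviation(-z) == -expected

    def test_odd_and_non_decreasing(self):
        grid = np.linspace(-30, 30, 2001)
        out = discretize_deviation(grid)
        assert np.allclose(out, -discretize_deviation(-grid))
        assert np.all(np.diff(out) >= 0)

    @given(st.floats(min_value=-1e6, max_value=1e6),
           st.floats(min_value=-1e6, max_value=1e6))
    @settings(deadline=None, derandomize=True)
    def test_component_never_exceeds_either_sides_component(self, dm, dp):
        """Discretizing the signed-minimum combination never yields a
        component larger in magnitude than either side's own class."""
        z = np.sign(dm) * np.sign(dp) * min(abs(dm), abs(dp))
        comp = discretize_deviation(z)
        assert abs(comp) <= min(abs(discretize_deviation(dm)),
                                abs(discretize_deviation(dp)))
        assert abs(comp) <= 2.0


class TestConcordanceIndex:
    def test_maximal_concordance_of_extreme_identical_vectors(self):
        s = make_summary("m", [0, 20, 40, 60], [1, 1, 1, 1])
        dv = condition_deviations(s)
        assert np.all(np.abs(dv.d) >= 10)
        res = concordance_index(dv, dv)
        assert res.ic == 24.0
        assert res.ic_neg == 0.0

    def test_ic_is_sum_of_signed_component_branches(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            a = make_summary("a", rng.normal(0, 3, 4), rng.uniform(0.2, 2, 4))
            b = make_summary("b", rng.normal(0, 3, 4), rng.uniform(0.2, 2, 4))
            res = concordance_index(condition_deviations(a), condition_deviations(b))
            assert res.ic == res.ic_neg + res.ic_pos
            assert res.ic_pos >= 0 >= res.ic_neg
            assert abs(res.ic) <= 24
            # quarter-integer grid, exactly representable
            assert (4 * res.ic) == int(4 * res.ic)


class TestSpearman:
    def test_identity_and_antitone(self):
        vals = {c: [float(i) for i in range(r, r + 3)]
                for r, c in enumerate(CONDITIONS)}
        m = make_series("m", vals)
        p_same = make_series("p", vals, molecule_class="phosphopeptide")
        rho, p, n = spearman_pair(m, p_same)
        assert rho == pytest.approx(1.0)
        assert n == 12
        assert p < 0.05
        p_neg = make_series("q", {c: [-v for v in vv] for c, vv in vals.items()},
                            molecule_class="phosphopeptide")
        rho_neg, _, _ = spearman_pair(m, p_neg)
        assert rho_neg == pytest.approx(-1.0)

    def test_matches_closed_form_rank_formula_without_ties(self):
        rng = np.random.default_rng(13)
        x = np.arange(1, 13, dtype=float)
        y = rng.permutation(x)
        m = make_series("m", {c: x[i * 3:(i + 1) * 3]
                              for i, c in enumerate(CONDITIONS)})
        p = make_series("p", {c: y[i * 3:(i + 1) * 3]
                              for i, c in enumerate(CONDITIONS)},
                        molecule_class="phosphopeptide")
        rho, _, n = spearman_pair(m, p)
        d = stats.rankdata(x) - stats.rankdata(y)
        # closed form 1 - 6 sum d^2 / (n (n^2 - 1)); exact absent ties
        assert rho == pytest.approx(1 - 6 * np.sum(d ** 2) / (n * (n ** 2 - 1)))

    def test_truncation_to_smaller_replicate_count(self):
        m = make_series("m", {"DR": [1, 2, 3, 4], "DS": [5, 6]})
        p = make_series("p", {"DR": [1, 2], "DS": [5, 6, 7]},
                        molecule_class="phosphopeptide")
        rho, _, n = spearman_pair(m, p)
        assert n == 4  # 2 from DR, 2 from DS

    def test_agrees_with_scipy_spearmanr_including_ties(self):
        rng = np.random.default_rng(29)
        for _ in range(20):
            vals_m = {c: np.round(rng.normal(i, 1, 5), 1)
                      for i, c in enumerate(CONDITIONS)}
            vals_p = {c: np.round(rng.normal(0, 1, 5), 1) for c in CONDITIONS}
            m = make_series("m", vals_m)
            p = make_series("p", vals_p, molecule_class="phosphopeptide")
            rho, pval, n = spearman_pair(m, p)
            x = np.concatenate([vals_m[c] for c in CONDITIONS])
            y = np.concatenate([vals_p[c] for c in CONDITIONS])
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic)
            assert pval == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_points_forces_p_one(self):
        m = make_series("m", {"DR": [1, 2]})
        p = make_series("p", {"DR": [3, 4]}, molecule_class="phosphopeptide")
        _, pval, n = spearman_pair(m, p)
        assert n == 2 and pval == 1.0


class TestConcordanceTable:
    def _inputs(self, n_m, n_p, seed=0):
        rng = np.random.default_rng(seed)
        mets, phos = [], []
        for i in range(n_m):
            vals = {c: rng.normal(rng.normal(0, 2), 0.5, 5) for c in CONDITIONS}
            ser = make_series(f"M{i}", vals)
            from concoex.preprocessing import summarize
            mets.append((summarize(ser), ser))
        for i in range(n_p):
            vals = {c: rng.normal(rng.normal(0, 2), 0.5, 5) for c in CONDITIONS}
            ser = make_series(f"P{i}", vals, molecule_class="phosphopeptide")
            from concoex.preprocessing import summarize
            phos.append((summarize(ser), ser))
        return mets, phos

    def test_cardinality_one_by_one(self):
        mets, phos = self._inputs(1, 1)
        assert len(concordance_table(mets, phos, "wild_type")) == 1

    def test_rows_match_independent_per_pair_recomputation(self):
        mets, phos = self._inputs(3, 5, seed=21)
        table = concordance_table(mets, phos, "wild_type")
        assert len(table) == 15
        for (sm, serm) in mets:
            for (sp, serp) in phos:
                row = table[(table.metabolite_id == sm.molecule_id)
                            & (table.phosphopeptide_id == sp.molecule_id)].iloc[0]
                res = concordance_index(condition_deviations(sm),
                                        condition_deviations(sp))
                assert row.ic == res.ic
                assert row.ic_neg == res.ic_neg
                rho, pval, n = spearman_pair(serm, serp)
                assert row.rho == pytest.approx(rho)
                assert row.rho_p == pytest.approx(pval)
                assert row.n_rho == n

    def test_duplicate_ids_rejected(self):
        mets, phos = self._inputs(2, 2)
        mets[1][0].molecule_id = mets[0][0].molecule_id
        with pytest.raises(ValueError, match="duplicate metabolite ids"):
            concordance_table(mets, phos, "wild_type")


class TestInvariants:
    """Seeded random-pair invariants of the concordance index."""

    def _random_summaries(self, n, seed):
        rng = np.random.default_rng(seed)
        return ([make_summary(f"a{i}", rng.normal(0, 3, 4), rng.uniform(0.1, 2, 4))
                 for i in range(n)],
                [make_summary(f"b{i}", rng.normal(0, 3, 4), rng.uniform(0.1, 2, 4))
                 for i in range(n)])

    def test_symmetry_affine_reflection_bounds(self):
        A, B = self._random_summaries(1000, seed=99)
        for sa, sb in zip(A, B):
            da, db = condition_deviations(sa), condition_deviations(sb)
            ic_ab = concordance_index(da, db).ic
            ic_ba = concordance_index(db, da).ic
            assert ic_ab == ic_ba                       # symmetry
            assert -24 <= ic_ab <= 24                   # bound
            # affine x -> a x + b on molecule a
            a, b = 2.3, -1.1
            sa2 = make_summary("a2", a * np.array([sa.mean[c] for c in CONDITIONS]) + b,
                               a * np.array([sa.sd[c] for c in CONDITIONS]))
            assert concordance_index(condition_deviations(sa2), db).ic == ic_ab
            # reflection x -> -x + b negates I_C
            sa3 = make_summary("a3", -np.array([sa.mean[c] for c in CONDITIONS]) + b,
                               np.array([sa.sd[c] for c in CONDITIONS]))
            assert concordance_index(condition_deviations(sa3), db).ic == -ic_ab

    def test_self_concordance_nonnegative_and_scale_free(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            s = make_summary("m", rng.normal(0, 3, 4), rng.uniform(0.1, 2, 4))
            d = condition_deviations(s)
            ic_self = concordance_index(d, d).ic
            assert ic_self >= 0
            s2 = make_summary("m2", 1.7 * np.array([s.mean[c] for c in CONDITIONS]) + 4,
                              1.7 * np.array([s.sd[c] for c in CONDITIONS]))
            assert concordance_index(condition_deviations(s2), d).ic == ic_self

    def test_flat_partner_suppresses_concordance(self):
        rng = np.random.default_rng(23)
        flat = make_summary("flat", [1.0, 1.0, 1.0, 1.0], [0.5, 0.4, 0.3, 0.2])
        for _ in range(100):
            other = make_summary("o", rng.normal(0, 5, 4), rng.uniform(0.1, 1, 4))
            res = concordance_index(condition_deviations(flat),
                                    condition_deviations(other))
            assert res.ic == 0.0
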