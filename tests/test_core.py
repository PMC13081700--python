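"""ODC statistic, adaptive-gamma permutation machinery, and the IUT p-value."""

import warnings
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netdom import (
    GammaGrid,
    ImagingMatrix,
    NetworkPartition,
    PermutationPlan,
    PhenotypeDesign,
    bh_fdr,
    d_gamma,
    gamma_p_values,
    netdom_test,
    null_q_distribution,
    odc_plugin,
    p_zero,
    select_q,
)
from netdom.core import d_values

from conftest import make_dataset


def curve_from(in_vals, out_vals):
    values = np.concatenate([in_vals, out_vals])
    labels = np.r_[np.ones(len(in_vals), int), np.zeros(len(out_vals), int)]
    return odc_plugin(values, NetworkPartition(labels, 1))


class TestOdcPlugin:
    def test_step_heights_direct_ecdf_count(self):
        curve = curve_from([1.5, 2.0, 3.0], [0.5, 1.0, 2.5, 4.0])
        np.testing.assert_allclose(curve.step_heights, [0.5, 0.5, 0.75])

    def test_total_dominance(self):
        curve = curve_from([10.0, 11.0, 12.0], [0.5, 1.0, 2.5, 4.0])
        np.testing.assert_allclose(curve.step_heights, 1.0)

    def test_identical_samples_tie_convention(self):
        curve = curve_from([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        np.testing.assert_allclose(curve.step_heights, [1 / 3, 2 / 3, 1.0])

    def test_empty_side_errors(self):
        values = np.arange(4.0)
        with pytest.raises(ValueError):
            odc_plugin(values, NetworkPartition(np.array([1, 1, 1, 1]), 1))


class TestDGamma:
    def test_total_dominance_bound(self):
        curve = curve_from([10.0, 11.0, 12.0], [0.5, 1.0, 2.5])
        assert d_gamma(curve, 0.0) == pytest.approx(0.5)

    def test_pairwise_count_example(self):
        curve = curve_from([1.5, 2.0, 3.0], [0.5, 1.0, 2.5, 4.0])
        assert d_gamma(curve, 0.0) == pytest.approx(7 / 12 - 0.5)

    def test_identical_samples_value(self):
        for m in (3, 7, 20):
            vals = np.arange(1.0, m + 1)
            curve = curve_from(vals, vals)
            assert d_gamma(curve, 0.0) == pytest.approx(1 / (2 * m))

    def test_gamma_out_of_range_errors(self):
        curve = curve_from([1.0, 2.0], [0.0, 3.0])
        with pytest.raises(ValueError):
            d_gamma(curve, 1.0)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_d0_equals_pairwise_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(2, 30, size=2)
        inv = rng.normal(size=m)
        outv = np.round(rng.normal(size=n), 1)  # provoke occasional ties
        curve = curve_from(inv, outv)
        pairs = sum(1 for x in outv for y in inv if x <= y)
        assert d_gamma(curve, 0.0) == pytest.approx(pairs / (n * m) - 0.5, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_d_gamma_matches_riemann_sum(self, seed):
        rng = np.random.default_rng(seed)
        m, n = rng.integers(3, 25, size=2)
        curve = curve_from(rng.normal(size=m), rng.normal(size=n))
        t = (np.arange(1_000_000) + 0.5) / 1_000_000
        odc = curve.step_heights[np.minimum((np.ceil(t * m) - 1).astype(int), m - 1)]
        for gamma in GammaGrid().gammas:
            riemann = np.sum((t > gamma) * (odc - t)) / 1_000_000
            assert d_gamma(curve, float(gamma)) == pytest.approx(riemann, abs=1e-5)

    @given(st.integers(0, 2**32 - 1), st.floats(0.01, 5.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_monotone_under_in_network_shift(self, seed, shift):
        rng = np.random.default_rng(seed)
        inv = rng.normal(size=rng.integers(2, 20))
        outv = rng.normal(size=rng.integers(2, 20))
        before = curve_from(inv, outv)
        after = curve_from(inv + shift, outv)
        for gamma in GammaGrid().gammas:
            assert d_gamma(after, float(gamma)) >= d_gamma(before, float(gamma)) - 1e-12


class TestGammaPValues:
    def test_count_arithmetic(self):
        assert gamma_p_values([0.4], [[0.1], [0.2], [0.5]], "right")[0] == 0.5

    def test_extreme_observation_floor(self):
        p = gamma_p_values([0.9], [[0.1], [0.2], [0.3]], "right")
        assert p[0] == pytest.approx(1 / 4)

    def test_inclusive_ties(self):
        p = gamma_p_values([0.4], [[0.4], [0.1], [0.2]], "right")
        assert p[0] == pytest.approx(2 / 4)

    def test_left_side_flips_inequality(self):
        p = gamma_p_values([0.1], [[0.1], [0.2], [0.5]], "left")
        assert p[0] == pytest.approx(2 / 4)

    def test_no_nulls_errors(self):
        with pytest.raises(ValueError):
            gamma_p_values([0.4], np.empty((0, 1)), "right")


class TestSelectQ:
    def test_minimum_and_gamma(self):
        q, g = select_q([0.2, 0.04, 0.1], [0.0, 0.05, 0.1])
        assert q == 0.04 and g == 0.05

    def test_ties_break_to_smallest_gamma(self):
        q, g = select_q([0.3, 0.3, 0.3], [0.0, 0.05, 0.1])
        assert q == 0.3 and g == 0.0

    def test_single_gamma(self):
        q, g = select_q([0.77], [0.0])
        assert q == 0.77 and g == 0.0


class TestNullQDistribution:
    def test_leave_one_out_formula(self):
        q = null_q_distribution(np.array([[1.0], [2.0], [3.0]]), "right")
        np.testing.assert_allclose(q, [1.0, 2 / 3, 1 / 3])

    def test_complete_ties_give_one(self):
        q = null_q_distribution(np.full((5, 3), 2.0), "right")
        np.testing.assert_allclose(q, 1.0)

    @pytest.mark.parametrize("side", ["right", "left"])
    def test_matches_brute_force_double_loop(self, side, rng):
        K, G = 20, 3
        D = np.round(rng.normal(size=(K, G)), 1)  # ties included
        q = null_q_distribution(D, side)
        expected = np.empty(K)
        for k in range(K):
            ps = []
            for g in range(G):
                if side == "right":
                    cnt = sum(D[k1, g] >= D[k, g] for k1 in range(K) if k1 != k)
                else:
                    cnt = sum(D[k1, g] <= D[k, g] for k1 in range(K) if k1 != k)
                ps.append((1 + cnt) / K)
            expected[k] = min(ps)
        np.testing.assert_allclose(q, expected)


class TestPZero:
    def test_count_arithmetic(self):
        assert p_zero(0.5, [0.1, -0.2, 0.7], "right") == 0.5

    def test_extreme_observation_floor(self):
        assert p_zero(5.0, [0.1, -0.2, 0.7], "right") == pytest.approx(1 / 4)

    def test_left_equals_right_on_negated(self, rng):
        nulls = rng.normal(size=20)
        obs = 0.3
        assert p_zero(obs, nulls, "left") == p_zero(-obs, -nulls, "right")

    def test_left_on_unsigned_errors(self):
        with pytest.raises(ValueError, match="signed"):
            p_zero(0.5, [0.1], "left", signed=False)


# ---------------------------------------------------------------------------
# full orchestration
# ---------------------------------------------------------------------------


def _reference_netdom(imaging, design, labels, network_id, perms, gammas):
    """Straight-line reimplementation of the whole six-step procedure.

    Per-location OLS via lstsq, explicit Freedman-Lane loops, exact rational
    D_gamma integrals, and explicit counting loops for every p-value.
    """
    Y = imaging.data
    N, V = Y.shape
    X = np.column_stack(
        [np.ones(N)]
        + [design.values[c].to_numpy() for c in design.nuisance]
        + [design.values[design.target].to_numpy()]
    )
    p = X.shape[1]

    def tmap(M):
        beta, *_ = np.linalg.lstsq(X, M, rcond=None)
        rss = ((M - X @ beta) ** 2).sum(axis=0)
        se = np.sqrt(rss / (N - p) * np.linalg.inv(X.T @ X)[-1, -1])
        return beta[-1] / se

    Z = X[:, :-1]
    fits = Z @ np.linalg.lstsq(Z, Y, rcond=None)[0]
    resid = Y - fits
    maps = [tmap(Y)] + [tmap(fits + resid[perm]) for perm in perms]

    in_mask = labels == network_id
    m, n = int(in_mask.sum()), int((~in_mask).sum())

    def D_exact(vals, gamma):
        ins = np.sort(vals[in_mask])
        outs = vals[~in_mask]
        total = Fraction(0)
        for i in range(1, m + 1):
            c = Fraction(int((outs <= ins[i - 1]).sum()), n)
            lo = max(gamma, Fraction(i - 1, m))
            if Fraction(i, m) > lo:
                total += c * (Fraction(i, m) - lo)
        return total - Fraction(1 - gamma * gamma, 2)

    gam_fracs = [Fraction(g).limit_denominator(10**6) for g in gammas]
    D = [[D_exact(vals, g) for g in gam_fracs] for vals in maps]
    K = len(perms)
    p_gamma = [
        Fraction(1 + sum(D[k][g] >= D[0][g] for k in range(1, K + 1)), K + 1)
        for g in range(len(gammas))
    ]
    q_obs = min(p_gamma)
    q_null = []
    for k in range(1, K + 1):
        ps = []
        for g in range(len(gammas)):
            cnt = sum(D[k1][g] >= D[k][g] for k1 in range(1, K + 1) if k1 != k)
            ps.append(Fraction(1 + cnt, K))
        q_null.append(min(ps))
    p_diff = Fraction(1 + sum(qk <= q_obs for qk in q_null), K + 1)
    mean_in = [vals[in_mask].mean() for vals in maps]
    pz = Fraction(1 + sum(mi >= mean_in[0] for mi in mean_in[1:]), K + 1)
    return float(max(p_diff, pz)), float(p_diff), float(pz)


def test_netdom_matches_straightline_reference():
    rng = np.random.default_rng(77)
    N, V, K = 30, 50, 50
    design = PhenotypeDesign(
        pd.DataFrame({"z": rng.standard_normal(N), "x": rng.standard_normal(N)}),
        target="x",
        nuisance=("z",),
    )
    labels = np.zeros(V, int)
    labels[rng.choice(V, 30, replace=False)] = 1
    beta = np.where(labels == 1, 0.3, 0.0)
    Y = rng.standard_normal((N, V)) + np.outer(design.values["x"], beta)
    imaging = ImagingMatrix(Y)
    plan = PermutationPlan.generate(N, K, "freedman_lane", 13)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-network warning expected
        res = netdom_test(imaging, design, NetworkPartition(labels, 1), plan)
    p_ref, p_diff_ref, p_zero_ref = _reference_netdom(
        imaging, design, labels, 1, plan.permutations, res.gammas
    )
    assert res.p_diff == pytest.approx(p_diff_ref, abs=1e-12)
    assert res.p_zero == pytest.approx(p_zero_ref, abs=1e-12)
    assert res.p == pytest.approx(p_ref, abs=1e-12)


def test_iut_maximum_and_floor():
    # enormous positive in-network effects: both component p-values hit the
    # permutation floor and p = 1/(K+1)
    rng = np.random.default_rng(5)
    N, V, K = 40, 60, 99
    design = PhenotypeDesign(pd.DataFrame({"x": rng.standard_normal(N)}), target="x")
    labels = np.r_[np.ones(30, int), np.zeros(30, int)]
    Y = rng.standard_normal((N, V))
    Y[:, :30] += np.outer(design.values["x"], np.full(30, 3.0))
    plan = PermutationPlan.generate(N, K, "freedman_lane", 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = netdom_test(ImagingMatrix(Y), design, NetworkPartition(labels, 1), plan)
    assert res.p == pytest.approx(1 / 100)
    assert res.p == max(res.p_diff, res.p_zero)


def test_p_is_max_of_components_and_bounded(rng):
    # random null data: p = max(p_diff, p_zero) and all p in [1/(K+1), 1]
    for seed in range(4):
        imaging, design = make_dataset(25, 40, seed=seed)
        labels = np.zeros(40, int)
        labels[:15] = 1
        plan = PermutationPlan.generate(25, 30, "freedman_lane", seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = netdom_test(imaging, design, NetworkPartition(labels, 1), plan)
        assert res.p == max(res.p_diff, res.p_zero)
        for p in (res.p, res.p_diff, res.p_zero, res.q_obs, *res.p_gamma):
            assert 1 / 31 - 1e-12 <= p <= 1 + 1e-12


def test_left_right_symmetry_under_sign_flip():
    imaging, design = make_dataset(40, 80, seed=21)
    labels = np.zeros(80, int)
    labels[:35] = 1
    plan = PermutationPlan.generate(40, 60, "freedman_lane", 9)
    part = NetworkPartition(labels, 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        right = netdom_test(imaging, design, part, plan, side="right")
        left = netdom_test(
            ImagingMatrix(-imaging.data, mask=imaging.mask),
            design, part, plan, side="left",
        )
    assert left.p == right.p
    assert left.p_diff == right.p_diff
    assert left.p_zero == right.p_zero
    assert left.gamma_selected == right.gamma_selected


def test_left_side_on_unsigned_statistic_errors():
    imaging, design = make_dataset(25, 30, seed=2)
    labels = np.zeros(30, int)
    labels[:10] = 1
    plan = PermutationPlan.generate(25, 10, "freedman_lane", 1)
    with pytest.raises(ValueError, match="unsigned|signed"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            netdom_test(imaging, design, NetworkPartition(labels, 1), plan,
                        side="left", stat_kind="F")


def test_small_network_warns():
    imaging, design = make_dataset(25, 120, seed=2)
    labels = np.zeros(120, int)
    labels[:20] = 1
    plan = PermutationPlan.generate(25, 10, "freedman_lane", 1)
    with pytest.warns(UserWarning, match="m="):
        netdom_test(imaging, design, NetworkPartition(labels, 1), plan)


class TestBhFdr:
    def test_closed_form_example(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_matches_textbook_step_up(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=rng.integers(1, 25))
        adj = bh_fdr(p)
        # textbook oracle: sort, p_(i) * m / i, cumulative min from the right
        order = np.argsort(p)
        mvals = p[order] * len(p) / np.arange(1, len(p) + 1)
        stepped = np.minimum.accumulate(mvals[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(adj, expected, atol=1e-12)
        assert np.all(adj >= p - 1e-12)
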