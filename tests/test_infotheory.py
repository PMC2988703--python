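"""B-spline MI estimator, synergy, proxy ranking, and the Gumbel null."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evasig.infotheory import (
    bspline_mi,
    bspline_weights,
    exhaustive_synergy_search,
    fit_gumbel_null,
    gumbel_pvalue,
    mi_rank_against_proxy,
    permutation_maxima,
    synergy,
)
from evasig.simulate import SimulationConfig, generate_dataset, generate_normal_control, generate_xor_triple


class TestBsplineWeights:
    @pytest.mark.parametrize("order", [1, 2, 3])
    def test_partition_of_unity(self, order):
        rng = np.random.default_rng(0)
        W = bspline_weights(rng.normal(size=200), bins=6, order=order)
        assert W.shape == (200, 6)
        np.testing.assert_allclose(W.sum(axis=1), 1.0)
        assert (W >= 0).all()

    def test_weighted_histograms_normalised_in_all_dimensionalities(self):
        rng = np.random.default_rng(1)
        Ws = [bspline_weights(rng.normal(size=150)) for _ in range(3)]
        p1 = Ws[0].mean(axis=0)
        p2 = np.einsum("ia,ib->ab", Ws[0], Ws[1]) / 150
        p3 = np.einsum("ia,ib,ic->abc", *Ws) / 150
        for p in (p1, p2, p3):
            assert p.sum() == pytest.approx(1.0)

    def test_rejects_too_few_samples_and_nonfinite(self):
        with pytest.raises(ValueError):
            bspline_weights([1.0, 2.0], bins=6, order=3)
        with pytest.raises(ValueError):
            bspline_weights([1.0, np.inf, 2.0, 3.0])


class TestBsplineMi:
    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(2)
        mi = bspline_mi(rng.normal(size=5000), rng.normal(size=5000))
        assert mi.value < 0.02

    def test_monotone_in_correlation_strength(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=4000)
        vals = []
        for rho in (0.0, 0.5, 0.9, 0.99):
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=4000)
            vals.append(bspline_mi(x, y).value)
        assert vals == sorted(vals)

    def test_identity_is_maximal_and_bounded(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2000)
        self_mi = bspline_mi(x, x).value
        for _ in range(3):
            assert self_mi >= bspline_mi(x, rng.permutation(x)).value
        assert 0.0 <= self_mi <= np.log2(6)

    def test_constant_variable_zero_by_convention(self):
        rng = np.random.default_rng(5)
        assert bspline_mi(np.ones(100), rng.normal(size=100)).value == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_affine_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300)
        y = 0.6 * x + rng.normal(size=300)
        a = bspline_mi(x, y).value
        assert a == pytest.approx(bspline_mi(y, x).value, abs=1e-10)
        assert a == pytest.approx(bspline_mi(3.5 * x + 11.0, y).value, abs=1e-10)
        assert a >= 0.0


class TestSynergy:
    def test_xor_gate_close_to_one_bit(self):
        a, b, t = generate_xor_triple(5000, seed=6)
        s = synergy(a, b, t)
        assert s.synergy == pytest.approx(1.0, abs=0.15)
        assert s.mi_1 < 0.05 and s.mi_2 < 0.05
        # identity holds exactly
        assert s.synergy == s.joint_mi - s.mi_1 - s.mi_2

    def test_xor_matches_discrete_gate_oracle(self):
        """Plug-in MI on the generating binary gate is the reference value."""
        a, b, t = generate_xor_triple(5000, seed=7)
        sa = a > np.median(a)
        sb = b > np.median(b)
        st_ = t > np.median(t)
        # discrete I((sa,sb); st) via joint counts
        joint = np.zeros((2, 2, 2))
        for i in range(len(a)):
            joint[int(sa[i]), int(sb[i]), int(st_[i])] += 1
        joint /= joint.sum()
        p_ab = joint.sum(axis=2)
        p_t = joint.sum(axis=(0, 1))
        mask = joint > 0
        denom = p_ab[..., None] * p_t[None, None, :]
        oracle = float(np.sum(joint[mask] * np.log2(joint[mask] / denom[mask])))
        s = synergy(a, b, t)
        assert s.joint_mi == pytest.approx(oracle, abs=0.1)

    def test_independent_target_near_zero_synergy(self):
        rng = np.random.default_rng(8)
        g1, g2, g3 = rng.normal(6, 1, size=(3, 5000))
        assert abs(synergy(g1, g2, g3).synergy) < 0.05

    def test_constant_second_argument_reduces_to_single_mi(self):
        rng = np.random.default_rng(9)
        g1 = rng.normal(size=500)
        g3 = g1 + 0.3 * rng.normal(size=500)
        s = synergy(g1, np.full(500, 2.0), g3)
        assert s.mi_2 == 0.0
        assert s.joint_mi == pytest.approx(s.mi_1, abs=0.02)

    def test_joint_mi_at_least_each_marginal(self):
        rng = np.random.default_rng(10)
        g1 = rng.normal(size=1000)
        g2 = rng.normal(size=1000)
        g3 = 0.7 * g1 + 0.3 * g2 + 0.5 * rng.normal(size=1000)
        s = synergy(g1, g2, g3)
        assert s.joint_mi >= max(s.mi_1, s.mi_2) - 0.02


class TestProxyRanking:
    def test_block_probes_dominate_top_ranks(self):
        hits = 0
        for seed in range(5):
            sim = generate_dataset(SimulationConfig(seed=seed))
            table = mi_rank_against_proxy(sim.expression, sim.proxy_probe)
            top20 = set(table["probe_id"].head(20))
            hits += len(top20 & (sim.truth - {sim.proxy_probe}))
        assert hits / (5 * 19) >= 15 / 20

    def test_control_matrix_block_not_associated(self):
        cfg = SimulationConfig(seed=12)
        sim = generate_dataset(cfg)
        ctrl = generate_normal_control(cfg)
        table = mi_rank_against_proxy(ctrl, sim.proxy_probe).set_index("probe_id")
        nulls = sorted(set(ctrl.probe_ids) - sim.truth)
        cutoff = np.quantile(table.loc[nulls, "mi"], 0.95)
        block = sorted(sim.truth - {sim.proxy_probe})
        assert (table.loc[block, "mi"] <= cutoff).all()

    def test_proxy_excluded_and_missing_proxy_errors(self, planted):
        table = mi_rank_against_proxy(planted.expression, planted.proxy_probe)
        assert planted.proxy_probe not in set(table["probe_id"])
        with pytest.raises(KeyError):
            mi_rank_against_proxy(planted.expression, "NOPE")

    def test_multi_dataset_average_restricted_to_shared_probes(self, planted):
        half = planted.expression.subset_probes(planted.expression.probe_ids[:500])
        if planted.proxy_probe not in half.probe_ids:
            half = planted.expression.subset_probes(
                planted.expression.probe_ids[:499] + [planted.proxy_probe]
            )
        table = mi_rank_against_proxy([planted.expression, half], planted.proxy_probe)
        assert set(table["probe_id"]) <= set(half.probe_ids)


class TestSynergySearch:
    def test_planted_pair_ranks_first(self):
        wins = 0
        for seed in range(3):
            sim = generate_dataset(
                SimulationConfig(n_probes=60, n_samples=300, include_synergy_triple=True, seed=seed)
            )
            a, b, t = sim.synergy_triple
            table = exhaustive_synergy_search(sim.expression, t)
            wins += {table["probe_1"].iloc[0], table["probe_2"].iloc[0]} == {a, b}
        assert wins >= 2

    def test_two_candidates_single_pair(self, planted):
        probes = planted.expression.probe_ids
        table = exhaustive_synergy_search(
            planted.expression, probes[0], candidate_probes=probes[1:3]
        )
        assert len(table) == 1

    def test_repeat_search_identical(self):
        sim = generate_dataset(
            SimulationConfig(n_probes=30, n_samples=200, include_synergy_triple=True, seed=3)
        )
        t = sim.synergy_triple[2]
        a = exhaustive_synergy_search(sim.expression, t)
        b = exhaustive_synergy_search(sim.expression, t)
        assert a.equals(b)

    def test_variance_prefilter_bounds_search(self, planted):
        table = exhaustive_synergy_search(
            planted.expression, planted.expression.probe_ids[0], top_v=5, top=100
        )
        assert len(table) == 10  # C(5,2)


class TestGumbelNull:
    def test_parameter_recovery_from_gumbel_samples(self):
        rng = np.random.default_rng(13)
        maxima = rng.gumbel(loc=0.0, scale=1.0, size=500)
        null = fit_gumbel_null(None, maxima=maxima)
        assert abs(null.location) <= 0.1
        assert 0.9 <= null.scale <= 1.1

    def test_pvalue_identities(self):
        rng = np.random.default_rng(14)
        null = fit_gumbel_null(None, maxima=rng.gumbel(2.0, 0.5, size=200))
        assert null.pvalue(null.location) == pytest.approx(1 - np.exp(-1))
        assert gumbel_pvalue(null.location + 100 * null.scale, null) < 1e-10
        assert gumbel_pvalue(null.location - 10 * null.scale, null) == pytest.approx(1.0)
        xs = np.linspace(null.location, null.location + 3 * null.scale, 25)
        ps = [null.pvalue(x) for x in xs]
        assert all(p1 > p2 for p1, p2 in zip(ps, ps[1:]))

    def test_permutation_maxima_seeded_and_shaped(self):
        rng = np.random.default_rng(15)
        y = rng.normal(size=50)
        fn = lambda perm: float(perm[:10].max())
        a = permutation_maxima(fn, y, n_permutations=30, seed=1)
        b = permutation_maxima(fn, y, n_permutations=30, seed=1)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (30,)

    def test_degenerate_maxima_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gumbel_null(None, maxima=np.ones(50))
        with pytest.raises(ValueError, match="permutations"):
            fit_gumbel_null(lambda p: 0.0, labels=np.arange(10), n_permutations=5)

    def test_planted_synergy_significant_under_permutation_null(self):
        """The gate pair's synergy is far out in the permutation-maximum null."""
        sim = generate_dataset(
            SimulationConfig(n_probes=40, n_samples=200, include_synergy_triple=True, seed=4)
        )
        a_id, b_id, t_id = sim.synergy_triple
        ds = sim.expression
        observed = exhaustive_synergy_search(ds, t_id)["synergy"].iloc[0]

        idx = ds.probe_ids.index(t_id)

        def max_score(perm_target):
            m = ds.matrix.copy()
            m[idx] = perm_target
            from evasig.datasets import ExpressionDataset

            shuffled = ExpressionDataset(ds.probe_ids, ds.sample_ids, m)
            return float(
                exhaustive_synergy_search(shuffled, t_id, top=1)["synergy"].iloc[0]
            )

        null = fit_gumbel_null(max_score, ds.probe_values(t_id), n_permutations=30, seed=2)
        assert gumbel_pvalue(observed, null) < 1e-3
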