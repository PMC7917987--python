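"""SNP-effect back-solving, DGV extraction and the weighting strategies."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stepweight.genomic import allele_frequencies, build_G, center_genotypes
from stepweight.mixed_model import VarianceComponents, ssgblup
from stepweight.weighting import (
    IterationTrace,
    SnpEffects,
    WeightingError,
    WeightState,
    WeightStrategy,
    backsolve_snp_effects,
    compute_dgv,
    normalize_weights,
    run_weighting_iterations,
    snp_variances,
    strategy_weights,
    weight_constant,
    weight_default,
    weight_nonlinear_a,
    window_weights,
)

STRATEGY_NAMES = ("default", "constant", "nonlinearA",
                  "window_largest", "window_mean", "window_summed")


def effects_from(u, p=None, iteration=2):
    u = np.asarray(u, dtype=float)
    p = np.full(len(u), 0.5) if p is None else np.asarray(p)
    return SnpEffects(u_hat=u, var_u=snp_variances(u, p), iteration=iteration)


def snp_map_for(m, chrom=None):
    return pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)],
        "chrom": np.ones(m, dtype=int) if chrom is None else chrom,
        "pos_bp": np.arange(1, m + 1) * 1000,
    })


class TestBacksolve:
    def _instance(self, seed=0, n=20, m=50):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(n, m)).astype(float)
        p = rng.uniform(0.1, 0.9, size=m)  # external p keeps G full rank
        M = center_genotypes(g, p)
        d = rng.uniform(0.5, 2.0, size=m)
        G = build_G(M, p, d)
        return M, p, d, G

    def test_zero_gebv_gives_zero_effects(self):
        M, p, d, G = self._instance()
        u = backsolve_snp_effects(d, M, np.linalg.inv(G), np.zeros(20), p)
        assert np.all(u == 0.0)

    def test_reconstructs_gebv_for_invertible_G(self):
        M, p, d, G = self._instance()
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        u = backsolve_snp_effects(d, M, np.linalg.inv(G), a, p)
        assert np.abs(M @ u - a).max() < 1e-8

    def test_linearity(self):
        M, p, d, G = self._instance(seed=2)
        Gi = np.linalg.inv(G)
        a = np.random.default_rng(2).normal(size=20)
        u1 = backsolve_snp_effects(d, M, Gi, a, p)
        u2 = backsolve_snp_effects(d, M, Gi, 2 * a, p)
        assert np.abs(u2 - 2 * u1).max() < 1e-12

    def test_dimension_mismatch(self):
        M, p, d, G = self._instance()
        with pytest.raises(WeightingError, match="dimension"):
            backsolve_snp_effects(d[:-1], M, np.linalg.inv(G), np.zeros(20), p)


class TestDgv:
    def test_unrelated_animals_have_zero_dgv(self):
        assert compute_dgv(np.diag([2.0, 3.0]), np.array([1.0, -1.0])) == pytest.approx([0, 0])

    def test_two_by_two_arithmetic(self):
        Ginv = np.array([[2.0, -1.0], [-1.0, 2.0]])
        assert compute_dgv(Ginv, np.array([4.0, 2.0])) == pytest.approx([1.0, 2.0])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        B = rng.normal(size=(6, 10))
        Gi = np.linalg.inv(B @ B.T / 10 + 0.1 * np.eye(6))
        gebv = rng.normal(size=6)
        perm = rng.permutation(6)
        direct = compute_dgv(Gi, gebv)[perm]
        permuted = compute_dgv(Gi[np.ix_(perm, perm)], gebv[perm])
        assert np.abs(direct - permuted).max() < 1e-12


class TestSingleSnpStrategies:
    def test_default_scalar(self):
        eff = effects_from([1.0])  # p = 0.5 -> 2*0.25*1 = 0.5
        assert weight_default(eff) == pytest.approx([0.5])

    def test_default_zero_effect(self):
        assert weight_default(effects_from([0.0])) == pytest.approx([0.0])

    def test_default_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        u = rng.normal(size=40)
        p = rng.uniform(0.05, 0.95, size=40)
        eff = effects_from(u, p)
        oracle = np.array([2 * p[i] * (1 - p[i]) * u[i] ** 2 for i in range(40)])
        assert weight_default(eff) == pytest.approx(oracle, abs=0)

    def test_constant_arithmetic(self):
        eff = SnpEffects(u_hat=np.zeros(2), var_u=np.array([0.1, 0.3]), iteration=2)
        assert weight_constant(eff, 0.3) == pytest.approx([0.4, 0.6])
        assert weight_constant(eff, 0.3).min() >= 0.3

    def test_constant_with_null_effects_reduces_to_unweighted(self):
        eff = SnpEffects(u_hat=np.zeros(4), var_u=np.zeros(4), iteration=2)
        d = normalize_weights(weight_constant(eff, 0.7))
        assert d == pytest.approx(np.ones(4))

    def test_constant_requires_positive_c(self):
        with pytest.raises(WeightingError, match="positive"):
            weight_constant(effects_from([1.0]), 0.0)

    def test_nonlinear_a_unit_at_two_sd(self):
        u = np.array([2.0, -2.0, 1.0, -1.0, 0.5, -0.5])
        sd = np.std(u, ddof=1)
        eff = effects_from(u)
        d = weight_nonlinear_a(eff, ct=1.25, cap=5.0)
        at_2sd = np.isclose(np.abs(u) / sd, 2.0)
        assert np.allclose(d[at_2sd], 1.0)

    def test_nonlinear_a_arithmetic_and_caps(self):
        u = np.array([1.0, 40.0])
        sd = np.std(u, ddof=1)
        d = weight_nonlinear_a(effects_from(u), ct=1.125, cap=20.0)
        assert d == pytest.approx(np.minimum(1.125 ** (np.abs(u) / sd - 2), 20.0))
        big = np.array([0.1] * 100 + [40.0])  # uncapped weight would be ~1.25**8
        d5 = weight_nonlinear_a(effects_from(big), ct=1.25, cap=5.0)
        assert d5[-1] == 5.0  # cap binds

    def test_nonlinear_a_degenerate_sd(self):
        with pytest.warns(UserWarning, match="sd"):
            d = weight_nonlinear_a(effects_from(np.full(5, 1.0)), 1.25, 5.0)
        assert np.all(d == 1.0)


class TestWindowStrategies:
    def test_constant_variances(self):
        eff = SnpEffects(u_hat=np.zeros(6), var_u=np.full(6, 2.0), iteration=2)
        m = snp_map_for(6)
        assert window_weights(eff, m, 3, "largest") == pytest.approx(np.full(6, 2.0))
        assert window_weights(eff, m, 3, "mean") == pytest.approx(np.full(6, 2.0))
        assert window_weights(eff, m, 3, "summed") == pytest.approx(np.full(6, 6.0))

    def test_worked_example_size_two(self):
        eff = SnpEffects(u_hat=np.zeros(4), var_u=np.array([1.0, 3.0, 2.0, 8.0]), iteration=2)
        m = snp_map_for(4)
        assert window_weights(eff, m, 2, "largest") == pytest.approx([3, 3, 8, 8])
        assert window_weights(eff, m, 2, "mean") == pytest.approx([2, 2, 5, 5])
        assert window_weights(eff, m, 2, "summed") == pytest.approx([4, 4, 10, 10])

    def test_windows_do_not_span_chromosomes(self):
        chrom = np.array([1, 1, 1, 2, 2])
        eff = SnpEffects(u_hat=np.zeros(5), var_u=np.array([1, 5, 2, 7, 3.0]), iteration=2)
        d = window_weights(eff, snp_map_for(5, chrom), 2, "largest")
        assert d == pytest.approx([5, 5, 2, 7, 7])

    @pytest.mark.parametrize("size", [25, 50, 75, 100])
    @pytest.mark.parametrize("mode", ["largest", "mean", "summed"])
    def test_matches_brute_force_oracle(self, size, mode):
        rng = np.random.default_rng(size)
        mvar = rng.exponential(size=321)
        chrom = np.repeat([1, 2], [160, 161])
        eff = SnpEffects(u_hat=np.zeros(321), var_u=mvar, iteration=2)
        got = window_weights(eff, snp_map_for(321, chrom), size, mode)
        oracle = np.empty(321)
        fn = {"largest": np.max, "mean": np.mean, "summed": np.sum}[mode]
        for start, stop in ((0, 160), (160, 321)):
            for lo in range(start, stop, size):
                hi = min(lo + size, stop)
                oracle[lo:hi] = fn(mvar[lo:hi])
        assert got == pytest.approx(oracle, rel=1e-12)
        # piecewise-constant within every window
        for start, stop in ((0, 160), (160, 321)):
            for lo in range(start, stop, size):
                hi = min(lo + size, stop)
                assert np.unique(got[lo:hi]).size == 1

    def test_invalid_size(self):
        with pytest.raises(WeightingError, match="window size"):
            window_weights(effects_from([1.0]), snp_map_for(1), 0, "mean")


class TestNormalize:
    def test_constant_rescales_to_one(self):
        assert normalize_weights(np.full(100, 0.5)) == pytest.approx(np.ones(100))

    def test_two_element_example(self):
        assert normalize_weights(np.array([1.0, 3.0])) == pytest.approx([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1e6), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_sums_to_m_and_positive(self, raw):
        raw = np.asarray(raw)
        if raw.sum() == 0.0:
            with pytest.raises(WeightingError):
                normalize_weights(raw)
            return
        d = normalize_weights(raw)
        assert abs(d.sum() - len(d)) < 1e-10
        assert np.all(d > 0)

    def test_zero_floor_keeps_positive(self):
        d = normalize_weights(np.array([0.0, 1.0]))
        assert d[0] > 0 and d.sum() == pytest.approx(2.0)


class TestIterationLoop:
    @pytest.fixture(scope="class")
    def setup(self, small_herd):
        herd = small_herd
        scn = herd.scenario
        phen = herd.phenotypes.set_index("animal")
        train = phen[phen["birth_year"] <= scn.cutoff_year]
        y = train[scn.trait]
        vc = VarianceComponents(scn.sigma_a2, scn.sigma_e2)
        return herd, y, vc

    def test_first_iteration_equals_unweighted_ssgblup(self, setup):
        herd, y, vc = setup
        base = ssgblup(herd.pedigree, herd.panel, y, vc)
        for name in STRATEGY_NAMES:
            tr = run_weighting_iterations(
                herd.pedigree, herd.panel, y, vc,
                strategy=WeightStrategy(name=name, window_size=10), n_iter=1,
            )
            assert len(tr) == 1
            assert np.all(tr[0].weights.d == 1.0)
            assert np.abs(tr[0].gebv.to_numpy() - base.a.to_numpy()).max() < 1e-8

    def test_trace_invariants_all_strategies(self, setup):
        herd, y, vc = setup
        for name in STRATEGY_NAMES:
            strat = WeightStrategy(name=name, window_size=10)
            tr = run_weighting_iterations(herd.pedigree, herd.panel, y, vc,
                                          strategy=strat, n_iter=3)
            assert len(tr) == 3
            m = herd.panel.m
            for rec in tr.records:
                assert rec.weights.d.sum() == pytest.approx(m, abs=1e-8)
                assert np.all(rec.weights.d > 0)
            if name.startswith("window_"):
                # piecewise-constant within windows that never cross chromosomes
                d = tr[2].weights.d
                chrom = herd.panel.snp_map["chrom"].to_numpy()
                for c in np.unique(chrom):
                    idx = np.flatnonzero(chrom == c)
                    for lo in range(0, len(idx), 10):
                        grp = idx[lo:lo + 10]
                        assert np.unique(np.round(d[grp], 12)).size == 1

    def test_constant_ranking_more_stable_than_default(self, setup):
        from scipy.stats import spearmanr

        herd, y, vc = setup

        def mean_rank_stability(name):
            tr = run_weighting_iterations(
                herd.pedigree, herd.panel, y, vc,
                strategy=WeightStrategy(name=name), n_iter=4,
            )
            cors = []
            for t in range(1, len(tr) - 1):
                cors.append(spearmanr(tr[t].weights.d, tr[t + 1].weights.d).statistic)
            return np.mean(cors)

        assert mean_rank_stability("constant") >= mean_rank_stability("default")

    def test_weight_concentration_grows_on_oligogenic_trait(self, oligo_default_runs):
        """Default weighting progressively piles weight on the large QTL."""
        def gini(x):
            x = np.sort(np.asarray(x))
            n = len(x)
            return float((2 * np.arange(1, n + 1) - n - 1) @ x / (n * x.sum()))

        trace = oligo_default_runs[1].traces["default"]
        gs = [gini(rec.weights.d) for rec in trace.records[1:6]]  # iterations 2..6
        assert np.all(np.diff(gs) > 0)

    def test_invalid_iteration_count(self, setup):
        herd, y, vc = setup
        with pytest.raises(WeightingError, match="n_iter"):
            run_weighting_iterations(herd.pedigree, herd.panel, y, vc, n_iter=0)


def test_weight_state_validation():
    with pytest.raises(WeightingError):
        WeightState(d=np.array([1.0, -0.5]), iteration=2, strategy=WeightStrategy())
    with pytest.raises(WeightingError, match="unknown strategy"):
        WeightStrategy(name="bogus")
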