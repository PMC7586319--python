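"""Weighted ANOVA, BH adjustment, tolerance-interval benchmark, and the gene ladder."""

import numpy as np
import pytest
import scipy.stats

from salsa import (
    GeneStratifier,
    SnrBenchmark,
    bh_adjust,
    pairwise_contrasts,
    snr_benchmark,
    stratify,
    weighted_anova,
)
from salsa.stratification import STRATA_ORDER, StratumStats, resolution_weights
import scipy.sparse as sp


class TestWeights:
    def test_uniform_coverage_gives_unit_weights(self):
        upt = sp.csr_matrix(np.full((4, 10), 2.0))
        w = resolution_weights(upt)
        assert np.allclose(w, 1.0)

    def test_double_coverage_at_equal_cv_doubles_weight(self):
        a = np.array([1.0, 2.0, 3.0, 2.0])
        upt = sp.csr_matrix(np.vstack([a, 2 * a]))
        w = resolution_weights(upt)
        assert w[1] / w[0] == pytest.approx(2.0)

    def test_representation_flag_controls_cluster_dependence(self):
        from salsa import representation_rates
        from salsa.stratification import observation_weights
        from conftest import toy_stack

        stack = toy_stack([(0, 0, 1), (0, 1, 1), (0, 2, 1)], 1, 4)
        rep = representation_rates(stack, {0: 0, 1: 0, 2: 1, 3: 1})
        w_res = np.ones(1)
        with_rep = [observation_weights(0, k, rep, w_res, True) for k in (0, 1)]
        without = [observation_weights(0, k, rep, w_res, False) for k in (0, 1)]
        assert with_rep[0] != with_rep[1]
        assert without[0] == without[1]


class TestWeightedAnova:
    def test_unit_weights_match_closed_form_f(self):
        # 3 clusters x 5 observations, textbook one-way ANOVA
        rng = np.random.default_rng(0)
        table = rng.normal([0, 1, 3], 1.0, size=(5, 3)).T
        values = table.ravel()
        groups = np.repeat([0, 1, 2], 5)
        f, p = weighted_anova(values, groups, np.ones(15))
        f_ref, p_ref = scipy.stats.f_oneway(*table)
        assert f == pytest.approx(f_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(42)
        ps = []
        for _ in range(500):
            x = rng.standard_normal(40)
            g = np.repeat([0, 1], 20)
            ps.append(weighted_anova(x, g, np.ones(40))[1])
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_strong_separation_detected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.5, 30), rng.normal(3, 0.5, 30)])
        g = np.repeat([0, 1], 30)
        assert weighted_anova(x, g, np.ones(60))[1] < 1e-6

    def test_single_usable_cluster_gives_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 9.0])
        g = np.array([0, 0, 0, 1])
        assert weighted_anova(x, g, np.ones(4))[1] == 1.0

    def test_zero_residuals_give_p_zero(self):
        x = np.array([1.0, 1.0, 5.0, 5.0])
        g = np.array([0, 0, 1, 1])
        f, p = weighted_anova(x, g, np.ones(4))
        assert p == 0.0 and np.isinf(f)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_stay_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_empty_input(self):
        assert bh_adjust([]).size == 0

    def test_q_at_least_p(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)


class TestSnrBenchmark:
    def test_asymptotic_limit_is_z_score(self):
        rng = np.random.default_rng(0)
        bench = snr_benchmark(rng.standard_normal(100_000))
        assert bench.ti_halfwidth == pytest.approx(1.960, rel=0.005)

    def test_zero_residuals_give_zero_halfwidth(self):
        assert snr_benchmark(np.zeros(10)).ti_halfwidth == 0.0

    def test_finite_sample_factor_exceeds_asymptote(self):
        rng = np.random.default_rng(1)
        r = rng.standard_normal(50)
        s = r.std(ddof=1)
        assert snr_benchmark(r).ti_halfwidth / s > 1.96

    def test_too_few_residuals_rejected(self):
        with pytest.raises(ValueError):
            snr_benchmark(np.ones(2))

    def test_nonparametric_option(self):
        rng = np.random.default_rng(2)
        r = rng.standard_normal(10_000)
        hw = snr_benchmark(r, method="nonparametric").ti_halfwidth
        assert hw == pytest.approx(np.quantile(np.abs(r), 0.975), rel=1e-12)


class TestPairwiseContrasts:
    def test_identical_clusters_have_zero_delta(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.repeat([0, 1], 3)
        out = pairwise_contrasts(x, g, np.ones(6), ti_halfwidth=1.0)
        assert out[(0, 1)]["delta"] == pytest.approx(0.0)
        assert not out[(0, 1)]["exclusive"]

    def test_unit_weights_match_welch_oracle(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 2, 17)
        x = np.concatenate([a, b])
        g = np.repeat([0, 1], [12, 17])
        out = pairwise_contrasts(x, g, np.ones(29), ti_halfwidth=1.0)
        t_ref = scipy.stats.ttest_ind(a, b, equal_var=False)
        assert out[(0, 1)]["p"] == pytest.approx(t_ref.pvalue, abs=1e-10)
        assert out[(0, 1)]["delta"] == pytest.approx(a.mean() - b.mean(), abs=1e-12)

    def test_wide_separation_is_exclusive(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 0.01, 20), rng.normal(3, 0.01, 20)])
        g = np.repeat([0, 1], 20)
        out = pairwise_contrasts(x, g, np.ones(40), ti_halfwidth=1.0)
        assert out[(0, 1)]["exclusive"]

    def test_singleton_cluster_gets_p_one(self):
        x = np.array([1.0, 2.0, 9.0])
        g = np.array([0, 0, 1])
        out = pairwise_contrasts(x, g, np.ones(3), ti_halfwidth=1.0)
        assert out[(0, 1)]["p"] == 1.0


def make_stats(gene, q_anova, max_abs_mean, pair_q, delta, q_unw, exclusive=None):
    st = StratumStats(gene=gene, f_stat=1.0, p_anova=q_anova, q_anova=q_anova,
                      max_abs_mean=max_abs_mean, p_unweighted=q_unw, q_unweighted=q_unw)
    excl = exclusive if exclusive is not None else abs(delta) > 2.0
    st.pairwise = {(0, 1): {"delta": delta, "p": pair_q, "q": pair_q, "exclusive": excl}}
    st.cluster_means = {0: max_abs_mean, 1: 0.0}
    return st


class TestStratify:
    BENCH = SnrBenchmark(ti_halfwidth=1.0, coverage=0.95, confidence=0.95, n_residuals=100)

    def test_full_ladder_assignment(self):
        stats = {
            0: make_stats(0, q_anova=0.5, max_abs_mean=0.1, pair_q=1, delta=0, q_unw=1),
            1: make_stats(1, q_anova=0.01, max_abs_mean=0.5, pair_q=1, delta=0, q_unw=1),
            2: make_stats(2, q_anova=0.01, max_abs_mean=2.0, pair_q=0.5, delta=0.1, q_unw=1),
            3: make_stats(3, q_anova=0.01, max_abs_mean=2.0, pair_q=0.01, delta=3.0, q_unw=0.5),
            4: make_stats(4, q_anova=0.01, max_abs_mean=2.0, pair_q=0.01, delta=3.0, q_unw=0.01),
        }
        out = stratify(stats, self.BENCH, alpha=0.05)
        assert out.strata == {0: "facultative_only", 1: "SG", 2: "LSTNR",
                              3: "DEGREE", 4: "Profiler"}

    def test_overlapping_intervals_block_deg(self):
        # significant pairwise contrast but non-exclusive intervals
        st = make_stats(0, q_anova=0.01, max_abs_mean=2.0, pair_q=0.001,
                        delta=1.5, q_unw=0.001, exclusive=False)
        out = stratify({0: st}, self.BENCH, alpha=0.05)
        assert out.strata[0] == "LSTNR"

    def test_alpha_zero_empties_upper_strata(self):
        st = make_stats(0, q_anova=0.001, max_abs_mean=5.0, pair_q=0.001,
                        delta=5.0, q_unw=0.001)
        out = stratify({0: st}, self.BENCH, alpha=0.0)
        assert out.strata[0] == "facultative_only"

    def test_alpha_monotonicity(self):
        stats = {i: make_stats(i, q_anova=0.02 * i, max_abs_mean=2.0,
                               pair_q=0.02 * i, delta=3.0, q_unw=0.02 * i)
                 for i in range(1, 6)}
        order = list(STRATA_ORDER)

        def level_sets(alpha):
            out = stratify(stats, self.BENCH, alpha=alpha)
            return {lvl: {g for g, s in out.strata.items()
                          if order.index(s) >= order.index(lvl)} for lvl in order[1:]}

        small, large = level_sets(0.03), level_sets(0.09)
        for lvl in small:
            assert small[lvl] <= large[lvl]


@pytest.fixture(scope="module")
def planted_run():
    """Default planted fixture scored on true majors, stratified once."""
    from salsa import ExpressionScorer, SimulationConfig, simulate_stack

    cfg = SimulationConfig(seed=11)
    stack, truth = simulate_stack(cfg)
    fac = sorted(g for g, r in truth.gene_regime.items() if r == "facultative")
    focused = stack.subset(gene_idx=fac)
    ss = ExpressionScorer().fit_transform(focused, full_stack=stack)
    majors = {c: truth.cell_type[c] for c in truth.cell_type}
    strat = GeneStratifier().fit(ss, majors)
    fac_pos = {g: i for i, g in enumerate(fac)}
    sig = {fac_pos[g] for genes in truth.de_genes.values() for g in genes}
    return strat, sig


class TestLadderOnPlantedFixture:
    def test_strata_nesting_is_structural(self, planted_run):
        strat, _ = planted_run
        order = list(STRATA_ORDER)
        gs = strat.strata_
        nested = {lvl: {g for g, s in gs.strata.items()
                        if order.index(s) >= order.index(lvl)} for lvl in order}
        for lo, hi in zip(order, order[1:]):
            assert nested[hi] <= nested[lo]

    def test_signature_genes_reach_profiler(self, planted_run):
        strat, sig = planted_run
        prof = {g for g, s in strat.strata_.strata.items() if s == "Profiler"}
        assert len(prof & sig) / len(sig) >= 0.9
        assert len(prof - sig) <= 5

    def test_degree_membership_independent_of_ablation_layer(self, planted_run):
        strat, _ = planted_run
        order = list(STRATA_ORDER)
        degree_or_higher = {g for g, s in strat.strata_.strata.items()
                            if order.index(s) >= order.index("DEGREE")}
        # recompute the ladder with every q_unweighted forced to 1: DEGREE
        # and below must not move, only Profiler membership may
        import copy

        stats2 = copy.deepcopy(strat.stats_)
        for st in stats2.values():
            st.p_unweighted = 1.0
        out2 = stratify(stats2, strat.benchmark_, alpha=strat.alpha)
        degree2 = {g for g, s in out2.strata.items()
                   if order.index(s) >= order.index("DEGREE")}
        assert degree2 == degree_or_higher
        assert not any(s == "Profiler" for s in out2.strata.values())

    def test_retained_barcodes_express_a_profiler(self, planted_run):
        strat, _ = planted_run
        gs = strat.strata_
        prof = sorted(g for g, s in gs.strata.items() if s == "Profiler")
        stack = strat.stats_[prof[0]] if False else None
        assert gs.retained_barcodes  # non-empty on the planted fixture


class TestNullCalibration:
    def test_sg_count_controlled_under_global_null(self):
        """BH at alpha=0.05 yields few significant genes with no planted effects."""
        from salsa import ExpressionScorer, SimulationConfig, simulate_stack

        counts = []
        for seed in range(6):
            cfg = SimulationConfig(seed=100 + seed, n_signature_genes_per_type=0,
                                   n_null_facultative=300, n_rare=300,
                                   n_constitutive=30, cells_per_type=100,
                                   ambient_barcodes=0, doublet_fraction=0.0)
            stack, truth = simulate_stack(cfg)
            fac = sorted(g for g, r in truth.gene_regime.items() if r == "facultative")
            focused = stack.subset(gene_idx=fac)
            ss = ExpressionScorer().fit_transform(focused, full_stack=stack)
            rng = np.random.default_rng(seed)
            majors = {c: int(rng.integers(0, 5)) for c in range(focused.n_barcodes)}
            strat = GeneStratifier().fit(ss, majors)
            counts.append(sum(1 for s in strat.strata_.strata.values()
                              if s != "facultative_only"))
        n_genes = 300
        assert np.median(counts) <= 0.05 * n_genes * 1.5
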