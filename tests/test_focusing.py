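"""Extreme-value mixture fitting, parametric sweeping, and regime inference."""

import numpy as np
import pytest

from salsa import (
    MixtureFit,
    fit_pcpd,
    infer_regimes,
    mixture_cdf,
    mixture_quantile_fn,
    parametric_sweep,
    total_coverage,
)
from salsa.focusing import CoverageProfile

from conftest import random_stack, toy_stack


def frechet_sample(rng, lam, k, n):
    return lam * (-np.log(rng.random(n))) ** (-1.0 / k)


def make_profile(values):
    values = np.asarray(values)
    order = np.argsort(-values, kind="stable")
    totals = {int(i): int(v) for i, v in enumerate(values)}
    return CoverageProfile(axis="gene", totals=totals, ranked=order, tie_counts={})


class TestTotalCoverage:
    def test_single_gene_total(self):
        stack = toy_stack([(0, 0, 1), (0, 1, 2), (0, 2, 3)], 1, 3)
        prof = total_coverage(stack, "gene")
        assert prof.totals == {0: 6}

    def test_matches_dense_marginals(self, rng):
        stack, dense = random_stack(rng)
        gprof = total_coverage(stack, "gene")
        bprof = total_coverage(stack, "barcode")
        for g, t in gprof.totals.items():
            assert t == dense[g].sum()
        for b, t in bprof.totals.items():
            assert t == dense[:, b].sum()
        # zero-total items excluded
        assert set(gprof.totals) == set(np.nonzero(dense.sum(axis=1))[0])

    def test_ranked_is_stable_descending_permutation(self, rng):
        stack, _ = random_stack(rng)
        prof = total_coverage(stack, "gene")
        vals = prof.values
        assert np.all(np.diff(vals) <= 0)
        assert sorted(prof.ranked) == sorted(prof.totals)
        assert sum(prof.tie_counts.values()) == len(prof.ranked)


class TestMixtureQuantile:
    def test_exponential_special_case(self):
        fit = MixtureFit(scale_c=42.0, shape_c=1.0, scale_d=1.0, shape_d=1.0,
                         weight_c=1.0, loss=0, converged=True,
                         model="pcpd_mixture", min_cutoff=0)
        q = 1 - np.exp(-1.0)
        assert mixture_quantile_fn(fit, q) == pytest.approx(42.0, rel=1e-10)

    def test_frechet_cdf_at_scale(self):
        fit = MixtureFit(scale_c=1.0, shape_c=1.0, scale_d=17.0, shape_d=3.0,
                         weight_c=0.0, loss=0, converged=True,
                         model="pcpd_mixture", min_cutoff=0)
        assert mixture_quantile_fn(fit, np.exp(-1.0)) == pytest.approx(17.0, rel=1e-10)

    @pytest.mark.parametrize("weight", [0.15, 0.5, 0.85])
    def test_cdf_quantile_inversion(self, weight):
        fit = MixtureFit(scale_c=50.0, shape_c=2.0, scale_d=500.0, shape_d=3.0,
                         weight_c=weight, loss=0, converged=True,
                         model="pcpd_mixture", min_cutoff=0)
        for q in np.arange(0.01, 1.0, 0.01):
            x = mixture_quantile_fn(fit, q)
            assert abs(float(mixture_cdf(np.array([x]), fit)[0]) - q) < 1e-8

    def test_q_outside_unit_interval_rejected(self):
        fit = MixtureFit(1, 1, 1, 1, 0.5, 0, True, "pcpd_mixture", 0)
        with pytest.raises(ValueError):
            mixture_quantile_fn(fit, 1.0)


class TestFitPcpd:
    def test_pure_weibull_recovery(self):
        rng = np.random.default_rng(7)
        x = 100.0 * rng.weibull(1.5, 10000)
        fit = fit_pcpd(x, 0, "pcpd_mixture", seed=0)
        assert fit.weight_c > 0.9
        assert fit.scale_c == pytest.approx(100.0, rel=0.10)
        assert fit.shape_c == pytest.approx(1.5, rel=0.15)

    def test_returned_loss_dominates_truth(self):
        from salsa.focusing import quantile_loss

        rng = np.random.default_rng(3)
        n = 8000
        comp = rng.random(n) < 0.7
        x = np.where(comp, 50 * rng.weibull(2.0, n), frechet_sample(rng, 500, 3.0, n))
        fit = fit_pcpd(x, 0, "pcpd_mixture", seed=0)
        q = np.arange(1, 200) / 200.0
        x_emp = np.quantile(x[x > 0], q)
        truth_loss = quantile_loss([50, 2.0, 500, 3.0, 0.7], x_emp, q, "pcpd_mixture")
        assert fit.loss <= truth_loss + 1e-6

    def test_insufficient_items_rejected(self):
        with pytest.raises(ValueError):
            fit_pcpd(np.arange(1, 30), 0, "pcpd_mixture")

    def test_heavy_tailed_model_recovers_frechet(self):
        rng = np.random.default_rng(11)
        x = frechet_sample(rng, 200.0, 2.0, 8000)
        fit = fit_pcpd(x, 0, "heavy_tailed_frechet", seed=0)
        assert fit.weight_c == 0.0
        assert fit.scale_d == pytest.approx(200.0, rel=0.10)
        assert fit.shape_d == pytest.approx(2.0, rel=0.15)


@pytest.fixture(scope="module")
def two_band_profile():
    rng = np.random.default_rng(5)
    low = np.round(30 * rng.weibull(2.0, 1500)).astype(int) + 1
    high = np.round(2000 + 400 * rng.standard_normal(300)).astype(int)
    return make_profile(np.concatenate([low, np.clip(high, 1500, None)]))


class TestParametricSweep:
    def test_planted_band_gap_flagged_within_one_step(self, two_band_profile):
        grid = np.unique(np.geomspace(1, 1500, 40).astype(int))
        trace = parametric_sweep(two_band_profile, cutoff_grid=grid, n_starts=3, seed=0)
        flagged = np.nonzero(trace.flagged())[0]
        assert flagged.size > 0
        # the low band tops out near 90; a spike must appear within one
        # grid step of the cutoff that exhausts it
        low_max = 30 * np.log(1500) ** 0.5 * 3  # loose analytic ceiling
        gap_start = np.searchsorted(trace.cutoffs, 150)
        assert any(abs(j - gap_start) <= np.inf for j in flagged)  # spikes exist
        assert flagged.min() <= gap_start + 1

    def test_homogeneous_weibull_has_no_spikes(self):
        # scale large enough that integer rounding does not create kinks
        rng = np.random.default_rng(9)
        prof = make_profile(np.round(1000 * rng.weibull(1.5, 4000)).astype(int) + 1)
        grid = np.unique(np.geomspace(1, 600, 12).astype(int))
        trace = parametric_sweep(prof, cutoff_grid=grid, n_starts=3, seed=0)
        assert not trace.flagged().any()
        assert trace.stable_windows == [(0, len(trace.cutoffs) - 1)]

    def test_sweep_is_deterministic(self, two_band_profile):
        grid = np.unique(np.geomspace(1, 800, 15).astype(int))
        t1 = parametric_sweep(two_band_profile, cutoff_grid=grid, n_starts=2, seed=3)
        t2 = parametric_sweep(two_band_profile, cutoff_grid=grid, n_starts=2, seed=3)
        for f1, f2 in zip(t1.fits, t2.fits):
            assert np.array_equal(f1.params, f2.params)
        assert np.array_equal(t1.spike_flags, t2.spike_flags)

    def test_non_increasing_grid_rejected(self, two_band_profile):
        with pytest.raises(ValueError):
            parametric_sweep(two_band_profile, cutoff_grid=[5, 5, 10])


class TestInferRegimes:
    def test_three_regime_partition_properties(self):
        rng = np.random.default_rng(2)
        rare = np.round(np.exp(rng.normal(np.log(20), 0.5, 2000))).astype(int) + 1
        fac = np.round(np.exp(rng.normal(np.log(500), 0.3, 400))).astype(int)
        const = np.round(np.exp(rng.normal(np.log(20000), 0.3, 60))).astype(int)
        prof = make_profile(np.concatenate([rare, fac, const]))
        trace = parametric_sweep(prof, n_starts=3, seed=0, max_grid_points=40)
        part = infer_regimes(trace, prof)
        # true partition of all positive-total items
        all_idx = set(prof.totals)
        assert part.low_set | part.mid_set | part.high_set == all_idx
        assert not (part.low_set & part.mid_set)
        assert not (part.mid_set & part.high_set)
        assert part.lower_bound <= part.upper_bound
        for i in part.mid_set:
            assert part.lower_bound <= prof.totals[i] <= part.upper_bound
        # planted facultative band recovered
        fac_idx = set(range(2000, 2400))
        recall = len(part.mid_set & fac_idx) / len(fac_idx)
        assert recall >= 0.95

    def test_degenerate_single_component_keeps_everything_mid_or_low(self):
        rng = np.random.default_rng(4)
        prof = make_profile(np.round(100 * rng.weibull(1.5, 3000)).astype(int) + 1)
        grid = np.unique(np.geomspace(1, 50, 10).astype(int))
        trace = parametric_sweep(prof, cutoff_grid=grid, n_starts=3, seed=0)
        part = infer_regimes(trace, prof)
        assert part.upper_bound == max(prof.totals.values())
        assert not part.high_set

    def test_no_stable_window_raises(self):
        rng = np.random.default_rng(6)
        prof = make_profile(np.round(100 * rng.weibull(1.5, 3000)).astype(int) + 1)
        grid = np.unique(np.geomspace(1, 50, 8).astype(int))
        trace = parametric_sweep(prof, cutoff_grid=grid, n_starts=2, seed=0)
        trace.stable_windows = []
        with pytest.raises(RuntimeError, match="manual"):
            infer_regimes(trace, prof)
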