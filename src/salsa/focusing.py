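"""Parametric matrix focusing via a Weibull-Frechet extreme-value mixture.

Total UMI coverages per gene (or per barcode) in droplet scRNA-seq span
several decades and mix a low-coverage bulk with a heavy upper tail. This
module models the sorted coverage profile as a two-component extreme-value
mixture -- a Weibull "common" component P_C plus a Frechet "dominant"
component P_D -- fit by quantile regression on log coverage. Repeating the
fit while raising a minimum-coverage admission cutoff (the parametric
sweep) exposes numerical-solver "spikes" where the cutoff crosses a regime
boundary; the widest spike-free window yields consensus parameters from
which the rare/facultative/constitutive (genes) or
ambient/singlet/multiplet (barcodes) partition is projected:

* lower bound: smallest integer coverage at which the posterior
  responsibility of the heavy component reaches 1/2;
* upper bound: smallest integer coverage whose survival probability under
  the single heavy-tailed Frechet fit drops below 1/N for the N admitted
  items (an "expect less than one such item" outlier rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator

from .countstack import CountStack

__all__ = [
    "CoverageProfile",
    "MixtureFit",
    "SweepTrace",
    "RegimePartition",
    "total_coverage",
    "mixture_cdf",
    "mixture_pdf",
    "mixture_quantile_fn",
    "fit_pcpd",
    "parametric_sweep",
    "infer_regimes",
    "MatrixFocuser",
]

# log-parameter search box: scales may span the whole coverage range,
# shapes are kept away from degenerate spikes at 0 and vertical walls.
SCALE_BOUNDS = (1e-2, 1e8)
SHAPE_BOUNDS = (0.05, 50.0)
_WEIGHT_EPS = 1e-6
_IDENTIFIABLE = 0.10  # component weight below which its parameters are unidentifiable
MIN_SCALE_SEPARATION = 5.0  # scale ratio below which two components share one regime


# ---------------------------------------------------------------------------
# coverage profiles
# ---------------------------------------------------------------------------

@dataclass
class CoverageProfile:
    """Marginal total-UMI coverages along one axis, zero totals excluded."""

    axis: Literal["gene", "barcode"]
    totals: dict[int, int]
    ranked: np.ndarray          # indices sorted by descending total, ties by index
    tie_counts: dict[int, int]  # 1-based rank of first item at a total -> #items sharing it

    @property
    def values(self) -> np.ndarray:
        return np.asarray([self.totals[i] for i in self.ranked], dtype=np.int64)


def total_coverage(stack: CountStack, axis: Literal["gene", "barcode"]) -> CoverageProfile:
    """Exact marginal totals per gene or per barcode; items with zero total are dropped."""
    sums = np.asarray(stack.matrix.sum(axis=1 if axis == "gene" else 0)).ravel().astype(np.int64)
    pos = np.nonzero(sums > 0)[0]
    totals = {int(i): int(sums[i]) for i in pos}
    order = pos[np.lexsort((pos, -sums[pos]))]  # descending total, stable by index
    vals = sums[order]
    tie_counts: dict[int, int] = {}
    i = 0
    while i < len(vals):
        j = i
        while j < len(vals) and vals[j] == vals[i]:
            j += 1
        tie_counts[i + 1] = j - i
        i = j
    return CoverageProfile(axis=axis, totals=totals, ranked=order, tie_counts=tie_counts)


# ---------------------------------------------------------------------------
# mixture distribution
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    scale_c: float
    shape_c: float
    scale_d: float
    shape_d: float
    weight_c: float
    loss: float
    converged: bool
    model: Literal["pcpd_mixture", "heavy_tailed_frechet"]
    min_cutoff: int
    n_admitted: int = 0

    @property
    def params(self) -> np.ndarray:
        return np.array([self.scale_c, self.shape_c, self.scale_d, self.shape_d, self.weight_c])


def _weibull_cdf(x, lam, k):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = -np.expm1(-((x[pos] / lam) ** k))
    return out


def _frechet_cdf(x, lam, k):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = np.exp(-((x[pos] / lam) ** (-k)))
    return out


def _weibull_pdf(x, lam, k):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    z = x[pos] / lam
    out[pos] = (k / lam) * z ** (k - 1) * np.exp(-(z ** k))
    return out


def _frechet_pdf(x, lam, k):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    z = x[pos] / lam
    out[pos] = (k / lam) * z ** (-k - 1) * np.exp(-(z ** (-k)))
    return out


def mixture_cdf(x, fit: MixtureFit):
    """F_mix(x) = w * F_Weibull(x) + (1 - w) * F_Frechet(x)."""
    w = fit.weight_c
    return w * _weibull_cdf(x, fit.scale_c, fit.shape_c) + (1.0 - w) * _frechet_cdf(
        x, fit.scale_d, fit.shape_d
    )


def mixture_pdf(x, fit: MixtureFit):
    w = fit.weight_c
    return w * _weibull_pdf(x, fit.scale_c, fit.shape_c) + (1.0 - w) * _frechet_pdf(
        x, fit.scale_d, fit.shape_d
    )


def _component_quantiles(q, lam_w, k_w, lam_f, k_f, w):
    qw = lam_w * (-np.log1p(-q)) ** (1.0 / k_w)
    qf = lam_f * (-np.log(q)) ** (-1.0 / k_f)
    return qw, qf


def mixture_quantile_fn(fit: MixtureFit, q: float) -> float:
    """Invert the mixture CDF by bracketed root finding to |F(x) - q| < 1e-10."""
    if not (0.0 < q < 1.0):
        raise ValueError(f"q must lie strictly inside (0, 1); got {q}")
    qw, qf = _component_quantiles(
        np.asarray(q, dtype=float), fit.scale_c, fit.shape_c, fit.scale_d, fit.shape_d, fit.weight_c
    )
    if fit.weight_c >= 1.0 - _WEIGHT_EPS:
        return float(qw)
    if fit.weight_c <= _WEIGHT_EPS:
        return float(qf)
    lo = 0.5 * min(float(qw), float(qf))
    hi = 2.0 * max(float(qw), float(qf))
    f = lambda x: float(mixture_cdf(np.array([x]), fit)[0]) - q
    while f(lo) > 0:
        lo *= 0.5
    while f(hi) < 0:
        hi *= 2.0
    x = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    return float(x)


def _grid_quantiles(theta: np.ndarray, q: np.ndarray, model: str, n_grid: int = 2048) -> np.ndarray:
    """Vectorized model quantiles via monotone log-grid interpolation of the CDF.

    This is the workhorse of the quantile-regression objective; the public
    :func:`mixture_quantile_fn` refines single quantiles to 1e-10 instead.
    """
    if model == "heavy_tailed_frechet":
        lam, k = theta
        return lam * (-np.log(q)) ** (-1.0 / k)
    lam_w, k_w, lam_f, k_f, w = theta
    if w >= 1.0 - _WEIGHT_EPS:
        return lam_w * (-np.log1p(-q)) ** (1.0 / k_w)
    if w <= _WEIGHT_EPS:
        return lam_f * (-np.log(q)) ** (-1.0 / k_f)
    qw, qf = _component_quantiles(q, lam_w, k_w, lam_f, k_f, w)
    lo = 0.25 * min(qw.min(), qf.min())
    hi = 4.0 * max(qw.max(), qf.max())
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n_grid))
    F = w * _weibull_cdf(grid, lam_w, k_w) + (1 - w) * _frechet_cdf(grid, lam_f, k_f)
    F = np.maximum.accumulate(F)
    return np.exp(np.interp(q, F, np.log(grid)))


# ---------------------------------------------------------------------------
# quantile-regression fitting
# ---------------------------------------------------------------------------

def _pack(theta, model):
    if model == "heavy_tailed_frechet":
        return np.log(theta)
    return np.concatenate([np.log(theta[:4]), [theta[4]]])


def _unpack(x, model):
    if model == "heavy_tailed_frechet":
        return np.exp(x)
    return np.concatenate([np.exp(x[:4]), [x[4]]])


def _bounds(model):
    ls, hs = np.log(SCALE_BOUNDS[0]), np.log(SCALE_BOUNDS[1])
    lk, hk = np.log(SHAPE_BOUNDS[0]), np.log(SHAPE_BOUNDS[1])
    if model == "heavy_tailed_frechet":
        return (np.array([ls, lk]), np.array([hs, hk]))
    return (np.array([ls, lk, ls, lk, 0.0]), np.array([hs, hk, hs, hk, 1.0]))


def _initial_starts(x_emp, model, n_starts, rng):
    """Empirical-quantile anchored starts with seeded jitter."""
    q25, q50, q75, q95 = np.quantile(x_emp, [0.25, 0.50, 0.75, 0.95])
    starts = []
    if model == "heavy_tailed_frechet":
        base = np.array([q50, 1.0])
        for i in range(n_starts):
            jit = np.exp(rng.normal(0, 0.5, 2)) if i else np.ones(2)
            starts.append(base * jit)
        return starts
    base = np.array([max(q25, 1.0), 1.0, max(q95, 2.0), 2.0, 0.7])
    for i in range(n_starts):
        if i == 0:
            starts.append(base.copy())
            continue
        jit = np.exp(rng.normal(0, 0.6, 4))
        w = rng.uniform(0.05, 0.95)
        starts.append(np.array([base[0] * jit[0], base[1] * jit[1],
                                base[2] * jit[2], base[3] * jit[3], w]))
    return starts


def quantile_loss(theta: Sequence[float], x_emp: np.ndarray, q: np.ndarray, model: str) -> float:
    """Sum of squared log-quantile deviations, the regression objective."""
    r = np.log(_grid_quantiles(np.asarray(theta, dtype=float), q, model)) - np.log(x_emp)
    return float(np.dot(r, r))


def fit_pcpd(
    profile: CoverageProfile | np.ndarray,
    min_cutoff: int = 0,
    model: Literal["pcpd_mixture", "heavy_tailed_frechet"] = "pcpd_mixture",
    n_quantiles: int = 199,
    n_starts: int = 8,
    seed: int | None = 0,
    extra_starts: Sequence[np.ndarray] = (),
    incumbent_margin: float = 0.02,
) -> MixtureFit:
    """Fit the coverage distribution by bounded multi-start quantile regression.

    Items with total > ``min_cutoff`` are admitted; the objective is the sum
    of squared differences between log model quantiles and log empirical
    quantiles on an even grid, minimized over log-scale/log-shape
    parameters (plus the mixing weight) by trust-region least squares.
    """
    totals = profile.values if isinstance(profile, CoverageProfile) else np.asarray(profile)
    admitted = np.asarray(totals, dtype=float)
    admitted = admitted[admitted > min_cutoff]
    if admitted.size < 50:
        raise ValueError(
            f"only {admitted.size} items exceed cutoff {min_cutoff}; at least 50 required"
        )
    q = (np.arange(1, n_quantiles + 1)) / (n_quantiles + 1)
    x_emp = np.quantile(admitted, q)
    x_emp = np.maximum(x_emp, 1e-9)

    rng = np.random.default_rng(seed)
    starts = list(extra_starts) + _initial_starts(x_emp, model, n_starts, rng)
    lo, hi = _bounds(model)
    log_x_emp = np.log(x_emp)

    def resid(x):
        theta = _unpack(x, model)
        return np.log(np.maximum(_grid_quantiles(theta, q, model), 1e-300)) - log_x_emp

    best = None
    incumbent = None
    for i, s in enumerate(starts):
        x0 = np.clip(_pack(np.asarray(s, dtype=float), model), lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=1200)
        except Exception:  # noqa: BLE001 - a diverging start is not fatal
            continue
        loss = 2.0 * res.cost
        if not np.isfinite(loss):
            continue
        cand = (loss, _unpack(res.x, model), res.success)
        if i < len(extra_starts) and (incumbent is None or loss < incumbent[0]):
            incumbent = cand
        if best is None or loss < best[0]:
            best = cand
    if best is None:
        raise RuntimeError("all optimizer starts failed")
    # hysteresis: near-tied optima of an overparameterized mixture flip
    # labels between cutoffs; keep the warm-started solution unless a
    # fresh start improves the objective by a real margin
    if incumbent is not None and incumbent[0] <= best[0] * (1 + incumbent_margin) + 1e-12:
        best = incumbent

    loss, theta, success = best
    if model == "heavy_tailed_frechet":
        lam, k = theta
        fit = MixtureFit(scale_c=1.0, shape_c=1.0, scale_d=float(lam), shape_d=float(k),
                         weight_c=0.0, loss=loss, converged=bool(success),
                         model=model, min_cutoff=int(min_cutoff), n_admitted=int(admitted.size))
        fit.converged = fit.converged and _inside_bounds([lam], [k])
        return fit
    lam_w, k_w, lam_f, k_f, w = theta
    fit = MixtureFit(scale_c=float(lam_w), shape_c=float(k_w), scale_d=float(lam_f),
                     shape_d=float(k_f), weight_c=float(np.clip(w, 0.0, 1.0)), loss=loss,
                     converged=bool(success), model=model, min_cutoff=int(min_cutoff),
                     n_admitted=int(admitted.size))
    # bound-hitting only matters for components that carry weight
    scales, shapes = [], []
    if fit.weight_c > _IDENTIFIABLE:
        scales.append(lam_w)
        shapes.append(k_w)
    if fit.weight_c < 1.0 - _IDENTIFIABLE:
        scales.append(lam_f)
        shapes.append(k_f)
    fit.converged = fit.converged and _inside_bounds(scales, shapes)
    return fit


def _inside_bounds(scales, shapes, rel=1e-6) -> bool:
    for v in scales:
        if v <= SCALE_BOUNDS[0] * (1 + rel) or v >= SCALE_BOUNDS[1] * (1 - rel):
            return False
    for v in shapes:
        if v <= SHAPE_BOUNDS[0] * (1 + rel) or v >= SHAPE_BOUNDS[1] * (1 - rel):
            return False
    return True


# ---------------------------------------------------------------------------
# parametric sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepTrace:
    cutoffs: np.ndarray
    fits: list[MixtureFit]          # pcpd_mixture fits, one per cutoff
    heavy_fits: list[MixtureFit]    # heavy-tailed Frechet fits, one per cutoff
    spike_flags: np.ndarray         # (n_cutoffs, n_params) booleans
    stable_windows: list[tuple[int, int]]  # inclusive index intervals free of spikes
    spike_factor: float = 2.0
    spike_magnitudes: np.ndarray | None = None  # largest |delta log param| per cutoff

    def flagged(self) -> np.ndarray:
        return self.spike_flags.any(axis=1)


def default_cutoff_grid(profile: CoverageProfile, max_points: int = 200) -> np.ndarray:
    """Unique observed totals, geometrically thinned to at most ``max_points`` cutoffs."""
    vals = np.unique(profile.values)
    cut = np.unique(np.concatenate([[0], vals[:-1]]))  # cutoff c admits totals > c
    if cut.size <= max_points:
        return cut
    idx = np.unique(np.round(np.geomspace(1, cut.size, max_points)).astype(int) - 1)
    return cut[idx]


def _effective_log_params(fit: MixtureFit) -> np.ndarray:
    """Log parameters used for spike comparison; NaN marks unidentifiable entries."""
    p = np.full(5, np.nan)
    w = fit.weight_c
    if fit.model == "heavy_tailed_frechet":
        p[2], p[3] = np.log(fit.scale_d), np.log(fit.shape_d)
        return p
    if w > _IDENTIFIABLE:
        p[0], p[1] = np.log(fit.scale_c), np.log(fit.shape_c)
    if w < 1.0 - _IDENTIFIABLE:
        p[2], p[3] = np.log(fit.scale_d), np.log(fit.shape_d)
    if _IDENTIFIABLE < w < 1.0 - _IDENTIFIABLE:
        p[4] = np.log(w)
    return p


def parametric_sweep(
    profile: CoverageProfile,
    cutoff_grid: Sequence[int] | None = None,
    spike_factor: float = 2.0,
    n_quantiles: int = 199,
    n_starts: int = 4,
    seed: int = 0,
    max_grid_points: int = 200,
) -> SweepTrace:
    """Refit both models at rising admission cutoffs and flag solver spikes.

    A cutoff is flagged when any identifiable parameter jumps by more than
    ``spike_factor``-fold relative to the previous cutoff, or when either
    fit fails to converge. Warm starts reuse the previous cutoff's optimum,
    keeping the trace deterministic for a given seed.
    """
    if cutoff_grid is None:
        cutoff_grid = default_cutoff_grid(profile, max_grid_points)
    cutoffs = np.asarray(cutoff_grid, dtype=np.int64)
    if cutoffs.size and np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoff_grid must be strictly increasing")

    totals = profile.values
    fits: list[MixtureFit] = []
    heavy: list[MixtureFit] = []
    kept: list[int] = []
    warm_mix: list[np.ndarray] = []
    warm_hvy: list[np.ndarray] = []
    truncated = False
    for j, c in enumerate(cutoffs):
        if np.count_nonzero(totals > c) < 50:
            truncated = True
            break
        fm = fit_pcpd(profile, int(c), "pcpd_mixture", n_quantiles, n_starts,
                      seed=seed * 100003 + j, extra_starts=warm_mix)
        fh = fit_pcpd(profile, int(c), "heavy_tailed_frechet", n_quantiles, n_starts,
                      seed=seed * 100003 + j, extra_starts=warm_hvy)
        fits.append(fm)
        heavy.append(fh)
        kept.append(int(c))
        warm_mix = [fm.params]
        warm_hvy = [np.array([fh.scale_d, fh.shape_d])]
    if truncated:
        import warnings

        warnings.warn("cutoff grid exhausted the coverage profile; sweep trace truncated",
                      stacklevel=2)
    cutoffs = np.asarray(kept, dtype=np.int64)

    n = len(fits)
    flags = np.zeros((n, 5), dtype=bool)
    magnitudes = np.zeros(n)
    log_thresh = np.log(spike_factor)
    prev = _effective_log_params(fits[0]) if n else None
    for j in range(n):
        cur = _effective_log_params(fits[j])
        if not fits[j].converged or not heavy[j].converged:
            flags[j, :] = True
        if j > 0:
            both = np.isfinite(prev) & np.isfinite(cur)
            diffs = np.abs(cur[both] - prev[both])
            flags[j, both] |= diffs > log_thresh
            if diffs.size:
                magnitudes[j] = float(diffs.max())
            # mixing-weight swings on the logit scale catch regime handoffs
            # that slip through the identifiability mask
            lw = [np.log(w / (1 - w)) for w in
                  (np.clip(fits[j - 1].weight_c, _IDENTIFIABLE, 1 - _IDENTIFIABLE),
                   np.clip(fits[j].weight_c, _IDENTIFIABLE, 1 - _IDENTIFIABLE))]
            if abs(lw[1] - lw[0]) > 2.0 * log_thresh:
                flags[j, 4] = True
                magnitudes[j] = max(magnitudes[j], abs(lw[1] - lw[0]))
        prev = cur

    any_flag = flags.any(axis=1)
    windows: list[tuple[int, int]] = []
    j = 0
    while j < n:
        if any_flag[j]:
            j += 1
            continue
        k = j
        while k + 1 < n and not any_flag[k + 1]:
            k += 1
        windows.append((j, k))
        j = k + 1
    return SweepTrace(cutoffs=cutoffs, fits=fits, heavy_fits=heavy, spike_flags=flags,
                      stable_windows=windows, spike_factor=spike_factor,
                      spike_magnitudes=magnitudes)


# ---------------------------------------------------------------------------
# regime inference
# ---------------------------------------------------------------------------

@dataclass
class RegimePartition:
    axis: Literal["gene", "barcode"]
    lower_bound: int
    upper_bound: int
    low_set: set[int]
    mid_set: set[int]
    high_set: set[int]
    provenance: tuple[MixtureFit, MixtureFit] | None = None

    REGIME_NAMES = {
        "gene": ("rare", "facultative", "constitutive"),
        "barcode": ("ambient", "singlet", "multiplet"),
    }

    def regime_of(self, index: int) -> str:
        names = self.REGIME_NAMES[self.axis]
        if index in self.low_set:
            return names[0]
        if index in self.mid_set:
            return names[1]
        if index in self.high_set:
            return names[2]
        raise KeyError(index)


def _consensus_fit(fits: list[MixtureFit], model: str) -> MixtureFit:
    """Component-wise geometric mean of window fits (arithmetic for the weight)."""
    P = np.array([f.params for f in fits])
    gm = np.exp(np.mean(np.log(np.maximum(P[:, :4], 1e-300)), axis=0))
    w = float(np.mean(P[:, 4]))
    tmpl = fits[0]
    return MixtureFit(scale_c=gm[0], shape_c=gm[1], scale_d=gm[2], shape_d=gm[3],
                      weight_c=w if model == "pcpd_mixture" else 0.0,
                      loss=float(np.mean([f.loss for f in fits])), converged=True,
                      model=model, min_cutoff=tmpl.min_cutoff, n_admitted=tmpl.n_admitted)


def _select_window(trace: SweepTrace) -> tuple[int, int]:
    """Pick the stable window describing the middle coverage regime.

    The boundary between the low and middle regimes announces itself as the
    sweep's dominant solver spike: the fit's components swap roles there,
    so every log parameter jumps by orders of magnitude, whereas
    within-regime instabilities produce much smaller flags. The window
    chosen is the first stable window after the first dominant spike (any
    flagged cutoff whose jump magnitude reaches half the sweep's maximum);
    with no spikes at all the profile is homogeneous and the single full
    window stands.
    """
    widest = max(trace.stable_windows, key=lambda w: (w[1] - w[0], -w[0]))
    if len(trace.stable_windows) == 1:
        return widest

    # canonical (label-invariant) per-window scales: transient label flaps
    # swap which component is Weibull vs Frechet without moving the sorted
    # scales, whereas crossing a regime boundary shifts them wholesale
    def window_scales(w):
        lo, hi = [], []
        for f in trace.fits[w[0]:w[1] + 1]:
            s = sorted((f.scale_c, f.scale_d))
            lo.append(np.log(s[0]))
            hi.append(np.log(s[1]))
        return float(np.mean(lo)), float(np.mean(hi))

    log_sf = np.log(trace.spike_factor)
    scales = [window_scales(w) for w in trace.stable_windows]
    groups: list[list[int]] = [[0]]
    for i in range(1, len(trace.stable_windows)):
        ref_lo = np.mean([scales[j][0] for j in groups[-1]])
        ref_hi = np.mean([scales[j][1] for j in groups[-1]])
        if abs(scales[i][0] - ref_lo) <= log_sf and abs(scales[i][1] - ref_hi) <= log_sf:
            groups[-1].append(i)
        else:
            groups.append([i])
    if len(groups) == 1:
        return widest
    # the low/mid regime boundary is the sharpest configuration change:
    # the consecutive-group transition with the largest bulk-scale jump
    grp_lo = [float(np.mean([scales[j][0] for j in grp])) for grp in groups]
    jumps = np.diff(grp_lo)
    i_best = int(np.argmax(jumps))
    if jumps[i_best] > log_sf:
        return trace.stable_windows[groups[i_best + 1][0]]
    return widest


def infer_regimes(trace: SweepTrace, profile: CoverageProfile) -> RegimePartition:
    """Project regime bounds from the consensus fit of the spike-flanked stable window.

    The lower bound is the window's admission cutoff plus one (the smallest
    coverage the stable fits describe; it is only resolvable to sweep-grid
    precision). The upper bound is the posterior-responsibility crossover
    between the window fit's small-scale (bulk) and large-scale (heavy)
    components -- the smallest integer coverage the heavy component owns.
    """
    if not trace.stable_windows:
        raise RuntimeError(
            "no spike-free window found in the parametric sweep; "
            "supply manual coverage cutoffs instead"
        )
    j0, j1 = _select_window(trace)
    mix = _consensus_fit(trace.fits[j0:j1 + 1], "pcpd_mixture")
    hvy = _consensus_fit(trace.heavy_fits[j0:j1 + 1], "heavy_tailed_frechet")

    totals = profile.values
    max_total = int(totals.max())

    lower = int(trace.cutoffs[j0]) + 1
    lower = max(lower, int(totals.min()))

    # order components by scale: the small-scale one is the middle-regime bulk
    w_bulk = mix.weight_c if mix.scale_c <= mix.scale_d else 1.0 - mix.weight_c
    if mix.scale_c <= mix.scale_d:
        bulk = (mix.scale_c, mix.shape_c, _weibull_pdf)
        heavy = (mix.scale_d, mix.shape_d, _frechet_pdf)
    else:
        bulk = (mix.scale_d, mix.shape_d, _frechet_pdf)
        heavy = (mix.scale_c, mix.shape_c, _weibull_pdf)

    scale_ratio = max(mix.scale_c, mix.scale_d) / max(min(mix.scale_c, mix.scale_d), 1e-300)
    if w_bulk >= 1.0 - 1e-3 or scale_ratio < MIN_SCALE_SEPARATION:
        # degenerate mixture (no heavy component) or both components inside
        # one regime: there is no resolvable high regime
        upper = max_total
    else:
        xs = np.arange(lower, max_total + 1, dtype=float)
        heavy_dom = (1.0 - w_bulk) * heavy[2](xs, heavy[0], heavy[1]) >= \
            w_bulk * bulk[2](xs, bulk[0], bulk[1])
        if heavy_dom.any():
            upper = int(xs[np.argmax(heavy_dom)]) - 1
            upper = min(max(upper, lower), max_total)
        else:
            upper = max_total

    low, mid, high = set(), set(), set()
    for idx, t in profile.totals.items():
        if t < lower:
            low.add(idx)
        elif t <= upper:
            mid.add(idx)
        else:
            high.add(idx)
    return RegimePartition(axis=profile.axis, lower_bound=lower, upper_bound=upper,
                           low_set=low, mid_set=mid, high_set=high, provenance=(mix, hvy))


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class MatrixFocuser(BaseEstimator):
    """Select the informative coverage regime along one axis of a count stack.

    Fitting runs the parametric sweep on per-gene (or per-barcode) total UMI
    coverage and stores the inferred regime partition; ``transform``
    restricts a stack to the middle (facultative / singlet) regime.

    Parameters
    ----------
    axis : {"gene", "barcode"}
        Marginal whose coverage distribution is modeled.
    spike_factor : float
        Fold-change in any identifiable parameter between consecutive
        cutoffs that flags a solver spike.
    n_quantiles, n_starts, max_grid_points, seed
        Quantile-regression grid size, multi-start count per cutoff,
        sweep-grid thinning and RNG seed.
    """

    def __init__(self, axis: str = "gene", spike_factor: float = 2.0,
                 n_quantiles: int = 199, n_starts: int = 4,
                 max_grid_points: int = 200, cutoff_grid=None, seed: int = 0):
        self.axis = axis
        self.spike_factor = spike_factor
        self.n_quantiles = n_quantiles
        self.n_starts = n_starts
        self.max_grid_points = max_grid_points
        self.cutoff_grid = cutoff_grid
        self.seed = seed

    def fit(self, stack: CountStack, y=None) -> "MatrixFocuser":
        self.profile_ = total_coverage(stack, self.axis)
        self.trace_ = parametric_sweep(
            self.profile_, cutoff_grid=self.cutoff_grid, spike_factor=self.spike_factor,
            n_quantiles=self.n_quantiles, n_starts=self.n_starts, seed=self.seed,
            max_grid_points=self.max_grid_points,
        )
        self.partition_ = infer_regimes(self.trace_, self.profile_)
        return self

    def transform(self, stack: CountStack) -> CountStack:
        part = self.partition_
        keep = sorted(part.mid_set)
        if self.axis == "gene":
            return stack.subset(gene_idx=keep)
        return stack.subset(barcode_idx=keep)

    def fit_transform(self, stack: CountStack, y=None) -> CountStack:
        return self.fit(stack).transform(stack)
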