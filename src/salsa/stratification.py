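"""The SG -> LSTNR -> DEG -> DEGREE -> Profiler gene ladder.

Facultative genes are sifted through nested reliability filters built on a
double-weighted ANOVA of Log2FC across cell majors. The double weighting
couples (a) coverage-resolution observation weights (high-coverage,
low-dispersion genes weigh more) with (b) within-cluster gene
representation rates, which enter as a response multiplier: the tested
quantity is the weighed expression rate(g, cluster) * Log2FC(g, cell).
Multiplying the response -- rather than the precision weight -- by the
representation rate is what lets absence carry signal without zero
imputation: a gene expressed broadly in one major and almost never in
another shows a large weighed-expression contrast even when the Log2FC of
its few stray observations is unremarkable. Effect sizes are benchmarked
against an SNR = 1 unit: the half-width of the 95%/95% tolerance interval
of weighed-expression residuals around cluster means.

Strata:

* SG        significant genes: BH-adjusted ANOVA q <= alpha;
* LSTNR     SGs whose weighted mean Log2FC exceeds the SNR unit in at
            least one major;
* DEG       LSTNRs with at least one significant, mutually exclusive
            pairwise contrast (mean +/- SNR-unit intervals disjoint);
* DEGREE    DEGs with a significant pairwise difference larger than the
            SNR unit;
* Profiler  DEGREEs that stay significant when representation-rate
            weights are ablated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .scoring import RepresentationTable, ScoreSet, representation_rates

__all__ = [
    "StratumStats",
    "SnrBenchmark",
    "GeneStrata",
    "STRATA_ORDER",
    "resolution_weights",
    "observation_weights",
    "weighted_anova",
    "zero_padded_anova",
    "bh_adjust",
    "snr_benchmark",
    "pairwise_contrasts",
    "stratify",
    "GeneStratifier",
]

STRATA_ORDER = ("facultative_only", "SG", "LSTNR", "DEG", "DEGREE", "Profiler")


@dataclass
class StratumStats:
    gene: int
    f_stat: float
    p_anova: float
    q_anova: float = np.nan
    cluster_means: dict[int, float] = field(default_factory=dict)
    cluster_sems: dict[int, float] = field(default_factory=dict)
    max_abs_mean: float = 0.0
    pairwise: dict[tuple[int, int], dict] = field(default_factory=dict)
    p_unweighted: float = 1.0
    q_unweighted: float = np.nan
    reason: str = ""


@dataclass
class SnrBenchmark:
    ti_halfwidth: float
    coverage: float
    confidence: float
    n_residuals: int


@dataclass
class GeneStrata:
    strata: dict[int, str]
    counts: dict[str, int]
    retained_barcodes: set[int]


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def resolution_weights(upt: sp.csr_matrix) -> np.ndarray:
    """Coverage-resolution weight per gene: n * mean / (1 + CV^2), mean-1 normalized."""
    csr = upt.tocsr()
    n_genes = csr.shape[0]
    w = np.zeros(n_genes)
    for g in range(n_genes):
        vals = csr.data[csr.indptr[g]:csr.indptr[g + 1]]
        if vals.size == 0:
            continue
        m = vals.mean()
        cv2 = (vals.std(ddof=0) / m) ** 2 if m > 0 else 0.0
        w[g] = vals.size * m / (1.0 + cv2)
    pos = w > 0
    if pos.any():
        w[pos] = w[pos] / w[pos].mean()
    return w


def observation_weights(gene: int, cluster: int, representation: RepresentationTable,
                        w_res: np.ndarray, use_representation: bool = True) -> float:
    """Weight of one cell-level observation of ``gene`` inside ``cluster``."""
    w = float(w_res[gene])
    if use_representation:
        w *= representation.rate.get((gene, cluster), 0.0)
    return w


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def zero_padded_anova(values: np.ndarray, groups: np.ndarray,
                      cluster_sizes: Mapping[int, int]) -> tuple[float, float]:
    """One-way F test of per-cell weighed expression including absent cells.

    Each expressing cell contributes its Log2FC; every other cell of the
    cluster contributes an (implicit, never materialized) zero. The
    cluster mean is then rate * mean(Log2FC) -- the weighed expression --
    while the within-cluster variance includes the presence/absence
    (binomial) noise of the representation rate itself, which keeps the
    test calibrated when rates differ between clusters only by sampling.
    """
    labs = np.unique(groups)
    sizes = np.array([cluster_sizes[int(k)] for k in labs], dtype=float)
    m_expr = np.array([np.count_nonzero(groups == k) for k in labs])
    if np.count_nonzero(m_expr >= 2) < 2 or len(labs) < 2:
        return 0.0, 1.0
    sums = np.array([values[groups == k].sum() for k in labs])
    means = sums / sizes
    n = float(sizes.sum())
    grand = float(sums.sum()) / n
    ssb = float(np.dot(sizes, (means - grand) ** 2))
    ssw = 0.0
    for k, mk, nk, m in zip(labs, means, sizes, m_expr):
        v = values[groups == k]
        ssw += float(((v - mk) ** 2).sum()) + (nk - m) * mk ** 2
    df1 = len(labs) - 1
    df2 = n - len(labs)
    if df2 <= 0:
        return 0.0, 1.0
    if ssw <= 1e-300:
        return np.inf, 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(scipy.stats.f.sf(f, df1, df2))


def weighted_anova(values: np.ndarray, groups: np.ndarray,
                   weights: np.ndarray) -> tuple[float, float]:
    """Weighted one-way ANOVA F test across cluster blocks.

    Degrees of freedom use observation counts (K - 1, n - K); the statistic
    is invariant to rescaling all weights. Requires at least two groups
    with two or more observations; otherwise p = 1. All-zero residuals
    yield p = 0 (perfect separation of discrete data).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    weights = np.asarray(weights, dtype=float)
    labs, counts = np.unique(groups, return_counts=True)
    if np.count_nonzero(counts >= 2) < 2 or len(labs) < 2:
        return 0.0, 1.0
    W = np.array([weights[groups == k].sum() for k in labs])
    if np.any(W <= 0):
        return 0.0, 1.0
    mk = np.array([np.dot(weights[groups == k], values[groups == k]) for k in labs]) / W
    grand = float(np.dot(weights, values) / weights.sum())
    ssb = float(np.dot(W, (mk - grand) ** 2))
    ssw = 0.0
    for k, m in zip(labs, mk):
        sel = groups == k
        ssw += float(np.dot(weights[sel], (values[sel] - m) ** 2))
    df1 = len(labs) - 1
    df2 = len(values) - len(labs)
    if df2 <= 0:
        return 0.0, 1.0
    if ssw <= 1e-300:
        return np.inf, 0.0
    f = (ssb / df1) / (ssw / df2)
    return float(f), float(scipy.stats.f.sf(f, df1, df2))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def snr_benchmark(residuals: np.ndarray, coverage: float = 0.95,
                  confidence: float = 0.95, method: str = "howe") -> SnrBenchmark:
    """SNR = 1 unit: half-width of the two-sided normal tolerance interval.

    Howe's factor k2 = z_{(1+P)/2} * sqrt(nu (1 + 1/n) / chi2_{1-gamma, nu})
    applied to the pooled residual SD; a nonparametric alternative uses the
    97.5th percentile of |residuals|.
    """
    r = np.asarray(residuals, dtype=float)
    n = r.size
    if n < 3:
        raise ValueError("need at least 3 residuals for a tolerance interval")
    if method == "nonparametric":
        hw = float(np.quantile(np.abs(r), 0.5 + coverage / 2))
    else:
        s = float(r.std(ddof=1))
        z = scipy.stats.norm.ppf(0.5 + coverage / 2)
        nu = n - 1
        chi2 = scipy.stats.chi2.ppf(1.0 - confidence, nu)
        hw = float(z * np.sqrt(nu * (1.0 + 1.0 / n) / chi2) * s)
    return SnrBenchmark(ti_halfwidth=hw, coverage=coverage, confidence=confidence,
                        n_residuals=n)


def _welch_weighted(x1, w1, x2, w2) -> tuple[float, float]:
    """Weighted Welch contrast; reduces to the textbook Welch t test at unit weights."""
    if len(x1) < 2 or len(x2) < 2:
        return float(np.nan), 1.0
    stats = []
    for x, w in ((x1, w1), (x2, w2)):
        sw = w.sum()
        m = float(np.dot(w, x) / sw)
        n_eff = sw ** 2 / np.dot(w, w)
        var = float(np.dot(w, (x - m) ** 2) / sw) * len(x) / (len(x) - 1)
        stats.append((m, var, n_eff))
    (m1, v1, n1), (m2, v2, n2) = stats
    se2 = v1 / n1 + v2 / n2
    if se2 <= 0:
        return float(m1 - m2), 1.0 if m1 == m2 else 0.0
    t = (m1 - m2) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return float(m1 - m2), float(p)


def pairwise_contrasts(values: np.ndarray, groups: np.ndarray, weights: np.ndarray,
                       ti_halfwidth: float) -> dict[tuple[int, int], dict]:
    """Weighted Welch-style contrasts for every cluster pair of one gene.

    ``exclusive`` marks pairs whose mean +/- SNR-unit intervals are
    disjoint, i.e. |delta| > 2 * ti_halfwidth. Pairs involving a singleton
    cluster get p = 1.
    """
    labs = np.unique(groups)
    out: dict[tuple[int, int], dict] = {}
    for i, k1 in enumerate(labs):
        for k2 in labs[i + 1:]:
            s1, s2 = groups == k1, groups == k2
            delta, p = _welch_weighted(values[s1], weights[s1], values[s2], weights[s2])
            if np.isnan(delta):
                m1 = np.dot(weights[s1], values[s1]) / weights[s1].sum() if weights[s1].sum() else 0
                m2 = np.dot(weights[s2], values[s2]) / weights[s2].sum() if weights[s2].sum() else 0
                delta = float(m1 - m2)
            out[(int(k1), int(k2))] = {
                "delta": delta,
                "p": p,
                "q": np.nan,
                "exclusive": bool(abs(delta) > 2.0 * ti_halfwidth),
            }
    return out


# ---------------------------------------------------------------------------
# the ladder
# ---------------------------------------------------------------------------

def stratify(stats: Mapping[int, StratumStats], benchmark: SnrBenchmark,
             alpha: float = 0.05, stack=None) -> GeneStrata:
    """Assign each facultative gene its stratum on the nested ladder.

    The representation-ablated significance of the Profiler layer is a
    follow-up hypothesis posed only for genes that reached DEGREE, so its
    BH family is the DEGREE set (hierarchical-testing scope), not the full
    facultative pool.
    """
    ti = benchmark.ti_halfwidth
    strata: dict[int, str] = {}
    for g, st in stats.items():
        label = "facultative_only"
        if np.isfinite(st.q_anova) and st.q_anova <= alpha:
            label = "SG"
            if st.max_abs_mean > ti:
                label = "LSTNR"
                sig_pairs = {pair: d for pair, d in st.pairwise.items()
                             if np.isfinite(d["q"]) and d["q"] <= alpha}
                if any(d["exclusive"] for d in sig_pairs.values()):
                    label = "DEG"
                    if any(abs(d["delta"]) > ti for d in sig_pairs.values()):
                        label = "DEGREE"
        strata[g] = label
    degree_genes = sorted(g for g, s in strata.items() if s == "DEGREE")
    if degree_genes:
        q_unw = bh_adjust([stats[g].p_unweighted for g in degree_genes])
        for g, q in zip(degree_genes, q_unw):
            stats[g].q_unweighted = float(q)
            if np.isfinite(q) and q <= alpha:
                strata[g] = "Profiler"
    counts = {name: 0 for name in STRATA_ORDER}
    for label in strata.values():
        counts[label] += 1
    retained: set[int] = set()
    if stack is not None:
        profilers = sorted(g for g, s in strata.items() if s == "Profiler")
        if profilers:
            sub = stack.matrix.tocsr()[profilers, :]
            retained = set(int(c) for c in np.nonzero(np.diff(sub.tocsc().indptr) > 0)[0])
    return GeneStrata(strata=strata, counts=counts, retained_barcodes=retained)


def nested_counts(strata: GeneStrata) -> dict[str, int]:
    """Cumulative (nested) stratum sizes: each level counts itself plus everything above."""
    order = list(STRATA_ORDER)
    out = {}
    for i, name in enumerate(order):
        out[name] = sum(strata.counts[n] for n in order[i:])
    return out


class GeneStratifier(BaseEstimator):
    """Fit the full double-weighted ANOVA ladder on a scored, clustered stack.

    Parameters
    ----------
    alpha : float
        BH-adjusted significance level shared by every layer.
    coverage, confidence : float
        Tolerance-interval construction of the SNR = 1 unit.
    ti_method : {"howe", "nonparametric"}
    """

    def __init__(self, alpha: float = 0.05, coverage: float = 0.95,
                 confidence: float = 0.95, ti_method: str = "howe"):
        self.alpha = alpha
        self.coverage = coverage
        self.confidence = confidence
        self.ti_method = ti_method

    def fit(self, score_set: ScoreSet, majors: Mapping[int, int]) -> "GeneStratifier":
        stack = score_set.stack
        cells = np.array(sorted(majors.keys()), dtype=int)
        cell_label = np.full(stack.n_barcodes, -1, dtype=int)
        for c, k in majors.items():
            cell_label[c] = k

        rep = representation_rates(stack.subset(barcode_idx=cells.tolist()),
                                   {i: majors[int(c)] for i, c in enumerate(cells)})
        w_res = resolution_weights(score_set.upt)

        log2fc = score_set.log2fc.tocsr()
        n_genes = stack.n_genes
        stats: dict[int, StratumStats] = {}
        residuals: list[np.ndarray] = []

        weighed: dict[int, tuple[np.ndarray, np.ndarray]] = {}  # gene -> (y, groups)
        for g in range(n_genes):
            lo, hi = log2fc.indptr[g], log2fc.indptr[g + 1]
            cols = log2fc.indices[lo:hi]
            vals = log2fc.data[lo:hi]
            in_major = cell_label[cols] >= 0
            cols, vals = cols[in_major], vals[in_major]
            if cols.size == 0:
                continue
            grp = cell_label[cols]
            rates = np.array([rep.rate.get((g, int(k)), 0.0) for k in grp])
            y = rates * vals                      # weighed expression response
            w_obs = np.full(cols.size, max(w_res[g], 1e-12))

            labs, counts = np.unique(grp, return_counts=True)
            eligible = np.count_nonzero(counts >= 2) >= 2
            st = StratumStats(gene=g, f_stat=0.0, p_anova=1.0)
            if eligible:
                st.f_stat, st.p_anova = zero_padded_anova(vals, grp, rep.n_cells)
                _, st.p_unweighted = weighted_anova(vals, grp, w_obs)
            else:
                st.reason = "fewer than 2 clusters with >=2 expressing cells"
            for k in labs:
                sel = grp == k
                m = float(y[sel].mean())
                st.cluster_means[int(k)] = m
                n_k = int(sel.sum())
                sd = float(y[sel].std(ddof=1)) if n_k > 1 else 0.0
                st.cluster_sems[int(k)] = sd / np.sqrt(n_k) if n_k > 0 else np.nan
                residuals.append(y[sel] - m)
            st.max_abs_mean = float(max(abs(v) for v in st.cluster_means.values()))
            stats[g] = st
            weighed[g] = (y, grp, w_obs)

        pooled = np.concatenate(residuals) if residuals else np.zeros(0)
        self.benchmark_ = snr_benchmark(pooled, self.coverage, self.confidence,
                                        self.ti_method)

        # pairwise contrasts on the weighed-expression (SNR) scale
        pair_ps, pair_keys = [], []
        for g, st in stats.items():
            y, grp, w_obs = weighed[g]
            st.pairwise = pairwise_contrasts(y, grp, w_obs,
                                             self.benchmark_.ti_halfwidth)
            for pair, d in st.pairwise.items():
                pair_keys.append((g, pair))
                pair_ps.append(d["p"])

        # one BH family per test layer (the ablated layer is adjusted inside
        # stratify over the DEGREE set it actually tests)
        genes = sorted(stats.keys())
        q_anova = bh_adjust([stats[g].p_anova for g in genes])
        for g, qa in zip(genes, q_anova):
            stats[g].q_anova = float(qa)
        q_pairs = bh_adjust(pair_ps)
        for (g, pair), qv in zip(pair_keys, q_pairs):
            stats[g].pairwise[pair]["q"] = float(qv)

        self.stats_ = stats
        self.representation_ = rep
        self.resolution_weights_ = w_res
        self.strata_ = stratify(stats, self.benchmark_, self.alpha, stack=stack)
        return self
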