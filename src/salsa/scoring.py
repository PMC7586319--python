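"""Normalized expression rates and GLM linear-predictor scores.

Expression in a cell is quantified as UMIs-per-thousand total (UPT), the
gene's tally scaled by the cell's full library size. Pseudo-bulk reference
means give per-gene Log2 fold changes, and a generalized-linear-model
transform turns positive UPT rates into approximately standard-normal
linear-predictor scores B(theta) suitable for latent-variable extraction.
Zeros are never imputed: every derived stack shares the focused stack's
data-positive support, with absence handled downstream via representation
rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.stats
from sklearn.base import BaseEstimator

from .countstack import CountStack

__all__ = [
    "ScoreSet",
    "RepresentationTable",
    "compute_upt",
    "reference_means",
    "fit_btheta",
    "compute_log2fc",
    "representation_rates",
    "ExpressionScorer",
]

FAMILY_CANDIDATES = ("gamma-log", "inverse-gaussian-log", "gaussian-log")


@dataclass
class ScoreSet:
    """Derived stacks on the focused support plus per-gene reference means.

    ``upt``, ``btheta`` and ``log2fc`` are CSR matrices sharing the sparsity
    pattern of the focused count stack (explicit zeros are meaningful scores
    for entries whose UMI exists).
    """

    stack: CountStack
    upt: sp.csr_matrix
    btheta: sp.csr_matrix
    log2fc: sp.csr_matrix
    ref_mean: dict[int, float]
    family: str
    denominators: np.ndarray
    singleton_genes: set[int]

    @property
    def gene_ids(self):
        return self.stack.gene_ids

    @property
    def barcode_ids(self):
        return self.stack.barcode_ids


@dataclass
class RepresentationTable:
    rate: dict[tuple[int, int], float]
    n_expressing: dict[tuple[int, int], int]
    n_cells: dict[int, int]


def _same_pattern(template: sp.csr_matrix, data: np.ndarray) -> sp.csr_matrix:
    out = sp.csr_matrix(
        (data, template.indices.copy(), template.indptr.copy()), shape=template.shape
    )
    return out


def compute_upt(stack: CountStack, denominators: Mapping[int, int] | np.ndarray) -> sp.csr_matrix:
    """UPT(g, c) = 1000 * umi(g, c) / total UMI of cell c over the full library."""
    den = np.zeros(stack.n_barcodes)
    if isinstance(denominators, Mapping):
        for c in range(stack.n_barcodes):
            if c not in denominators:
                # only an error if the barcode actually has entries
                if stack.matrix[:, c].nnz:
                    raise KeyError(f"no library-size denominator for barcode index {c}")
                den[c] = 1.0
            else:
                den[c] = denominators[c]
    else:
        den = np.asarray(denominators, dtype=float)
        if den.size != stack.n_barcodes:
            raise ValueError("denominator vector length must equal n_barcodes")
    if np.any(den <= 0):
        raise ValueError("denominators must be strictly positive")
    csr = stack.matrix.tocsr()
    coo = csr.tocoo()
    data = 1000.0 * coo.data / den[coo.col]
    return _same_pattern(csr, data)


def reference_means(upt: sp.csr_matrix, stack: CountStack,
                    denominators: np.ndarray) -> dict[int, float]:
    """Pseudo-bulk UPT per gene: pooled UMIs over pooled library sizes, times 1000."""
    den_total = float(np.sum(denominators))
    gene_umi = np.asarray(stack.matrix.sum(axis=1)).ravel()
    return {int(g): 1000.0 * gene_umi[g] / den_total
            for g in np.nonzero(gene_umi > 0)[0]}


def fit_btheta(upt: sp.csr_matrix, family_candidates: Sequence[str] = FAMILY_CANDIDATES,
               ref_mean: Mapping[int, float] | None = None,
               ) -> tuple[sp.csr_matrix, str, set[int]]:
    """Gene-wise GLM linear-predictor scores on the log link.

    The exponential family is chosen library-wide by minimizing the mean
    squared log-quantile deviation between fitted and empirical pooled UPT
    distributions. Scores are the link-transformed rates, anchored at the
    gene's pseudo-bulk reference mean when one is supplied (at the gene's
    within-support mean otherwise) and standardized by the gene's GLM
    dispersion, so they are approximately normal within gene. Anchoring at
    the reference mean keeps enrichment relative to bulk -- and hence
    expression presence -- visible to downstream latent extraction, where
    absent entries act as zeros. Genes expressed in a single cell get
    score 0 and are flagged.
    """
    if upt.nnz == 0:
        raise ValueError("empty UPT support")
    pooled = upt.data
    family = _select_family(pooled, family_candidates)

    csr = upt.tocsr()
    link = np.log(csr.data)
    scores = np.zeros_like(link)
    singletons: set[int] = set()
    for g in range(csr.shape[0]):
        lo, hi = csr.indptr[g], csr.indptr[g + 1]
        n = hi - lo
        if n == 0:
            continue
        if n == 1:
            scores[lo:hi] = 0.0
            singletons.add(g)
            continue
        eta = link[lo:hi]
        sd = eta.std(ddof=1)
        anchor = np.log(ref_mean[g]) if ref_mean is not None and g in ref_mean else eta.mean()
        scores[lo:hi] = 0.0 if sd == 0 else (eta - anchor) / sd
    return _same_pattern(csr, scores), family, singletons


def _select_family(pooled: np.ndarray, candidates: Sequence[str]) -> str:
    """Mean squared quantile deviation (log scale) of each family's pooled fit."""
    q = np.linspace(0.01, 0.99, 99)
    emp = np.quantile(pooled, q)
    best, best_err = None, np.inf
    for fam in candidates:
        try:
            if fam == "gamma-log":
                a, loc, scale = scipy.stats.gamma.fit(pooled, floc=0)
                th = scipy.stats.gamma.ppf(q, a, loc=0, scale=scale)
            elif fam == "inverse-gaussian-log":
                mu, loc, scale = scipy.stats.invgauss.fit(pooled, floc=0)
                th = scipy.stats.invgauss.ppf(q, mu, loc=0, scale=scale)
            elif fam == "gaussian-log":
                logd = np.log(pooled)
                th = np.exp(scipy.stats.norm.ppf(q, loc=logd.mean(),
                                                 scale=max(logd.std(), 1e-12)))
            else:
                raise ValueError(f"unknown family {fam!r}")
        except Exception:  # noqa: BLE001 - a failed candidate fit is skipped
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            err = np.nanmean((np.log(np.maximum(th, 1e-300)) - np.log(emp)) ** 2)
        if np.isfinite(err) and err < best_err:
            best, best_err = fam, err
    if best is None:
        raise RuntimeError("no candidate family could be fit")
    return best


def compute_log2fc(upt: sp.csr_matrix, ref_mean: Mapping[int, float]) -> sp.csr_matrix:
    """log2(UPT / reference mean), defined only on data-positive entries."""
    csr = upt.tocsr()
    ref = np.full(csr.shape[0], np.nan)
    for g, m in ref_mean.items():
        ref[g] = m
    coo = csr.tocoo()
    missing = np.unique(coo.row[~np.isfinite(ref[coo.row])])
    if missing.size:
        raise KeyError(f"missing reference mean for gene indices {missing[:5].tolist()}")
    data = np.log2(coo.data / ref[coo.row])
    return _same_pattern(csr, data)


def representation_rates(stack: CountStack, clusters: Mapping[int, int]) -> RepresentationTable:
    """Fraction of a cluster's cells with >= 1 UMI per gene (absence materialized as 0)."""
    if not clusters:
        raise ValueError("cluster assignment is empty")
    labels = sorted(set(clusters.values()))
    members: dict[int, list[int]] = {k: [] for k in labels}
    for c, k in clusters.items():
        members[k].append(c)
    n_cells = {k: len(v) for k, v in members.items()}
    for k, n in n_cells.items():
        if n == 0:
            raise ValueError(f"cluster {k} has no cells")
    csc = stack.matrix.tocsc()
    rate: dict[tuple[int, int], float] = {}
    n_exp: dict[tuple[int, int], int] = {}
    genes = np.nonzero(np.asarray(stack.matrix.sum(axis=1)).ravel() > 0)[0]
    for k in labels:
        sub = csc[:, members[k]]
        counts = np.asarray((sub > 0).sum(axis=1)).ravel()
        for g in genes:
            n_exp[(int(g), k)] = int(counts[g])
            rate[(int(g), k)] = counts[g] / n_cells[k]
    return RepresentationTable(rate=rate, n_expressing=n_exp, n_cells=n_cells)


class ExpressionScorer(BaseEstimator):
    """Transform a focused count stack into UPT / B(theta) / Log2FC stacks.

    Parameters
    ----------
    family : str
        "auto" selects the GLM family library-wide; otherwise one of
        ``gamma-log``, ``inverse-gaussian-log``, ``gaussian-log``.
    use_full_denominators : bool
        Use per-cell totals over the full (pre-focusing) library as UPT
        denominators (default); if False, the focused stack's own totals.
    """

    def __init__(self, family: str = "auto", use_full_denominators: bool = True):
        self.family = family
        self.use_full_denominators = use_full_denominators

    def fit(self, stack: CountStack, y=None, full_stack: CountStack | None = None):
        self.fit_transform(stack, full_stack=full_stack)
        return self

    def fit_transform(self, stack: CountStack, y=None,
                      full_stack: CountStack | None = None) -> ScoreSet:
        source = full_stack if (full_stack is not None and self.use_full_denominators) else stack
        den = np.asarray(source.matrix.sum(axis=0)).ravel().astype(float)
        if source is not stack:
            # align the full library's barcodes onto the focused stack's order
            pos = {b: i for i, b in enumerate(source.barcode_ids)}
            den = np.array([den[pos[b]] for b in stack.barcode_ids])
        if np.any(den <= 0):
            raise ValueError("every retained barcode needs a positive library size")
        upt = compute_upt(stack, den)
        ref = reference_means(upt, stack, den)
        candidates = FAMILY_CANDIDATES if self.family == "auto" else (self.family,)
        btheta, family, singletons = fit_btheta(upt, candidates, ref_mean=ref)
        log2fc = compute_log2fc(upt, ref)
        self.score_set_ = ScoreSet(stack=stack, upt=upt, btheta=btheta, log2fc=log2fc,
                                   ref_mean=ref, family=family, denominators=den,
                                   singleton_genes=singletons)
        return self.score_set_
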