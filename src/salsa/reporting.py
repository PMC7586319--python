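"""Diagnostic graphics with machine-readable twins.

Every plot writes a JSON or TSV twin holding exactly the numbers drawn;
tests and downstream tooling consume the twin, never pixels.

* frosty plot -- nested circles for the gene strata ladder (constitutive
  head, facultative body with nested significance strata, rare base) with
  stick arms showing input vs retained cell fractions;
* knee plot -- log-log rank vs total coverage with regime coloring and a
  tie-count depth axis;
* topograph -- per-gene weighed-expression quantiles over cell majors on
  the latent 2D layout, with a neighbor-joining tree over major centroids;
* violin summary -- per-major Log2FC distributions for selected genes
  with composite high-expression / high-representation shading tiers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402
from skbio import DistanceMatrix  # noqa: E402
from skbio.tree import nj  # noqa: E402

from .countstack import CountStack  # noqa: E402
from .focusing import CoverageProfile, RegimePartition  # noqa: E402
from .scoring import ScoreSet, representation_rates  # noqa: E402
from .stratification import STRATA_ORDER, GeneStrata, nested_counts  # noqa: E402

__all__ = ["frosty_plot", "knee_plot", "topograph", "violin_summary"]


def _save(fig, out_prefix: Path, fmt: str) -> str:
    path = out_prefix.with_suffix(f".{fmt}")
    fig.savefig(path, format=fmt)
    plt.close(fig)
    return str(path)


def frosty_plot(strata: GeneStrata, n_constitutive: int, n_rare: int,
                retained_fraction: float, out_prefix,
                marker_stratum: str = "Profiler", fmt: str = "svg") -> dict:
    """Nested-circle summary of the stratification ladder.

    Circle areas are proportional to nested stratum sizes; the left arm is
    the input cell fraction (1.0) and the right arm the fraction retained
    by the marker stratum.
    """
    if any(name not in strata.counts for name in STRATA_ORDER):
        raise ValueError("strata counts are incomplete")
    nested = nested_counts(strata)
    spec = {
        "head": int(n_constitutive),
        "body": {name: int(nested[name]) for name in STRATA_ORDER},
        "base": int(n_rare),
        "left_arm": 1.0,
        "right_arm": float(retained_fraction),
        "marker_stratum": marker_stratum,
    }
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(5, 7))
    body_max = max(nested["facultative_only"], 1)
    greys = np.linspace(0.9, 0.2, len(STRATA_ORDER))
    for name, g in zip(STRATA_ORDER, greys):
        r = np.sqrt(nested[name] / body_max)
        ax.add_patch(plt.Circle((0, 0), r, fill=True, color=str(g), zorder=2))
        ax.annotate(f"{name}: {nested[name]}", (1.15, 1.0 - 0.15 * STRATA_ORDER.index(name)),
                    fontsize=8)
    head_r = 0.45 * np.sqrt(n_constitutive / body_max) if body_max else 0.1
    ax.add_patch(plt.Circle((0, 1.0 + head_r), max(head_r, 0.05), color="black", zorder=3))
    ax.add_patch(plt.Rectangle((-1.2, -2.0), 2.4, 0.6, color="dimgray"))
    ax.annotate(f"rare: {n_rare}", (-0.3, -1.75), fontsize=8, color="white")
    ax.plot([-1.0, -1.0], [0, 1.0 * spec["left_arm"]], lw=3, color="black")
    ax.plot([1.0, 1.0], [0, 1.0 * spec["right_arm"]], lw=3, color="black")
    ax.set_xlim(-2.2, 2.6)
    ax.set_ylim(-2.2, 2.2)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title("Gene stratification (frosty plot)")
    spec["image"] = _save(fig, out_prefix, fmt)

    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(spec, fh, indent=2)
    spec["json"] = str(out_prefix.with_suffix(".json"))
    return spec


def knee_plot(profile: CoverageProfile, partition: RegimePartition | None,
              out_prefix, fmt: str = "svg") -> dict:
    """Rank vs total coverage on log-log axes with tie counts as depth."""
    if not profile.totals:
        raise ValueError("empty coverage profile")
    ranks = np.arange(1, len(profile.ranked) + 1)
    totals = profile.values
    regimes = []
    if partition is not None:
        regimes = [partition.regime_of(int(i)) for i in profile.ranked]
    tie_depth = np.ones(len(ranks))
    for start_rank, count in profile.tie_counts.items():
        tie_depth[start_rank - 1:start_rank - 1 + count] = count

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(6, 5))
    if regimes:
        colors = {"rare": "tab:blue", "facultative": "tab:green", "constitutive": "tab:red",
                  "ambient": "tab:blue", "singlet": "tab:green", "multiplet": "tab:red"}
        cs = [colors[r] for r in regimes]
    else:
        cs = "black"
    sc = ax.scatter(ranks, totals, c=cs, s=4 + 2 * np.log1p(tie_depth))
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("rank")
    ax.set_ylabel(f"total UMI per {profile.axis}")
    ax.set_title(f"{profile.axis} knee plot")
    data = {
        "axis": profile.axis,
        "rank": ranks.tolist(),
        "total": totals.tolist(),
        "tie_depth": tie_depth.astype(int).tolist(),
        "regime": regimes,
        "image": _save(fig, out_prefix, fmt),
    }
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(data, fh)
    data["json"] = str(out_prefix.with_suffix(".json"))
    return data


def _major_centroids(score_set: ScoreSet, majors: Mapping[int, int]) -> pd.DataFrame:
    bt = score_set.btheta.tocsc()
    labels = sorted(set(majors.values()))
    cent = {}
    for k in labels:
        cells = [c for c, lab in majors.items() if lab == k]
        sub = bt[:, cells]
        nnz = np.diff(sub.tocsr().indptr)
        sums = np.asarray(sub.sum(axis=1)).ravel()
        with np.errstate(invalid="ignore"):
            cent[k] = np.where(nnz > 0, sums / np.maximum(nnz, 1), 0.0)
    return pd.DataFrame(cent)


def neighbor_joining_tree(centroids: pd.DataFrame):
    """NJ tree over Euclidean distances between major centroid score means."""
    labels = [str(c) for c in centroids.columns]
    n = len(labels)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(centroids.iloc[:, i] - centroids.iloc[:, j]))
            dm[i, j] = dm[j, i] = d
    return nj(DistanceMatrix(dm, ids=labels))


def topograph(score_set: ScoreSet, majors: Mapping[int, int],
              layout: Mapping[int, tuple[float, float]], gene: int,
              out_prefix, fmt: str = "svg") -> dict:
    """Weighed-expression quantile map of one gene over the latent 2D layout."""
    l2 = score_set.log2fc.tocsr()
    lo, hi = l2.indptr[gene], l2.indptr[gene + 1]
    cells = l2.indices[lo:hi]
    vals = l2.data[lo:hi]
    in_major = np.array([c in majors for c in cells], dtype=bool)
    cells, vals = cells[in_major], vals[in_major]
    if cells.size == 0:
        raise ValueError(f"gene index {gene} is expressed in no major")

    rep = representation_rates(score_set.stack.subset(), majors)
    labels = sorted(set(majors.values()))
    composite = {}
    for k in labels:
        sel = np.array([majors[int(c)] == k for c in cells])
        if sel.any():
            composite[k] = float(vals[sel].mean()) * rep.rate.get((gene, k), 0.0)
    ranks = pd.Series(composite).rank(method="average")
    quantiles = ((ranks - 1) / max(len(ranks) - 1, 1)).to_dict() if len(ranks) > 1 \
        else {k: 1.0 for k in composite}

    tree = neighbor_joining_tree(_major_centroids(score_set, majors))
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(6, 5))
    xy = np.array([layout[c] for c in majors])
    cell_major = np.array([majors[c] for c in majors])
    cmap = plt.get_cmap("viridis")
    for k in labels:
        sel = cell_major == k
        q = quantiles.get(k, 0.0)
        ax.scatter(xy[sel, 0], xy[sel, 1], s=6, color=cmap(q), alpha=0.6,
                   label=f"major {k} (q={q:.2f})")
    expr_xy = np.array([layout[int(c)] for c in cells if int(c) in layout])
    if expr_xy.size:
        ax.scatter(expr_xy[:, 0], expr_xy[:, 1], s=3, color="black")
    ax.legend(fontsize=6)
    ax.set_title(f"topograph: {score_set.gene_ids[gene]}")
    spec = {
        "gene": score_set.gene_ids[gene],
        "weighed_score": {str(k): float(q) for k, q in quantiles.items()},
        "composite": {str(k): float(v) for k, v in composite.items()},
        "expressing_cells": [int(c) for c in cells],
        "layout_kind": "svd_plane",
        "tree_newick": str(tree),
        "image": _save(fig, out_prefix, fmt),
    }
    with open(out_prefix.with_suffix(".json"), "w") as fh:
        json.dump(spec, fh)
    spec["json"] = str(out_prefix.with_suffix(".json"))
    return spec


def violin_summary(score_set: ScoreSet, majors: Mapping[int, int],
                   genes: Sequence[int], out_prefix, fmt: str = "svg") -> pd.DataFrame:
    """Per gene x major Log2FC distribution stats plus shading tiers.

    Shading: tier 1 marks majors in the top quartile of mean Log2FC for
    the gene; tier 2 those also in the top quartile of representation.
    """
    l2 = score_set.log2fc.tocsr()
    rep = representation_rates(score_set.stack.subset(), majors)
    labels = sorted(set(majors.values()))
    rows = []
    for g in genes:
        lo, hi = l2.indptr[g], l2.indptr[g + 1]
        cells, vals = l2.indices[lo:hi], l2.data[lo:hi]
        means, rates = {}, {}
        for k in labels:
            sel = np.array([int(c) in majors and majors[int(c)] == k for c in cells])
            v = vals[sel]
            means[k] = float(v.mean()) if v.size else np.nan
            rates[k] = rep.rate.get((g, k), 0.0)
            rows.append({
                "gene": score_set.gene_ids[g], "major": k, "n_expressing": int(v.size),
                "median": float(np.median(v)) if v.size else np.nan,
                "q25": float(np.quantile(v, 0.25)) if v.size else np.nan,
                "q75": float(np.quantile(v, 0.75)) if v.size else np.nan,
                "representation": rates[k],
            })
        mvals = [m for m in means.values() if np.isfinite(m)]
        if mvals:
            m_thr = np.quantile(mvals, 0.75)
            r_thr = np.quantile(list(rates.values()), 0.75)
            for row in rows[-len(labels):]:
                k = row["major"]
                hi_expr = np.isfinite(means[k]) and means[k] >= m_thr
                row["tier"] = ("high_expr_high_rep" if hi_expr and rates[k] >= r_thr
                               else "high_expr" if hi_expr else "none")
        else:
            for row in rows[-len(labels):]:
                row["tier"] = "none"
    df = pd.DataFrame(rows)

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, max(len(genes), 1), figsize=(3 * max(len(genes), 1), 4),
                             squeeze=False)
    shade = {"none": "white", "high_expr": "0.85", "high_expr_high_rep": "0.6"}
    for ax, g in zip(axes[0], genes):
        lo, hi = l2.indptr[g], l2.indptr[g + 1]
        cells, vals = l2.indices[lo:hi], l2.data[lo:hi]
        data, positions = [], []
        for k in labels:
            sel = np.array([int(c) in majors and majors[int(c)] == k for c in cells])
            v = vals[sel]
            if v.size:
                data.append(v)
                positions.append(k)
            tier = df[(df.gene == score_set.gene_ids[g]) & (df.major == k)]["tier"].iloc[0]
            ax.axhspan(k - 0.4, k + 0.4, color=shade[tier], zorder=0)
        if data:
            ax.violinplot(data, positions=positions, vert=False, widths=0.8)
        ax.set_title(score_set.gene_ids[g], fontsize=8)
        ax.set_xlabel("Log2FC")
        ax.set_ylabel("major")
    img = _save(fig, out_prefix, fmt)
    df.attrs["image"] = img
    df.to_csv(out_prefix.with_suffix(".tsv"), sep="\t", index=False)
    return df
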