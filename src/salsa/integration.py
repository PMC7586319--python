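"""Multi-replicate integration by consensus facultative gene selection.

Each biological specimen is focused independently (no cross-specimen
pooling of coverage profiles), then a consensus facultative gene set is
built in two steps: a gene is *batch-consistent* for an experimental
round when it is facultative in every specimen of that round, and it
enters the consensus when batch-consistent in at least
``ceil(min_round_fraction * n_rounds)`` rounds. The integrated stack
concatenates the specimens' singlet barcodes restricted to the consensus
genes, namespacing barcodes as ``<specimen_id>:<barcode>`` and keeping
per-barcode library sizes within specimen (UPT never mixes denominators
across specimens).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .countstack import CountStack, read_mtx_dir
from .focusing import MatrixFocuser, RegimePartition

__all__ = [
    "ReplicateDesign",
    "ConsensusSet",
    "read_design",
    "per_specimen_focus",
    "consensus_facultative",
    "assemble_integrated",
    "post_stratification_retention",
]


@dataclass
class ReplicateDesign:
    specimens: list[tuple[str, object, str]]   # (specimen_id, stack or path, round_id)
    min_round_fraction: float = 0.75

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise ValueError("specimen ids must be unique")
        if not (0 < self.min_round_fraction <= 1):
            raise ValueError("min_round_fraction must lie in (0, 1]")

    @property
    def rounds(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for sid, _, rid in self.specimens:
            out.setdefault(rid, set()).add(sid)
        return out

    def stack(self, specimen_id: str) -> CountStack:
        for sid, obj, _ in self.specimens:
            if sid == specimen_id:
                return obj if isinstance(obj, CountStack) else read_mtx_dir(obj)
        raise KeyError(specimen_id)


@dataclass
class ConsensusSet:
    per_specimen_facultative: dict[str, set[str]]
    batch_consistent: dict[str, set[str]]
    consensus_genes: set[str]
    per_specimen_singlets: dict[str, set[str]]
    min_rounds_required: int = 0


def read_design(path, min_round_fraction: float = 0.75) -> ReplicateDesign:
    """Read a design TSV with columns specimen_id, matrix_dir, round_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = {"specimen_id", "matrix_dir", "round_id"}
    if not needed.issubset(df.columns):
        raise ValueError(f"design table must have columns {sorted(needed)}")
    specs = [(r.specimen_id, r.matrix_dir, r.round_id) for r in df.itertuples()]
    return ReplicateDesign(specimens=specs, min_round_fraction=min_round_fraction)


def per_specimen_focus(
    design: ReplicateDesign, seed: int = 0, focus_barcodes: bool = True, **focuser_kwargs
) -> dict[str, dict[str, RegimePartition]]:
    """Run independent parametric sweeps per specimen on both axes.

    Seeds are derived as ``seed * 1000 + specimen index`` so specimens are
    independent yet reproducible. A specimen whose sweep fails to produce
    a stable window is excluded with a report as long as two or more
    specimens remain.
    """
    out: dict[str, dict[str, RegimePartition]] = {}
    failures: dict[str, str] = {}
    for i, (sid, _, _) in enumerate(design.specimens):
        stack = design.stack(sid)
        try:
            parts: dict[str, RegimePartition] = {}
            if focus_barcodes:
                bf = MatrixFocuser(axis="barcode", seed=seed * 1000 + i, **focuser_kwargs)
                parts["barcode"] = bf.fit(stack).partition_
                stack = bf.transform(stack)
            gfoc = MatrixFocuser(axis="gene", seed=seed * 1000 + i, **focuser_kwargs)
            parts["gene"] = gfoc.fit(stack).partition_
            out[sid] = parts
        except (RuntimeError, ValueError) as exc:
            failures[sid] = str(exc)
    if failures and len(out) < 2:
        raise RuntimeError(f"focusing failed for specimens {sorted(failures)}: {failures}")
    if failures:
        import warnings

        warnings.warn(f"specimens excluded from integration: {sorted(failures)}", stacklevel=2)
    return out


def _id_sets(design: ReplicateDesign,
             partitions: Mapping[str, Mapping[str, RegimePartition]]):
    fac: dict[str, set[str]] = {}
    singlets: dict[str, set[str]] = {}
    for sid, parts in partitions.items():
        stack = design.stack(sid)
        if "barcode" in parts:
            bpart = parts["barcode"]
            singlets[sid] = {stack.barcode_ids[i] for i in bpart.mid_set}
            keep = sorted(bpart.mid_set)
            stack_f = stack.subset(barcode_idx=keep)
        else:
            singlets[sid] = set(stack.barcode_ids)
            stack_f = stack
        fac[sid] = {stack_f.gene_ids[g] for g in parts["gene"].mid_set}
    return fac, singlets


def consensus_facultative(
    per_specimen_facultative: Mapping[str, set[str]],
    design: ReplicateDesign,
    per_specimen_singlets: Mapping[str, set[str]] | None = None,
) -> ConsensusSet:
    """Intersect facultative sets within rounds, then require most rounds to agree."""
    rounds = design.rounds
    present = set(per_specimen_facultative)
    batch: dict[str, set[str]] = {}
    for rid, members in rounds.items():
        avail = members & present
        if not avail:
            continue
        sets = [per_specimen_facultative[s] for s in sorted(avail)]
        batch[rid] = set.intersection(*sets)
    need = math.ceil(design.min_round_fraction * len(batch))
    tally: dict[str, int] = {}
    for genes in batch.values():
        for g in genes:
            tally[g] = tally.get(g, 0) + 1
    consensus = {g for g, n in tally.items() if n >= need}
    if not consensus:
        raise ValueError(
            "consensus facultative set is empty; relax min_round_fraction "
            "or inspect per-specimen partitions"
        )
    return ConsensusSet(
        per_specimen_facultative={k: set(v) for k, v in per_specimen_facultative.items()},
        batch_consistent=batch,
        consensus_genes=consensus,
        per_specimen_singlets={k: set(v) for k, v in (per_specimen_singlets or {}).items()},
        min_rounds_required=need,
    )


def focus_and_consensus(design: ReplicateDesign, seed: int = 0,
                        focus_barcodes: bool = True, **kw) -> ConsensusSet:
    """Convenience path: per-specimen sweeps straight to a ConsensusSet."""
    parts = per_specimen_focus(design, seed=seed, focus_barcodes=focus_barcodes, **kw)
    fac, singlets = _id_sets(design, parts)
    return consensus_facultative(fac, design, singlets)


def assemble_integrated(
    stacks: Mapping[str, CountStack],
    consensus_genes: set[str],
    per_specimen_singlets: Mapping[str, set[str]],
    replicated_gene_filter: set[str] | None = None,
    annotation: pd.DataFrame | None = None,
) -> tuple[CountStack, dict[str, str], np.ndarray]:
    """Concatenate specimen stacks over (consensus genes x singlets).

    ``replicated_gene_filter`` defaults to genes detected in every
    specimen; ``annotation`` (columns id, biotype) optionally restricts to
    protein-coding, non-ribosomal entries. Returns the integrated stack, a
    barcode -> specimen map, and per-barcode denominators taken from each
    specimen's own library totals.
    """
    sids = sorted(stacks)
    if replicated_gene_filter is None:
        per_detected = []
        for sid in sids:
            st = stacks[sid]
            det = np.asarray(st.matrix.sum(axis=1)).ravel() > 0
            per_detected.append({st.gene_ids[i] for i in np.nonzero(det)[0]})
        replicated_gene_filter = set.intersection(*per_detected)
    genes = consensus_genes & replicated_gene_filter
    if annotation is not None:
        keep_ann = set(annotation.loc[
            annotation["biotype"].str.contains("protein_coding", case=False)
            & ~annotation["id"].isin(
                annotation.loc[annotation["biotype"].str.contains("ribo", case=False), "id"]
            ),
            "id",
        ])
        genes &= keep_ann
    if not genes:
        raise ValueError("no genes survive the consensus and replication filters")
    gene_order = sorted(genes)
    gene_pos = {g: i for i, g in enumerate(gene_order)}

    blocks, barcode_ids, specimen_of, dens = [], [], {}, []
    for sid in sids:
        st = stacks[sid]
        missing = genes - set(st.gene_ids)
        if missing and len(missing) == len(genes):
            raise ValueError(f"specimen {sid} shares no gene ids with the consensus set")
        full_den = np.asarray(st.matrix.sum(axis=0)).ravel()
        bidx = [i for i, b in enumerate(st.barcode_ids)
                if b in per_specimen_singlets.get(sid, set())]
        if not bidx:
            continue
        gid_idx = {g: i for i, g in enumerate(st.gene_ids)}
        sel_rows = [gid_idx[g] for g in gene_order if g in gid_idx]
        row_map = [gene_pos[g] for g in gene_order if g in gid_idx]
        sub = st.matrix[sel_rows][:, bidx]
        lifted = sp.lil_matrix((len(gene_order), len(bidx)), dtype=np.int64)
        lifted[row_map, :] = sub
        blocks.append(lifted.tocsr())
        for i in bidx:
            name = f"{sid}:{st.barcode_ids[i]}"
            barcode_ids.append(name)
            specimen_of[name] = sid
            dens.append(full_den[i])
    if not blocks:
        raise ValueError("no singlet barcodes to integrate")
    mat = sp.hstack(blocks).tocsr()
    stack = CountStack(mat, gene_order, barcode_ids)
    return stack, specimen_of, np.asarray(dens, dtype=float)


def post_stratification_retention(
    profiler_genes: Sequence[int],
    integrated_stack: CountStack,
    specimen_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-specimen retained/dropped singlet counts with median total UMI of each group.

    A singlet is retained when it carries at least one UMI of a Profiler
    gene. Dropped barcodes with conspicuously *higher* totals than
    retained ones behave like multi-cell barcodes whose normalized rates
    were diluted below the noise benchmark.
    """
    genes = sorted(set(int(g) for g in profiler_genes))
    totals = np.asarray(integrated_stack.matrix.sum(axis=0)).ravel()
    if genes:
        sub = integrated_stack.matrix.tocsr()[genes, :]
        retained_mask = np.asarray((sub > 0).sum(axis=0)).ravel() > 0
    else:
        retained_mask = np.zeros(integrated_stack.n_barcodes, dtype=bool)
    rows = []
    by_spec: dict[str, list[int]] = {}
    for i, b in enumerate(integrated_stack.barcode_ids):
        by_spec.setdefault(specimen_of[b], []).append(i)
    for sid in sorted(by_spec):
        idx = np.asarray(by_spec[sid])
        kept = idx[retained_mask[idx]]
        drop = idx[~retained_mask[idx]]
        rows.append({
            "specimen": sid,
            "n_retained": int(kept.size),
            "n_dropped": int(drop.size),
            "retention_rate": kept.size / idx.size if idx.size else np.nan,
            "median_umi_retained": float(np.median(totals[kept])) if kept.size else np.nan,
            "median_umi_dropped": float(np.median(totals[drop])) if drop.size else np.nan,
        })
    return pd.DataFrame(rows)
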