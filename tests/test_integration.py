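"""Consensus facultative selection and multi-replicate stack assembly."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from salsa.countstack import CountStack
from salsa.integration import (
    ConsensusSet,
    ReplicateDesign,
    assemble_integrated,
    consensus_facultative,
    post_stratification_retention,
)

from conftest import toy_stack


def design_of(spec_rounds, min_round_fraction=0.75):
    """ReplicateDesign from {specimen: round} with placeholder stacks."""
    dummy = toy_stack([(0, 0, 1)], 1, 1)
    return ReplicateDesign(
        specimens=[(sid, dummy, rid) for sid, rid in spec_rounds.items()],
        min_round_fraction=min_round_fraction,
    )


def brute_force_consensus(fac, spec_rounds, fraction):
    rounds = {}
    for sid, rid in spec_rounds.items():
        rounds.setdefault(rid, []).append(sid)
    batch = {rid: set.intersection(*(fac[s] for s in members))
             for rid, members in rounds.items()}
    need = math.ceil(fraction * len(batch))
    all_genes = set().union(*fac.values())
    return {g for g in all_genes
            if sum(g in s for s in batch.values()) >= need}, batch


class TestConsensusFacultative:
    SPEC_ROUNDS = {"s1": "d1", "s2": "d2", "s3": "d2", "s4": "d3",
                   "s5": "d3", "s6": "d3", "s7": "d4"}

    def test_three_of_four_rounds_included_at_075(self):
        fac = {s: {"G"} for s in self.SPEC_ROUNDS}
        fac["s7"] = set()  # round d4 misses the gene
        cons = consensus_facultative(fac, design_of(self.SPEC_ROUNDS))
        assert "G" in cons.consensus_genes
        with pytest.raises(ValueError):
            consensus_facultative(fac, design_of(self.SPEC_ROUNDS, 1.0))

    def test_partial_round_agreement_is_not_batch_consistent(self):
        fac = {"a": {"G", "H"}, "b": {"H"}, "c": {"G", "H"}}
        cons = consensus_facultative(fac, design_of({"a": "d1", "b": "d1", "c": "d1"},
                                                    min_round_fraction=1.0))
        assert cons.batch_consistent["d1"] == {"H"}
        assert cons.consensus_genes == {"H"}

    def test_randomized_designs_match_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(12)]
        for trial in range(25):
            n_spec = rng.integers(2, 7)
            spec_rounds = {f"s{i}": f"d{rng.integers(1, 4)}" for i in range(n_spec)}
            fac = {s: {g for g in genes if rng.random() < 0.5} for s in spec_rounds}
            if not set().union(*fac.values()):
                continue
            frac = float(rng.choice([0.5, 0.75, 1.0]))
            expected, batch = brute_force_consensus(fac, spec_rounds, frac)
            if not expected:
                with pytest.raises(ValueError):
                    consensus_facultative(fac, design_of(spec_rounds, frac))
                continue
            cons = consensus_facultative(fac, design_of(spec_rounds, frac))
            assert cons.consensus_genes == expected
            assert cons.batch_consistent == batch

    def test_adding_a_specimen_shrinks_batch_set(self):
        base = {"a": {"G", "H", "K"}, "b": {"G", "H"}}
        more = dict(base, c={"G"})
        d2 = design_of({"a": "d1", "b": "d1"}, 1.0)
        d3 = design_of({"a": "d1", "b": "d1", "c": "d1"}, 1.0)
        c2 = consensus_facultative(base, d2)
        c3 = consensus_facultative(more, d3)
        assert c3.batch_consistent["d1"] <= c2.batch_consistent["d1"]

    def test_single_round_reduces_to_intersection(self):
        fac = {"a": {"G", "H"}, "b": {"G"}}
        cons = consensus_facultative(fac, design_of({"a": "d1", "b": "d1"}))
        assert cons.consensus_genes == {"G"}


def specimen_stack(gene_ids, barcode_ids, dense):
    import scipy.sparse as sp

    return CountStack(sp.csr_matrix(np.asarray(dense)), list(gene_ids), list(barcode_ids))


class TestAssembleIntegrated:
    def test_disjoint_barcodes_concatenate_and_namespace(self):
        s1 = specimen_stack(["gA", "gB"], ["b1", "b2"], [[1, 2], [0, 3]])
        s2 = specimen_stack(["gA", "gB"], ["b1", "b3"], [[4, 0], [1, 1]])
        stack, spec_of, dens = assemble_integrated(
            {"s1": s1, "s2": s2}, {"gA", "gB"},
            {"s1": {"b1", "b2"}, "s2": {"b1", "b3"}})
        assert stack.n_barcodes == 4
        assert set(stack.barcode_ids) == {"s1:b1", "s1:b2", "s2:b1", "s2:b3"}
        assert spec_of["s2:b1"] == "s2"
        # denominators are within-specimen library totals
        d = dict(zip(stack.barcode_ids, dens))
        assert d["s1:b1"] == 1 and d["s2:b1"] == 5

    def test_gene_absent_from_one_specimen_excluded_by_replicated_filter(self):
        s1 = specimen_stack(["gA", "gB"], ["b1"], [[1], [1]])
        s2 = specimen_stack(["gA", "gB"], ["b2"], [[1], [0]])
        stack, _, _ = assemble_integrated(
            {"s1": s1, "s2": s2}, {"gA", "gB"},
            {"s1": {"b1"}, "s2": {"b2"}})
        assert stack.gene_ids == ["gA"]

    def test_integrated_occupancy_matches_dense_oracle(self, rng):
        dense1 = (rng.random((5, 6)) < 0.4) * rng.integers(1, 4, (5, 6))
        dense2 = (rng.random((5, 4)) < 0.4) * rng.integers(1, 4, (5, 4))
        genes = [f"g{i}" for i in range(5)]
        s1 = specimen_stack(genes, [f"x{i}" for i in range(6)], dense1)
        s2 = specimen_stack(genes, [f"y{i}" for i in range(4)], dense2)
        keep = {g for g in genes
                if dense1[genes.index(g)].sum() and dense2[genes.index(g)].sum()}
        stack, _, _ = assemble_integrated(
            {"s1": s1, "s2": s2}, set(genes),
            {"s1": {f"x{i}" for i in range(6)}, "s2": {f"y{i}" for i in range(4)}})
        rows = [genes.index(g) for g in stack.gene_ids]
        expected_nnz = int((dense1[rows] > 0).sum() + (dense2[rows] > 0).sum())
        assert stack.n_positive == expected_nnz

    def test_annotation_filter_drops_non_coding_and_ribosomal(self):
        s1 = specimen_stack(["gA", "gB", "gC"], ["b1"], [[1], [1], [1]])
        ann = pd.DataFrame({"id": ["gA", "gB", "gC"],
                            "biotype": ["protein_coding", "lincRNA",
                                        "protein_coding_ribosomal"]})
        stack, _, _ = assemble_integrated({"s1": s1}, {"gA", "gB", "gC"},
                                          {"s1": {"b1"}}, annotation=ann)
        assert stack.gene_ids == ["gA"]


class TestRetention:
    def test_all_cells_expressing_a_profiler_are_retained(self):
        s = specimen_stack(["gA", "gB"], ["b1", "b2"], [[1, 2], [1, 1]])
        stack, spec_of, _ = assemble_integrated({"s1": s}, {"gA", "gB"}, {"s1": {"b1", "b2"}})
        rep = post_stratification_retention([0], stack, spec_of)
        assert rep.loc[0, "retention_rate"] == 1.0

    def test_multiplet_like_dropouts_have_higher_totals(self):
        # cells 0-3 express the profiler modestly; cells 4-5 are high-total
        # barcodes whose counts avoid the profiler gene entirely
        dense = np.array([
            [1, 2, 1, 2, 0, 0],     # profiler gene
            [1, 1, 2, 1, 40, 55],   # everything else
        ])
        s = specimen_stack(["p", "q"], [f"b{i}" for i in range(6)], dense)
        stack, spec_of, _ = assemble_integrated({"s1": s}, {"p", "q"},
                                                {"s1": {f"b{i}" for i in range(6)}})
        gene_pos = stack.gene_ids.index("p")
        rep = post_stratification_retention([gene_pos], stack, spec_of)
        assert rep.loc[0, "n_dropped"] == 2
        assert rep.loc[0, "median_umi_dropped"] > rep.loc[0, "median_umi_retained"]

    def test_counts_match_bruteforce(self, rng):
        dense = (rng.random((4, 10)) < 0.5) * rng.integers(1, 3, (4, 10))
        s = specimen_stack([f"g{i}" for i in range(4)],
                           [f"b{i}" for i in range(10)], dense)
        stack, spec_of, _ = assemble_integrated(
            {"s1": s}, {f"g{i}" for i in range(4)},
            {"s1": {f"b{i}" for i in range(10)}})
        prof = [0, 2]
        rows = [stack.gene_ids.index(f"g{i}") for i in (0, 2)]
        rep = post_stratification_retention(rows, stack, spec_of)
        expected = sum(1 for c in range(10)
                       if any(dense[g, c] > 0 for g in (0, 2)))
        # barcode order inside the integrated stack may differ; compare counts
        col_of = {b: i for i, b in enumerate(stack.barcode_ids)}
        assert rep.loc[0, "n_retained"] == expected
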