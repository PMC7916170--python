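"""The synthetic-data generator: determinism, composition control, and
self-consistent truth tables."""

import numpy as np
import pytest

from nudimine.records import gc_fraction, revcomp, translate
from nudimine.simulate import (
    FragmentTruth,
    ParameterError,
    build_reference_model,
    evolve_virus,
    fragment_genome,
    simulate_dataset,
    simulate_reads,
    truth_gene_maps,
)
from nudimine.records import SequenceRecord


class TestReferenceModel:
    def test_genes_translate_cleanly(self):
        model = build_reference_model(100, 130_000, seed=11)
        assert len(model.genes) == 100
        for g in model.genes:
            assert g.protein.startswith("M")
            assert "*" not in g.protein
            cds = model.genome[g.start : g.end]
            if g.strand == "-":
                cds = revcomp(cds)
            assert translate(cds) == g.protein + "*"

    def test_gc_target_realized(self):
        model = build_reference_model(100, 130_000, gc=0.28, seed=5)
        assert 0.26 <= gc_fraction(model.genome) <= 0.30

    def test_deterministic(self):
        a = build_reference_model(20, 30_000, seed=3)
        b = build_reference_model(20, 30_000, seed=3)
        assert a.genome == b.genome
        assert a.genes == b.genes

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ParameterError):
            build_reference_model(100, 5_000, seed=0)

    def test_gene_order_indices(self, ref_model):
        assert [g.order_index for g in ref_model.genes] == list(range(30))
        assert any(g.is_core for g in ref_model.genes)


class TestEvolve:
    def test_zero_divergence_identity(self, ref_model):
        _, truth, _ = evolve_virus(ref_model, 0.0, 0.0, seed=1)
        ref = {g.gene_id: g.protein for g in ref_model.genes}
        assert all(t.protein == ref[t.ref_gene_id] for t in truth)
        assert all(t.identity_to_ref == 1.0 for t in truth)

    def test_mean_identity_tracks_divergence(self):
        model = build_reference_model(100, 130_000, seed=2)
        _, truth, _ = evolve_virus(model, 0.4, 0.0, seed=9)
        mean_ident = np.mean([t.identity_to_ref for t in truth])
        assert abs(mean_ident - 0.60) < 0.03

    def test_gene_loss_rate_binomial(self, ref_model):
        # 50 replicates at loss rate 0.1 on 30 genes: mean within the 99% CI
        losses = []
        for seed in range(50):
            _, truth, _ = evolve_virus(ref_model, 0.1, 0.1, seed=seed)
            losses.append(30 - len(truth))
        expected = 3.0
        se = np.sqrt(30 * 0.1 * 0.9 / 50)
        assert abs(np.mean(losses) - expected) < 2.58 * se

    def test_retained_genes_keep_order(self, ref_model):
        _, truth, _ = evolve_virus(ref_model, 0.2, 0.2, seed=4)
        ref_orders = [
            next(g.order_index for g in ref_model.genes if g.gene_id == t.ref_gene_id)
            for t in truth
        ]
        assert ref_orders == sorted(ref_orders)
        assert [t.order_index for t in truth] == list(range(len(truth)))


class TestFragment:
    def test_single_fragment_covers_nearly_all(self, ref_model):
        frags, truths = fragment_genome(ref_model.genome, 1, min_gap=1, seed=0)
        assert len(frags) == 1
        assert len(frags[0].seq) >= len(ref_model.genome) - 3

    def test_length_conservation(self, ref_model):
        frags, truths = fragment_genome(ref_model.genome, 5, min_gap=40, seed=2)
        total_frag = sum(len(f.seq) for f in frags)
        assert total_frag < len(ref_model.genome)
        gaps = len(ref_model.genome) - total_frag
        assert gaps >= 5 * 40  # every gap at least min_gap

    def test_emitted_sequences_match_truth_coordinates(self, ref_model):
        genome = ref_model.genome
        frags, truths = fragment_genome(genome, 4, min_gap=25, seed=3)
        double = genome + genome
        for frag, t in zip(frags, truths):
            expect = double[t.start : t.end]
            if t.orientation == "-":
                expect = revcomp(expect)
            assert frag.seq == expect

    def test_constructed_cut_marks_both_halves_partial(self):
        # a gene spanning [1000, 2000) cut at its midpoint
        from nudimine.simulate import TruthGene

        gene = TruthGene("nv1", "gene1", 1000, 2000, "+", "M" * 333, 1.0, False, 0)
        cut_truths = [
            FragmentTruth("F1", 0, 1500, "+"),
            FragmentTruth("F2", 1510, 3000, "+"),
        ]
        maps = truth_gene_maps([gene], cut_truths, 3000)
        left = maps[0].orfs[0]
        right = maps[1].orfs[0]
        assert (left.partial5, left.partial3) == (False, True)
        assert (right.partial5, right.partial3) == (True, False)


class TestReads:
    def test_closed_form_read_count(self, rng):
        from conftest import random_dna

        seq = SequenceRecord("f1", random_dna(rng, 6515))
        reads = simulate_reads([seq], coverage=18.5, read_length=100,
                               error_rate=0.0, seed=0)
        assert len(reads) == 1205  # round(18.5 * 6515 / 100)

    def test_error_free_reads_are_substrings(self, rng):
        from conftest import random_dna

        seq = SequenceRecord("f1", random_dna(rng, 3000))
        reads = simulate_reads([seq], coverage=3, read_length=100,
                               error_rate=0.0, seed=1)
        doubled = seq.seq
        for read in reads:
            assert read.seq in doubled or revcomp(read.seq) in doubled

    def test_realized_coverage_near_requested(self, rng):
        from conftest import random_dna

        seq = SequenceRecord("f1", random_dna(rng, 5000))
        covs = []
        for seed in range(20):
            reads = simulate_reads([seq], coverage=12, read_length=100,
                                   error_rate=0.0, seed=seed)
            covs.append(sum(len(r) for r in reads) / 5000)
        assert abs(np.mean(covs) - 12) / 12 < 0.02


class TestDataset:
    def test_deterministic(self):
        kwargs = dict(n_genes=8, genome_length=10_000, n_fragments=3,
                      min_gap=20, n_host=4, host_length_range=(300, 800),
                      coverage=5, seed=42)
        a = simulate_dataset(**kwargs)
        b = simulate_dataset(**kwargs)
        assert a.novel_genome == b.novel_genome
        assert a.fragments == b.fragments
        assert a.reads == b.reads
        assert [t.__dict__ for t in a.truth_genes] == [t.__dict__ for t in b.truth_genes]

    def test_truth_gene_maps_consistent_with_sequences(self, small_dataset):
        # every truth ORF piece flagged complete must translate from its fragment
        genome_len = len(small_dataset.novel_genome)
        by_id = {t.gene_id: t for t in small_dataset.truth_genes}
        frag_by_id = {f.id: f for f in small_dataset.fragments}
        for gm in small_dataset.gene_maps():
            for orf in gm.orfs:
                gene = by_id[orf.name]
                if orf.partial5 or orf.partial3:
                    continue
                frag = frag_by_id[gm.fragment_id]
                seq = frag.seq
                assert gene.protein[5:50] in translate(seq) or \
                    gene.protein[5:50] in translate(seq[1:]) or \
                    gene.protein[5:50] in translate(seq[2:]) or \
                    gene.protein[5:50] in translate(revcomp(seq)) or \
                    gene.protein[5:50] in translate(revcomp(seq)[1:]) or \
                    gene.protein[5:50] in translate(revcomp(seq)[2:])
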