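"""Paralog filtering, orthology verification, and the tiered detection cascade."""

import numpy as np
import pytest

from locusdrift.homology import (
    Baits,
    PipelineThresholds,
    call_gene_status,
    paralog_filter,
    verify_ortholog,
)
from locusdrift.homology.cascade import jc69_distance
from locusdrift.pipeline import detect_all
from locusdrift.sim import evolve_sequence, random_sequence, simulate
from conftest import small_config

TH = PipelineThresholds()


def protein_of(nt: str) -> str:
    from locusdrift.pipeline import _first_frame_protein

    return _first_frame_protein(nt)


class TestParalogFilter:
    def test_paralog_substring_discarded(self, rng):
        paralog = random_sequence(600, rng)
        contigs = {"hit": paralog[100:220], "other": random_sequence(120, rng)}
        kept = paralog_filter(contigs, paralog, TH)
        assert "hit" not in kept and "other" in kept

    def test_39nt_perfect_match_retained(self, rng):
        paralog = random_sequence(600, rng)
        contigs = {"short": paralog[10:49]}
        assert "short" in paralog_filter(contigs, paralog, TH)

    def test_idempotent(self, rng):
        paralog = random_sequence(500, rng)
        contigs = {
            "a": paralog[:200],
            "b": random_sequence(150, rng),
            "c": evolve_sequence(paralog[:200], 0.3, "JC69", rng),
        }
        once = paralog_filter(contigs, paralog, TH)
        assert paralog_filter(once, paralog, TH) == once

    def test_diverged_ortholog_passes_paralog_contig_fails(self, rng):
        # contigs from a near-identical paralog are discarded while contigs
        # from a diverged true ortholog survive, over seeded replicates
        ok = 0
        n = 20
        for seed in range(n):
            r = np.random.default_rng(seed)
            paralog_ref = random_sequence(600, r)
            paralog_contig = evolve_sequence(paralog_ref, 0.02, "JC69", r)[50:250]
            ortholog_contig = evolve_sequence(paralog_ref, 0.4, "JC69", r)[50:250]
            kept = paralog_filter(
                {"par": paralog_contig, "orth": ortholog_contig}, paralog_ref, TH
            )
            if "par" not in kept and "orth" in kept:
                ok += 1
        assert ok >= 0.95 * n


class TestVerifyOrtholog:
    def test_identical_candidate_accepted(self, rng):
        ref = random_sequence(300, rng)
        v = verify_ortholog(ref, ref, thresholds=TH)
        assert v.accepted and v.reason == "identity" and v.identity == 1.0

    def test_moderate_divergence_accepted_by_identity(self, rng):
        ref = random_sequence(600, rng)
        cand = evolve_sequence(ref, 0.15, "JC69", rng)
        v = verify_ortholog(cand, ref, thresholds=TH)
        assert v.accepted and v.reason == "identity"

    def test_divergence_is_jc69_corrected(self, rng):
        ref = random_sequence(5000, rng)
        cand = evolve_sequence(ref, 0.25, "JC69", rng)
        v = verify_ortholog(cand, ref, thresholds=TH)
        assert v.divergence == pytest.approx(jc69_distance(1 - v.identity))
        assert v.divergence == pytest.approx(0.25, rel=0.15)

    def test_short_alignment_rejected(self, rng):
        # candidate aligning over only ~19 aa of the target family
        ref = random_sequence(900, rng)
        panel_prot = protein_of(ref)
        cand = evolve_sequence(ref, 1.2, "JC69", rng)[:57]  # 19 codons, saturated
        baits = Baits(
            protein=panel_prot,
            nucleotide=ref,
            panel=(("target", panel_prot),),
        )
        v = verify_ortholog(cand, ref, baits, TH)
        assert not v.accepted
        assert v.reason in ("short_alignment", "inconsistent_besthits", "low_identity",
                            "no_alignment")
        assert v.aligned_aa < TH.min_aligned_aa

    def test_fast_evolver_accepted_via_besthit_branch(self):
        # atypical ortholog beyond the identity cutoff but vouched for by an
        # honest labelled panel, over seeded replicates
        n, ok = 25, 0
        for seed in range(n):
            r = np.random.default_rng(1000 + seed)
            root = random_sequence(1200, r)
            paralog_root = evolve_sequence(root, 0.6, "JC69", r)
            # reference tip and candidate tip diverge far apart
            ref_tip = evolve_sequence(root, 0.1, "JC69", r)
            cand = evolve_sequence(root, 0.55, "JC69", r)
            baits = Baits(
                protein=protein_of(ref_tip),
                nucleotide=ref_tip,
                paralog_nucleotide=paralog_root,
                panel=(
                    ("target", protein_of(ref_tip)),
                    ("target", protein_of(evolve_sequence(root, 0.12, "JC69", r))),
                    ("paralog", protein_of(paralog_root)),
                    ("paralog", protein_of(evolve_sequence(paralog_root, 0.1, "JC69", r))),
                ),
            )
            v = verify_ortholog(cand, ref_tip, baits, TH)
            if v.accepted and v.reason == "besthit_consistency":
                ok += 1
        assert ok >= 0.9 * n

    def test_empty_candidate_rejected(self):
        with pytest.raises(ValueError):
            verify_ortholog("", "ACGT", thresholds=TH)


class TestCallGeneStatus:
    def test_annotation_tier_lookup(self, small_sim):
        res = small_sim
        sp = "anseriform"
        genome = res.tables[sp]
        baits = Baits(
            protein=protein_of(res.root_seqs["G01"]),
            nucleotide=res.root_seqs["G01"],
        )
        rec = call_gene_status("G01", sp, genome, res.seqs[sp], None, baits, TH)
        assert rec.status == "detected" and rec.tier == "annotation"

    def test_missing_bait_rejected(self, small_sim):
        with pytest.raises(ValueError):
            call_gene_status(
                "G01", "anseriform", small_sim.tables["anseriform"], None, None,
                Baits(protein="", nucleotide=""), TH,
            )

    def test_deleted_gene_not_detected_with_all_tiers_recorded(self, small_sim):
        res = small_sim
        ev = res.truth.events[0]
        gene = sorted(ev.lost)[0]
        sp = "galliform_A"
        baits = Baits(
            protein=protein_of(res.root_seqs[gene]),
            nucleotide=res.root_seqs[gene],
            paralog_nucleotide=res.root_seqs["G03_paralog"],
        )
        rec = call_gene_status(
            gene, sp, res.tables[sp], res.seqs[sp], res.reads[sp], baits, TH
        )
        assert rec.status == "not_detected"
        assert rec.tiers_tried == ["annotation", "assembly", "reads"]

    def test_reads_tier_recovers_unannotated_gene(self, small_sim):
        # gene present in reads but removed from annotation and assembly
        res = small_sim
        sp = "ratite"
        gene = "G02"
        genome_df = res.tables[sp].df
        from locusdrift.synteny import GenomeTable

        genome = GenomeTable(genome_df[genome_df["gene"] != gene], species=sp)
        seqs = {g: s for g, s in res.seqs[sp].items() if g != gene}
        baits = Baits(
            protein=protein_of(res.root_seqs[gene]),
            nucleotide=res.root_seqs[gene],
            paralog_nucleotide=res.root_seqs["G03_paralog"],
        )
        rec = call_gene_status(gene, sp, genome, seqs, res.reads[sp], baits, TH)
        assert rec.status == "detected"
        assert rec.tier == "reads"

    def test_assembly_tier_via_translated_search(self, small_sim):
        # gene unannotated but its sequence still among the assembly records
        res = small_sim
        sp = "ratite"
        gene = "G04"
        from locusdrift.synteny import GenomeTable

        genome_df = res.tables[sp].df
        genome = GenomeTable(genome_df[genome_df["gene"] != gene], species=sp)
        baits = Baits(
            protein=protein_of(res.root_seqs[gene]),
            nucleotide=res.root_seqs[gene],
            paralog_nucleotide=res.root_seqs["G03_paralog"],
        )
        rec = call_gene_status(gene, sp, genome, res.seqs[sp], None, baits, TH)
        assert rec.status == "detected"
        assert rec.tier == "assembly"

    def test_bitscore_monotonicity(self, small_sim):
        # raising the relaxed floor never converts not_detected into detected
        res = small_sim
        sp = "ratite"
        gene = "G04"
        from locusdrift.synteny import GenomeTable

        genome_df = res.tables[sp].df
        genome = GenomeTable(genome_df[genome_df["gene"] != gene], species=sp)
        baits = Baits(
            protein=protein_of(res.root_seqs[gene]),
            nucleotide=res.root_seqs[gene],
            paralog_nucleotide=res.root_seqs["G03_paralog"],
        )
        detected_at = []
        for floor in (25.0, 200.0, 100000.0):
            th = PipelineThresholds(relaxed_min_bitscore=floor)
            rec = call_gene_status(gene, sp, genome, res.seqs[sp], None, baits, th)
            detected_at.append(rec.status == "detected")
        assert detected_at == sorted(detected_at, reverse=True)


class TestCascadeSoundness:
    def test_precision_recall_on_simulations(self):
        # end-to-end recovery across seeded scenarios with a diverged paralog
        tp = fp = fn = 0
        for seed in (101, 202, 303):
            res = simulate(small_config(seed=seed, paralog_divergence=0.5))
            presence, _ = detect_all(res, TH)
            for sp in presence.columns:
                lost = res.truth.lost_in(sp, res.tree)
                for gene in presence.index:
                    truly = gene not in lost
                    called = bool(presence.loc[gene, sp])
                    tp += called and truly
                    fp += called and not truly
                    fn += (not called) and truly
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.95
        assert recall >= 0.95
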