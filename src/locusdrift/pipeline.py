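"""End-to-end orchestration.

``run_pipeline`` executes the stages in dependency order on a synthetic
scenario: simulate -> detect (three-tier cascade) -> synteny (fate calls) ->
substitution mapping -> rates (branch lengths, root-to-tip, group
comparison).  In synthetic mode the report carries a recovery section scoring
every stage against the simulator's ground truth.

``fixture_report`` runs the synteny/fate machinery on the bundled transcribed
tables and returns the worked-example counts (disrupted-segment size, genes
undetected in all Galliformes, genes salvaged in all Galliformes).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import fixtures
from .homology import Baits, DetectionRecord, PipelineThresholds, call_gene_status
from .homology.cascade import ReadIndex
from .rates import (
    GroupComparison,
    RateTable,
    compare_groups,
    fit_branch_lengths,
    root_to_tip,
)
from .sim import SimConfig, SimResult, simulate
from .substmap import AlignedSet, map_substitutions, reconstruct_ancestor
from .synteny import (
    DisruptionReport,
    classify_fates,
    find_blocks,
    map_to_reference,
)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "fixture_report", "load_fixture"]

# re-exported for the fixture-mode entry point
load_fixture = fixtures.load_fixture


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    Exactly one input mode is active: a :class:`SimConfig` (synthetic mode)
    or paths to real inputs.  ``rate_genes`` restricts the (expensive)
    branch-length stage to a subset of genes; None fits every gene.
    """

    sim: SimConfig | None = None
    genomes_dir: str | None = None
    thresholds: PipelineThresholds = field(default_factory=PipelineThresholds)
    seed: int = 0
    out_dir: str | None = None
    run_detection: bool = True
    run_synteny: bool = True
    run_substmap: bool = True
    run_rates: bool = True
    rate_genes: Sequence[str] | None = None
    use_reads_tier: bool = True

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.genomes_dir is None):
            raise ValueError("exactly one of sim config / real input paths must be set")

    def config_hash(self) -> str:
        payload = repr(
            (
                self.sim,
                self.genomes_dir,
                self.thresholds,
                self.seed,
                self.rate_genes,
                self.run_detection,
                self.run_synteny,
                self.run_substmap,
                self.run_rates,
                self.use_reads_tier,
            )
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    presence: pd.DataFrame | None = None           # genes x species, 1/0
    records: list[DetectionRecord] = field(default_factory=list)
    disruption: dict[str, DisruptionReport] = field(default_factory=dict)
    substmap_summary: dict[str, dict[str, int]] = field(default_factory=dict)
    rate_table: RateTable | None = None
    comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    recovery: dict | None = None                   # synthetic mode only

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# config_hash={self.config_hash} seed={self.seed}\n"
        if self.presence is not None:
            with open(out / "presence_matrix.tsv", "w") as fh:
                fh.write(header)
                self.presence.to_csv(fh, sep="\t")
        if self.records:
            with open(out / "detection_records.tsv", "w") as fh:
                fh.write(header)
                pd.DataFrame([r.to_dict() for r in self.records]).to_csv(
                    fh, sep="\t", index=False
                )
        for sp, rep in self.disruption.items():
            rep.write_json(out / f"disruption_{sp}.json")
        if self.rate_table is not None:
            with open(out / "rate_table.tsv", "w") as fh:
                fh.write(header)
                self.rate_table.df.to_csv(fh, sep="\t", index=False)
        summary = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "substmap_summary": self.substmap_summary,
            "comparisons": {k: v.to_dict() for k, v in self.comparisons.items()},
            "recovery": self.recovery,
        }
        (out / "report.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# synthetic-mode stages


def _first_frame_protein(nt: str) -> str:
    """Frame +1 translation (simulated genes are frame-aligned), stops as X.

    Stops are recoded so the bait can be used whole in local alignments."""
    from Bio.Seq import Seq

    sub = nt[: len(nt) - len(nt) % 3]
    return str(Seq(sub).translate()).replace("*", "X")


def _make_baits(result: SimResult) -> dict[str, Baits]:
    """Ancestral-reference baits plus an honest labelled panel per gene.

    The bait is the root (ancestral) sequence of each gene; the panel holds
    the outgroup and one basal ingroup tip for both the target family and the
    paralog family.
    """
    cfg = result.config
    paralog_id = f"{cfg.target_gene}_paralog"
    outgroup = cfg.outgroup
    ingroups = [sp for sp in result.species if sp != outgroup]
    basal = ingroups[0]
    baits: dict[str, Baits] = {}
    for gene, root_nt in result.root_seqs.items():
        if gene == paralog_id:
            continue
        panel: list[tuple[str, str]] = []
        for sp in (outgroup, basal):
            seq = result.seqs[sp].get(gene)
            if seq:
                panel.append(("target", _first_frame_protein(seq)))
            pseq = result.seqs[sp].get(paralog_id)
            if pseq:
                panel.append(("paralog", _first_frame_protein(pseq)))
        baits[gene] = Baits(
            protein=_first_frame_protein(root_nt),
            nucleotide=root_nt,
            paralog_nucleotide=result.root_seqs[paralog_id],
            panel=tuple(panel),
            target_label="target",
        )
    return baits


def detect_all(
    result: SimResult,
    thresholds: PipelineThresholds,
    use_reads_tier: bool = True,
) -> tuple[pd.DataFrame, list[DetectionRecord]]:
    """Run the cascade for every reference gene in every species."""
    import dataclasses

    baits = _make_baits(result)
    paralog_id = f"{result.config.target_gene}_paralog"
    genes = [g for g, _ in result.reference_order]
    species = [sp for sp in result.species if sp != result.config.outgroup]
    records: list[DetectionRecord] = []
    presence = pd.DataFrame(0, index=genes, columns=species, dtype=int)
    read_indices: dict[str, ReadIndex] = {}
    for sp in species:
        genome = result.tables[sp]
        seqs = {
            f"{sp}|{g}|{genome.scaffold_of(g)}": s for g, s in result.seqs[sp].items()
        }
        # the paralog filter screens against the species' own paralog copy
        # (reads come from it verbatim); fall back to the ancestral copy
        sp_paralog = result.seqs[sp].get(paralog_id, result.root_seqs[paralog_id])
        sp_baits = {
            g: dataclasses.replace(b, paralog_nucleotide=sp_paralog)
            for g, b in baits.items()
        }
        for gene in genes:
            reads = None
            if use_reads_tier:
                if gene not in genome and sp not in read_indices:
                    read_indices[sp] = ReadIndex(result.reads[sp], thresholds.read_seed_k)
                reads = read_indices.get(sp)
            rec = call_gene_status(
                gene, sp, genome, seqs, reads, sp_baits[gene], thresholds
            )
            records.append(rec)
            presence.loc[gene, sp] = int(rec.status == "detected")
    return presence, records


def synteny_all(
    result: SimResult, presence: pd.DataFrame
) -> dict[str, DisruptionReport]:
    reports = {}
    for sp in presence.columns:
        placements = map_to_reference(result.reference_order, result.tables[sp])
        detected = {g: bool(presence.loc[g, sp]) for g in presence.index}
        blocks = find_blocks(result.reference_order, placements)
        reports[sp] = classify_fates(
            result.reference_order, placements, detected, blocks, species=sp
        )
    return reports


def substmap_summary(result: SimResult) -> dict[str, dict[str, int]]:
    """Ancestor-vs-tip substitution classes for the target gene's protein."""
    cfg = result.config
    gene = cfg.target_gene
    carriers = [
        sp for sp in result.species
        if sp != cfg.outgroup and gene in result.seqs[sp]
    ]
    if len(carriers) < 2:
        return {}
    aln = AlignedSet(
        ids=list(carriers),
        rows=[_first_frame_protein(result.seqs[sp][gene]) for sp in carriers],
        alphabet="protein",
    )
    sub = result.tree.extract_tree_with_taxa_labels(carriers)
    ancestor = reconstruct_ancestor(aln, sub.as_string(schema="newick"))
    out = {}
    for sp in carriers:
        m = map_substitutions(ancestor, aln.row(sp), ancestor_id="ancestor", descendant_id=sp)
        out[sp] = m.counts()
    return out


def rates_stage(
    result: SimResult,
    reports: Mapping[str, DisruptionReport],
    rate_genes: Sequence[str] | None = None,
) -> tuple[RateTable, dict[str, GroupComparison]]:
    """Fit per-gene branch lengths and compare salvaged vs intact rates.

    Group labels per (gene, species) come from the synteny fate calls:
    ``salvaged_locus`` for salvaged locus genes, ``intact_locus`` for locus
    genes retained in place, ``outside_locus`` for flank genes.
    """
    cfg = result.config
    outgroup = cfg.outgroup
    locus_ids = {g.gene_id for g in cfg.locus}
    genes = [g for g, _ in result.reference_order]
    if rate_genes is not None:
        genes = [g for g in genes if g in set(rate_genes)]
    table = RateTable()
    for gene in genes:
        carriers = [sp for sp in result.species if gene in result.seqs.get(sp, {})]
        ingroup = [sp for sp in carriers if sp != outgroup]
        if outgroup not in carriers or len(ingroup) < 2:
            continue
        aln = AlignedSet(
            ids=carriers,
            rows=[result.seqs[sp][gene] for sp in carriers],
            alphabet="nucleotide",
        )
        sub = result.tree.extract_tree_with_taxa_labels(carriers)
        for e in sub.preorder_edge_iter():  # neutral initialisation: data decide
            if e.head_node.parent_node is not None:
                e.length = 0.05
        blt = fit_branch_lengths(sub, aln, model=cfg.subst_model, kappa=cfg.kappa,
                                 outgroup=outgroup)
        for sp in ingroup:
            fate = reports[sp].fates.get(gene) if sp in reports else None
            if gene in locus_ids:
                group = "salvaged_locus" if fate == "salvaged" else "intact_locus"
            else:
                group = "outside_locus"
            table.add(gene, sp, root_to_tip(blt, sp), group)
    comparisons: dict[str, GroupComparison] = {}
    salv = table.group_values("salvaged_locus")
    for other in ("intact_locus", "outside_locus"):
        vals = table.group_values(other)
        if salv.size >= 3 and vals.size >= 3:
            comparisons[f"salvaged_vs_{other}"] = compare_groups(salv, vals)
    return table, comparisons


def score_recovery(
    result: SimResult,
    presence: pd.DataFrame,
    reports: Mapping[str, DisruptionReport],
) -> dict:
    """Detection precision/recall and fate accuracy against the truth log."""
    truth = result.truth
    tp = fp = fn = tn = 0
    fate_ok = fate_total = 0
    for sp in presence.columns:
        lost = truth.lost_in(sp, result.tree)
        salvaged = truth.salvaged_in(sp, result.tree)
        for gene in presence.index:
            truly_present = gene not in lost
            called = bool(presence.loc[gene, sp])
            if called and truly_present:
                tp += 1
            elif called and not truly_present:
                fp += 1
            elif not called and truly_present:
                fn += 1
            else:
                tn += 1
            true_fate = (
                "lost" if gene in lost
                else "salvaged" if gene in salvaged
                else "retained_in_locus"
            )
            fate_total += 1
            if reports and reports[sp].fates.get(gene) == true_fate:
                fate_ok += 1
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {
        "detection": {"tp": tp, "fp": fp, "fn": fn, "tn": tn,
                      "precision": precision, "recall": recall},
        "fate_accuracy": fate_ok / fate_total if fate_total else 1.0,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all enabled stages and assemble the report.

    Any stage failure propagates as an exception naming the stage; no partial
    report is written.
    """
    if config.sim is None:
        raise NotImplementedError(
            "real-input mode is exposed through the per-stage CLI verbs; "
            "run_pipeline drives the synthetic scenario"
        )
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    sim_cfg = config.sim
    if sim_cfg.seed != config.seed:
        sim_cfg = SimConfig(**{**sim_cfg.__dict__, "seed": config.seed})
    try:
        result = simulate(sim_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc

    presence = None
    reports: dict[str, DisruptionReport] = {}
    if config.run_detection:
        try:
            presence, records = detect_all(result, config.thresholds, config.use_reads_tier)
        except Exception as exc:
            raise RuntimeError(f"stage detect failed: {exc}") from exc
        report.presence = presence
        report.records = records
    if config.run_synteny and presence is not None:
        try:
            reports = synteny_all(result, presence)
        except Exception as exc:
            raise RuntimeError(f"stage synteny failed: {exc}") from exc
        report.disruption = reports
    if config.run_substmap:
        try:
            report.substmap_summary = substmap_summary(result)
        except Exception as exc:
            raise RuntimeError(f"stage substmap failed: {exc}") from exc
    if config.run_rates and reports:
        try:
            report.rate_table, report.comparisons = rates_stage(
                result, reports, config.rate_genes
            )
        except Exception as exc:
            raise RuntimeError(f"stage rates failed: {exc}") from exc
    if presence is not None:
        report.recovery = score_recovery(result, presence, reports)
    if config.out_dir:
        report.write(config.out_dir)
    return report


# ---------------------------------------------------------------------------
# fixture (worked-example) mode


def fixture_report() -> dict:
    """Worked-example counts from the bundled transcribed tables.

    Returns the chicken disrupted-segment size, the number of genes
    undetected in all four Galliformes, the number salvaged in all four, and
    the per-species fate calls.
    """
    ref, tables, matrix = fixtures.load_fixture("locus")
    genes = [g for g, _ in ref]
    galliformes = list(fixtures.GALLIFORM_SPECIES)

    per_species: dict[str, DisruptionReport] = {}
    for sp in galliformes:
        detected = {g: matrix.loc[g, sp] != "absent" for g in genes}
        if sp in tables:
            placements = map_to_reference(ref, tables[sp])
        else:
            placements = {g: None for g in genes}
        per_species[sp] = classify_fates(ref, placements, detected, species=sp)

    undetected_all = [
        g for g in genes if all(matrix.loc[g, sp] == "absent" for sp in galliformes)
    ]
    salvaged_all = [
        g for g in genes
        if all(per_species[sp].fates[g] == "salvaged" for sp in galliformes)
    ]
    chicken = per_species["chicken"]
    return {
        "disrupted_segment_size": chicken.disrupted_segment_size,
        "disrupted_segment_genes": [
            genes[i] for i in range(chicken.disrupted_segment[0], chicken.disrupted_segment[1] + 1)
        ] if chicken.disrupted_segment else [],
        "undetected_in_all_galliformes": undetected_all,
        "salvaged_in_all_galliformes": salvaged_all,
        "inversions_chicken": chicken.inversions,
        "reports": per_species,
    }
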