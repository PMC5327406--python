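"""The tiered presence/absence decision cascade.

For each (gene, species) the detector tries, in order:

tier ``annotation``
    name lookup in the species' annotation table;
tier ``assembly``
    translated (six-frame) similarity search of the species' assembled
    sequences with the reference protein as bait, gated by a relaxed bit-score
    floor;
tier ``reads``
    k-mer retrieval of raw reads matching the bait, greedy contig assembly,
    paralog filtering, and orthology verification of the surviving contigs.

A gene is ``detected`` at the first tier whose evidence passes verification;
``not_detected`` only after every available tier has failed.  Verification
accepts high-identity matches outright and passes fast-evolving candidates
through a best-hit consistency vote over a labelled reference panel,
mirroring how orthology of rapidly diverging genes is usually confirmed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import edlib

from ..synteny import GenomeTable
from .align import (
    LocalAlignment,
    bit_score,
    local_align,
    local_align_score,
    nucleotide_align,
    translate_six_frames,
)
from .assemble import greedy_assemble

__all__ = [
    "PipelineThresholds",
    "Baits",
    "Verdict",
    "DetectionRecord",
    "paralog_filter",
    "verify_ortholog",
    "call_gene_status",
]


@dataclass(frozen=True)
class PipelineThresholds:
    """Every numeric threshold used anywhere in the detection cascade.

    Defaults encode a desk-scale version of a relaxed-stringency homology
    search: a raw bit-score floor stands in for a permissive E-value cutoff,
    and the "consistent annotation of the first hits" rule becomes a top-k
    majority vote over a bundled labelled panel.
    """

    relaxed_min_bitscore: float = 25.0
    orf_min_aa: int = 50
    read_merge_identity: float = 0.97
    paralog_id: float = 0.95
    paralog_minlen_nt: int = 40
    ortholog_min_identity: float = 0.75
    fast_evolver_branchlength: float = 0.4
    min_aligned_aa: int = 20
    besthit_panel_top_k: int = 5
    assembler_min_overlap: int = 20
    read_seed_k: int = 16
    prescreen_min_identity: float = 0.30

    def __post_init__(self) -> None:
        for name in (
            "read_merge_identity",
            "paralog_id",
            "ortholog_min_identity",
            "prescreen_min_identity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "orf_min_aa",
            "paralog_minlen_nt",
            "min_aligned_aa",
            "besthit_panel_top_k",
            "assembler_min_overlap",
            "read_seed_k",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name}={v} must be a positive integer")


@dataclass(frozen=True)
class Baits:
    """Reference material for one gene family.

    ``panel`` is a labelled protein set (label, sequence) used for the
    best-hit consistency vote; ``target_label`` is the label that counts as
    the right family.
    """

    protein: str
    nucleotide: str
    paralog_nucleotide: str | None = None
    panel: tuple[tuple[str, str], ...] = ()
    target_label: str = "target"


@dataclass
class Verdict:
    accepted: bool
    reason: str                     # identity | besthit_consistency | low_identity |
                                    # short_alignment | inconsistent_besthits | no_alignment
    identity: float | None = None   # fraction over aligned core columns
    divergence: float | None = None  # JC69-corrected substitutions/site
    aligned_aa: int = 0


@dataclass
class DetectionRecord:
    gene_id: str
    species_id: str
    tier: str                       # annotation | assembly | reads | none
    status: str                     # detected | not_detected
    evidence: str = ""              # contig/sequence id of the accepted evidence
    identity: float | None = None
    divergence: float | None = None
    aligned_aa: int = 0
    tiers_tried: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# paralog filter


def _paralog_hit(seq: str, paralog_reference: str, thresholds: PipelineThresholds) -> bool:
    aln = nucleotide_align(seq, paralog_reference, mode="local")
    if aln.aligned_length == 0:
        return False
    identity = aln.percent_identity / 100.0
    return aln.aligned_length > thresholds.paralog_minlen_nt and identity > thresholds.paralog_id


def paralog_filter(
    contigs: Mapping[str, str] | Sequence[str],
    paralog_reference: str,
    thresholds: PipelineThresholds | None = None,
) -> dict[str, str]:
    """Discard contigs whose best local match to the paralog reference is
    long (> ``paralog_minlen_nt``) and near-identical (> ``paralog_id``);
    everything else is retained in order.  Idempotent by construction.
    """
    thresholds = thresholds or PipelineThresholds()
    if not isinstance(contigs, Mapping):
        contigs = {f"c{i:04d}": s for i, s in enumerate(contigs)}
    return {
        cid: seq
        for cid, seq in contigs.items()
        if not _paralog_hit(seq, paralog_reference, thresholds)
    }


# ---------------------------------------------------------------------------
# orthology verification


def jc69_distance(p: float) -> float:
    """JC69-corrected distance of a mismatch fraction; inf at saturation."""
    if p < 0:
        raise ValueError("negative mismatch fraction")
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def _core_identity(aln: LocalAlignment) -> tuple[float | None, int]:
    """Identity over aligned core columns, terminal gaps excluded.

    Returns (identity fraction or None when nothing aligns, compared columns).
    Internal gap columns are excluded from the denominator so the corrected
    distance is a substitution distance.
    """
    q, t = aln.aligned_query, aln.aligned_target
    # trim terminal gap columns
    start, end = 0, len(q)
    while start < end and (q[start] == "-" or t[start] == "-"):
        start += 1
    while end > start and (q[end - 1] == "-" or t[end - 1] == "-"):
        end -= 1
    matches = compared = 0
    for a, b in zip(q[start:end], t[start:end]):
        if a == "-" or b == "-":
            continue
        compared += 1
        if a == b:
            matches += 1
    if compared == 0:
        return None, 0
    return matches / compared, compared


def _besthit_vote(
    candidate_nt: str, baits: Baits, thresholds: PipelineThresholds
) -> tuple[str | None, int]:
    """Majority label over the top-k panel hits and the aligned aa length of
    the best target-family hit."""
    if not baits.panel:
        return None, 0
    frames = [f for f in translate_six_frames(candidate_nt).values() if f]
    scored: list[tuple[float, str, int]] = []
    for label, prot in baits.panel:
        best_score, best_frame = 0.0, None
        for frame in frames:
            # cheap edit-distance screen prunes out-of-frame translations
            if not _edlib_prescreen(prot, frame, 0.2) and not _edlib_prescreen(frame, prot, 0.2):
                continue
            s = local_align_score(frame, prot)
            if s > best_score:
                best_score, best_frame = s, frame
        best_aa = 0
        if best_frame is not None:
            aln = local_align(best_frame, prot)
            best_aa = sum(1 for c in aln.aligned_query if c != "-")
        scored.append((best_score, label, best_aa))
    scored.sort(key=lambda x: (-x[0], x[1]))
    top = [s for s in scored if s[0] > 0][: thresholds.besthit_panel_top_k]
    if not top:
        return None, 0
    counts: dict[str, int] = {}
    best_score: dict[str, float] = {}
    for score, label, _ in top:
        counts[label] = counts.get(label, 0) + 1
        best_score[label] = max(best_score.get(label, 0.0), score)
    # ties in hit counts go to the label with the strongest individual hit
    majority = sorted(
        counts.items(), key=lambda kv: (-kv[1], -best_score[kv[0]], kv[0])
    )[0][0]
    aligned_aa = max((aa for s, lab, aa in top if lab == baits.target_label), default=0)
    return majority, aligned_aa


def verify_ortholog(
    candidate: str,
    reference_ortholog: str,
    baits: Baits | None = None,
    thresholds: PipelineThresholds | None = None,
) -> Verdict:
    """Decide whether *candidate* is an ortholog of the reference.

    High global nucleotide identity (> ``ortholog_min_identity``, judged on
    aligned core columns with terminal gaps free) accepts outright.  A
    fast-evolving candidate (JC69-corrected divergence >
    ``fast_evolver_branchlength``) is accepted only when the best-hit majority
    over the labelled panel is the target family and the aligned protein
    length reaches ``min_aligned_aa``.
    """
    thresholds = thresholds or PipelineThresholds()
    if not candidate:
        raise ValueError("empty candidate sequence")
    if len(candidate) == len(reference_ortholog):
        # indel-free case: column-wise identity without alignment
        compared = len(candidate)
        matches = sum(1 for a, b in zip(candidate.upper(), reference_ortholog.upper()) if a == b)
        identity = matches / compared
    else:
        aln = nucleotide_align(candidate, reference_ortholog, mode="global")
        identity, compared = _core_identity(aln)
    if identity is None or compared == 0:
        return Verdict(False, "no_alignment")
    divergence = jc69_distance(1.0 - identity)
    if compared < 3 * thresholds.min_aligned_aa:
        # a candidate aligning over less than the 20-aa floor carries no
        # orthology signal no matter how identical the scrap is
        return Verdict(False, "short_alignment", identity, divergence, compared // 3)
    if identity > thresholds.ortholog_min_identity:
        return Verdict(True, "identity", identity, divergence)
    if divergence > thresholds.fast_evolver_branchlength and baits is not None:
        majority, aligned_aa = _besthit_vote(candidate, baits, thresholds)
        if majority == baits.target_label:
            if aligned_aa >= thresholds.min_aligned_aa:
                return Verdict(True, "besthit_consistency", identity, divergence, aligned_aa)
            return Verdict(False, "short_alignment", identity, divergence, aligned_aa)
        return Verdict(False, "inconsistent_besthits", identity, divergence, aligned_aa)
    return Verdict(False, "low_identity", identity, divergence)


# ---------------------------------------------------------------------------
# read retrieval


class ReadIndex:
    """Exact k-mer index over a read set for bait-driven retrieval."""

    def __init__(self, reads: Sequence[str], k: int = 16):
        self.k = k
        self.reads = list(reads)
        self._index: dict[str, set[int]] = {}
        for i, r in enumerate(self.reads):
            for p in range(0, len(r) - k + 1):
                self._index.setdefault(r[p : p + k], set()).add(i)

    def retrieve(self, bait_nt: str) -> dict[str, str]:
        """Reads sharing at least one exact k-mer with the bait."""
        hits: set[int] = set()
        k = self.k
        for p in range(0, len(bait_nt) - k + 1):
            hits |= self._index.get(bait_nt[p : p + k], set())
        return {f"r{i:06d}": self.reads[i] for i in sorted(hits)}


# ---------------------------------------------------------------------------
# the cascade


def _edlib_prescreen(bait_protein: str, frame: str, floor: float) -> bool:
    """Cheap infix-alignment screen: skip exact SW only when even the
    edit-distance bound rules out a plausible homology."""
    if not frame:
        return False
    res = edlib.align(bait_protein, frame, mode="HW", task="distance")
    d = res["editDistance"]
    if d < 0:
        return False
    return (1.0 - d / len(bait_protein)) >= floor


def _tier_assembly(
    baits: Baits,
    assembly_seqs: Mapping[str, str],
    thresholds: PipelineThresholds,
) -> tuple[str, LocalAlignment] | None:
    """Best assembly sequence whose translated similarity clears the relaxed
    bit-score floor; returns (sequence id, alignment) or None."""
    best: tuple[float, str, LocalAlignment] | None = None
    for sid in sorted(assembly_seqs):
        seq = assembly_seqs[sid]
        frames = translate_six_frames(seq)
        for frame in frames.values():
            if not _edlib_prescreen(baits.protein, frame, thresholds.prescreen_min_identity):
                continue
            score = local_align_score(baits.protein, frame)
            if score <= 0 or bit_score(score) < thresholds.relaxed_min_bitscore:
                continue
            if best is None or score > best[0]:
                aln = local_align(baits.protein, frame)
                best = (score, sid, aln)
    if best is None:
        return None
    return best[1], best[2]


def call_gene_status(
    gene: str,
    species: str,
    genome: GenomeTable | None,
    assembly_seqs: Mapping[str, str] | None,
    reads: Sequence[str] | ReadIndex | None,
    baits: Baits,
    thresholds: PipelineThresholds | None = None,
) -> DetectionRecord:
    """Run the full three-tier cascade for one gene in one species.

    ``assembly_seqs`` maps sequence id -> nucleotide sequence (the species'
    assembled gene models); ``reads`` is the raw read set or a prebuilt
    :class:`ReadIndex`.  Any tier may be absent (``None``).
    """
    thresholds = thresholds or PipelineThresholds()
    if not baits.protein or not baits.nucleotide:
        raise ValueError("baits must provide the reference protein and nucleotide sequence")
    tiers_tried: list[str] = []

    # tier 1: annotation lookup
    if genome is not None:
        tiers_tried.append("annotation")
        if gene in genome:
            verdict = None
            if assembly_seqs:
                seq = _annotation_sequence(gene, species, assembly_seqs)
                if seq:
                    verdict = verify_ortholog(seq, baits.nucleotide, baits, thresholds)
            # a name-lookup hit is trusted unless its sequence demonstrably
            # belongs to another family (best-hit vote contradicts the label)
            if verdict is None or verdict.reason != "inconsistent_besthits":
                return DetectionRecord(
                    gene_id=gene,
                    species_id=species,
                    tier="annotation",
                    status="detected",
                    evidence=gene,
                    identity=verdict.identity if verdict else None,
                    divergence=verdict.divergence if verdict else None,
                    aligned_aa=verdict.aligned_aa if verdict else 0,
                    tiers_tried=tiers_tried,
                )

    # tier 2: translated search of assembled sequences
    if assembly_seqs:
        tiers_tried.append("assembly")
        hit = _tier_assembly(baits, assembly_seqs, thresholds)
        if hit is not None:
            sid, aln = hit
            verdict = verify_ortholog(assembly_seqs[sid], baits.nucleotide, baits, thresholds)
            if verdict.accepted:
                return DetectionRecord(
                    gene_id=gene,
                    species_id=species,
                    tier="assembly",
                    status="detected",
                    evidence=sid,
                    identity=verdict.identity,
                    divergence=verdict.divergence,
                    aligned_aa=verdict.aligned_aa,
                    tiers_tried=tiers_tried,
                )

    # tier 3: read retrieval + assembly + paralog filter + verification
    if reads is not None:
        tiers_tried.append("reads")
        index = reads if isinstance(reads, ReadIndex) else ReadIndex(reads, thresholds.read_seed_k)
        candidates = index.retrieve(baits.nucleotide)
        if candidates:
            contigs = greedy_assemble(
                candidates,
                min_overlap=thresholds.assembler_min_overlap,
                min_identity=thresholds.read_merge_identity,
            )
            if baits.paralog_nucleotide:
                contigs = paralog_filter(contigs, baits.paralog_nucleotide, thresholds)
            for cid in sorted(contigs, key=lambda c: (-len(contigs[c]), c)):
                verdict = verify_ortholog(contigs[cid], baits.nucleotide, baits, thresholds)
                if verdict.accepted:
                    return DetectionRecord(
                        gene_id=gene,
                        species_id=species,
                        tier="reads",
                        status="detected",
                        evidence=cid,
                        identity=verdict.identity,
                        divergence=verdict.divergence,
                        aligned_aa=verdict.aligned_aa,
                        tiers_tried=tiers_tried,
                    )

    return DetectionRecord(
        gene_id=gene,
        species_id=species,
        tier="none",
        status="not_detected",
        tiers_tried=tiers_tried,
    )


def _annotation_sequence(
    gene: str, species: str, assembly_seqs: Mapping[str, str]
) -> str | None:
    """Find the annotated gene's own sequence among the assembly records."""
    if gene in assembly_seqs:
        return assembly_seqs[gene]
    for sid, seq in assembly_seqs.items():
        parts = sid.split("|")
        if gene in parts:
            return seq
    return None
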