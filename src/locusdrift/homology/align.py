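"""Alignment primitives: six-frame translation, affine-gap local alignment,
and position-specific scoring-matrix scans.

Local alignment is Smith-Waterman with affine gaps, delegated to Biopython's
C ``PairwiseAligner`` engine.  A gap of length L costs
``gap_open + gap_extend * L`` (so the aligner's open score is set to
``-(gap_open + gap_extend)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
# X for ambiguous codons, * for stops in raw frame translations
PROTEIN_EXTENDED = PROTEIN_ALPHABET | set("X*")

# Karlin-Altschul parameters for BLOSUM62 with affine gaps (11, 1)
KA_LAMBDA = 0.267
KA_K = 0.041


def bit_score(raw_score: float, lam: float = KA_LAMBDA, k: float = KA_K) -> float:
    """Normalised bit score of a raw substitution-matrix score."""
    return (lam * raw_score - math.log(k)) / math.log(2)


@dataclass(frozen=True)
class LocalAlignment:
    """One local alignment with affine gap costs."""

    score: float
    query_interval: tuple[int, int]   # 0-based half-open on the query
    target_interval: tuple[int, int]  # 0-based half-open on the target
    aligned_query: str
    aligned_target: str
    percent_identity: float           # over aligned columns (gaps count as columns)

    @property
    def aligned_length(self) -> int:
        return len(self.aligned_query)

    @property
    def ungapped_query_length(self) -> int:
        return sum(1 for c in self.aligned_query if c != "-")

    @property
    def bits(self) -> float:
        return bit_score(self.score)


EMPTY_ALIGNMENT = LocalAlignment(0.0, (0, 0), (0, 0), "", "", 0.0)


def _check_nucleotide(seq: str, extra: str = "N") -> None:
    allowed = set("ACGT") | set(extra)
    for i, c in enumerate(seq):
        if c not in allowed:
            raise ValueError(f"non-nucleotide symbol {c!r} at position {i}")


def _check_protein(seq: str) -> None:
    for i, c in enumerate(seq):
        if c not in PROTEIN_EXTENDED:
            raise ValueError(f"non-standard residue {c!r} at position {i}")


def translate_six_frames(seq: str) -> dict[str, str]:
    """Translate all six reading frames under the standard genetic code.

    Frames ``+1..+3`` read the given strand, ``-1..-3`` the reverse
    complement.  Codons containing ``N`` yield ``X``; stops are ``*``.
    """
    seq = seq.upper()
    _check_nucleotide(seq)
    fwd = Seq(seq)
    rev = fwd.reverse_complement()
    frames: dict[str, str] = {}
    for k in range(3):
        for label, s in ((f"+{k+1}", fwd), (f"-{k+1}", rev)):
            sub = s[k:]
            sub = sub[: len(sub) - len(sub) % 3]
            prot = list(str(sub.translate()))
            for i in range(len(prot)):
                # every N-containing codon is reported as unknown, even where
                # the code happens to be unambiguous
                if "N" in sub[3 * i : 3 * i + 3]:
                    prot[i] = "X"
            frames[label] = "".join(prot)
    return frames


def longest_orf_length(protein: str) -> int:
    """Length in aa of the longest stop-free stretch of a frame translation."""
    best = 0
    for run in protein.split("*"):
        best = max(best, len(run))
    return best


@lru_cache(maxsize=8)
def _protein_aligner(gap_open: float, gap_extend: float, matrix_name: str) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix_name)
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


@lru_cache(maxsize=8)
def _nt_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float, mode: str
) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = mode
    al.match_score = match
    al.mismatch_score = -abs(mismatch)
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    if mode == "global":
        # free end gaps: identity is judged on the aligned core
        try:
            al.open_end_insertion_score = 0
            al.extend_end_insertion_score = 0
            al.open_end_deletion_score = 0
            al.extend_end_deletion_score = 0
        except AttributeError:  # Biopython < 1.86 naming
            al.target_end_open_gap_score = 0
            al.target_end_extend_gap_score = 0
            al.query_end_open_gap_score = 0
            al.query_end_extend_gap_score = 0
    return al


def _from_biopython(alignment, query: str, target: str) -> LocalAlignment:
    # Bio.Align convention: sequence 0 is the target, 1 the query
    t_aln = str(alignment[0])
    q_aln = str(alignment[1])
    coords = alignment.coordinates
    t_iv = (int(coords[0][0]), int(coords[0][-1]))
    q_iv = (int(coords[1][0]), int(coords[1][-1]))
    cols = len(q_aln)
    matches = sum(1 for a, b in zip(q_aln, t_aln) if a == b and a != "-")
    pid = 100.0 * matches / cols if cols else 0.0
    return LocalAlignment(
        score=float(alignment.score),
        query_interval=q_iv,
        target_interval=t_iv,
        aligned_query=q_aln,
        aligned_target=t_aln,
        percent_identity=pid,
    )


def local_align(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> LocalAlignment:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Returns the empty alignment (score 0) when no positive-scoring pair of
    segments exists.  Traceback is deterministic (the aligner's canonical
    path order).
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    _check_protein(query)
    _check_protein(target)
    al = _protein_aligner(gap_open, gap_extend, matrix)
    score = al.score(target, query)
    if score <= 0:
        return EMPTY_ALIGNMENT
    return _from_biopython(al.align(target, query)[0], query, target)


def local_align_score(
    query: str,
    target: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Score-only fast path of :func:`local_align`."""
    al = _protein_aligner(gap_open, gap_extend, matrix)
    return max(0.0, float(al.score(target, query)))


def nucleotide_align(
    query: str,
    target: str,
    match: float = 1.0,
    mismatch: float = 1.0,
    gap_open: float = 5.0,
    gap_extend: float = 2.0,
    mode: str = "local",
) -> LocalAlignment:
    """Nucleotide alignment with +match/-mismatch scoring.

    ``mode="local"`` is Smith-Waterman; ``mode="global"`` is a
    Needleman-Wunsch variant with free end gaps, suited to comparing a
    partial candidate against a full-length reference.
    """
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    _check_nucleotide(query.upper())
    _check_nucleotide(target.upper())
    al = _nt_aligner(match, mismatch, gap_open, gap_extend, mode)
    if mode == "local" and al.score(target.upper(), query.upper()) <= 0:
        return EMPTY_ALIGNMENT
    return _from_biopython(al.align(target.upper(), query.upper())[0], query, target)


# ---------------------------------------------------------------------------
# PSSM

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA_ORDER)}


def build_pssm(block: list[str], pseudocount: float = 0.5) -> np.ndarray:
    """Log-odds PSSM (columns x 20) from an ungapped aligned protein block.

    Background is uniform (1/20); entries are natural-log odds of the
    pseudocount-smoothed column frequencies.
    """
    if not block:
        raise ValueError("empty block")
    L = len(block[0])
    if any(len(s) != L for s in block):
        raise ValueError("block rows must have equal length")
    counts = np.full((L, 20), pseudocount)
    for s in block:
        for j, c in enumerate(s):
            if c in _AA_INDEX:
                counts[j, _AA_INDEX[c]] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    return np.log(freqs / (1.0 / 20.0))


def pssm_scan(
    profile: np.ndarray, target: str, min_score: float
) -> list[tuple[int, float]]:
    """All windows of *target* scoring >= min_score under the profile.

    Returns ``(offset, score)`` pairs sorted by score descending, then
    position.  Residues outside the 20-letter alphabet (X, stops) contribute
    score 0 in their column.
    """
    L = profile.shape[0]
    n = len(target)
    if n < L:
        return []
    idx = np.array([_AA_INDEX.get(c, -1) for c in target])
    # per-position per-profile-column score with unknown residues scoring 0
    hits = []
    for off in range(n - L + 1):
        w = idx[off : off + L]
        ok = w >= 0
        s = float(profile[np.nonzero(ok)[0], w[ok]].sum())
        if s >= min_score:
            hits.append((off, s))
    hits.sort(key=lambda h: (-h[1], h[0]))
    return hits
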