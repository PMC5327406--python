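"""Greedy overlap-merge read assembly.

A deliberately simple, fully deterministic stand-in for a de novo assembler:
repeatedly merge the pair of sequences with the best suffix/prefix overlap
(identity first, then overlap length, then lexicographic ids) until no pair
overlaps by at least ``min_overlap`` bases at ``min_identity`` or better.
Reads are treated as single-stranded; containment (an overlap covering the
whole right-hand sequence) absorbs the contained sequence.

Small inputs (<= 50 sequences) are compared exhaustively over all overlap
lengths.  Larger sets seed candidate overlaps with exact end 12-mers, which
can miss an overlap whose seed region carries a sequencing error; this is the
usual overlap-layout compromise and is documented in the methods note.
"""

from __future__ import annotations

from typing import Mapping, Sequence

__all__ = ["greedy_assemble"]

_SEED_K = 12
_EXHAUSTIVE_LIMIT = 50

Candidate = tuple[float, int, str, str]  # identity, overlap, left id, right id


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _best_overlap_exhaustive(a: str, b: str, min_overlap: int, min_identity: float):
    """Longest suffix(a)/prefix(b) overlap meeting the identity floor."""
    for ov in range(min(len(a), len(b)), min_overlap - 1, -1):
        mism = _hamming(a[-ov:], b[:ov])
        if mism <= (1.0 - min_identity) * ov:
            return (1.0 - mism / ov, ov)
    return None


def _best_overlap_seeded(a: str, b: str, k: int, min_overlap: int, min_identity: float):
    """Overlaps implied by occurrences of b's leading k-mers inside a.

    Two seed offsets (0 and k) are tried so a sequencing error inside the
    first seed window does not hide an otherwise valid overlap.
    """
    best = None
    for s in (0, k):
        seed = b[s : s + k]
        if len(seed) < k:
            break
        p = a.find(seed)
        while p != -1:
            start = p - s  # implied start of b within/behind a
            if start >= 0:
                ov = min(len(a) - start, len(b))
                if ov >= min_overlap:
                    mism = _hamming(a[start : start + ov], b[:ov])
                    if mism <= (1.0 - min_identity) * ov:
                        cand = (1.0 - mism / ov, ov)
                        if best is None or cand > best:
                            best = cand
            p = a.find(seed, p + 1)
    return best


def _pair_candidate(
    a: str, b: str, sa: str, sb: str, k: int, min_overlap: int, min_identity: float, exhaustive: bool
) -> Candidate | None:
    # the seeded scan also covers containment (b matching inside a), which
    # the suffix/prefix scan cannot see, so it runs in both modes
    res = _best_overlap_seeded(sa, sb, k, min_overlap, min_identity)
    if exhaustive:
        res2 = _best_overlap_exhaustive(sa, sb, min_overlap, min_identity)
        if res2 is not None and (res is None or res2 > res):
            res = res2
    if res is None:
        return None
    return (res[0], res[1], a, b)


def greedy_assemble(
    reads: Sequence[str] | Mapping[str, str],
    min_overlap: int = 20,
    min_identity: float = 0.97,
) -> dict[str, str]:
    """Assemble reads into contigs by greedy highest-identity overlap merging.

    Accepts a sequence of read strings (auto-named ``r000000`` ...) or a
    mapping id -> sequence.  Returns contig id -> sequence; a merged contig
    keeps the id of its left (suffix-side) member.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if isinstance(reads, Mapping):
        contigs = dict(reads)
    else:
        contigs = {f"r{i:06d}": s for i, s in enumerate(reads)}
    contigs = {k: v for k, v in contigs.items() if v}
    if len(contigs) <= 1:
        return contigs

    exhaustive = len(contigs) <= _EXHAUSTIVE_LIMIT
    k = min(_SEED_K, min_overlap)

    def pairs_for(ids_a, ids_b):
        out: dict[tuple[str, str], Candidate] = {}
        for a in ids_a:
            for b in ids_b:
                if a == b:
                    continue
                c = _pair_candidate(
                    a, b, contigs[a], contigs[b], k, min_overlap, min_identity, exhaustive
                )
                if c is not None:
                    out[(a, b)] = c
        return out

    ids = sorted(contigs)
    candidates = pairs_for(ids, ids)

    while candidates:
        # best by identity desc, overlap desc, then lexicographic ids
        ident, ov, a, b = sorted(
            candidates.values(), key=lambda c: (-c[0], -c[1], c[2], c[3])
        )[0]
        sa, sb = contigs[a], contigs[b]
        contigs[a] = sa if ov >= len(sb) else sa + sb[ov:]
        del contigs[b]
        candidates = {
            key: c for key, c in candidates.items() if a not in key and b not in key
        }
        others = [x for x in contigs if x != a]
        candidates.update(pairs_for([a], others))
        candidates.update(pairs_for(others, [a]))
    return contigs
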