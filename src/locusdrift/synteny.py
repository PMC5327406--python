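"""Gene-order (synteny) comparison against a reference locus.

A species genome is summarised as a :class:`GenomeTable` of ordered, stranded
gene annotations.  Comparing a target species against a reference locus order
(a signed gene list) yields maximal synteny blocks, inversion intervals,
breakpoints, the maximal disrupted segment, and a per-gene fate call:

``retained_in_locus``
    the gene still sits next to at least one of its ancestral neighbours;
``salvaged``
    the gene is detectable but has moved out of its ancestral syntenic
    context (typically to a scaffold carrying only one or two locus genes);
``lost``
    the gene is not detected at any evidence tier.

Coordinates in TSV I/O are 1-based inclusive; all internal indices are
0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "GenomeTable",
    "SyntenyBlock",
    "DisruptionReport",
    "Placement",
    "extract_locus",
    "map_to_reference",
    "find_blocks",
    "detect_inversions",
    "count_breakpoints",
    "classify_fates",
]

_STRAND_TO_SIGN = {"+": 1, "-": -1}
_SIGN_TO_STRAND = {1: "+", -1: "-"}

SignedGene = tuple[str, int]  # (gene_id, +1/-1)


class GenomeTableError(ValueError):
    """Raised for malformed annotation tables."""


@dataclass
class GenomeTable:
    """Ordered, stranded gene annotations for one species.

    Backed by a DataFrame with columns ``gene, scaffold, start, end, strand``
    (1-based inclusive coordinates, strand ``+``/``-``).
    """

    df: pd.DataFrame
    species: str = ""

    REQUIRED = ("gene", "scaffold", "start", "end", "strand")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise GenomeTableError(f"missing columns: {missing}")
        df = self.df.copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        if (df["start"] > df["end"]).any():
            bad = df[df["start"] > df["end"]]["gene"].tolist()
            raise GenomeTableError(f"start > end for genes {bad}")
        if df["gene"].duplicated().any():
            dup = df[df["gene"].duplicated()]["gene"].tolist()
            raise GenomeTableError(f"duplicate gene ids: {dup}")
        bad_strand = set(df["strand"]) - set("+-")
        if bad_strand:
            raise GenomeTableError(f"bad strand symbols: {sorted(bad_strand)}")
        # no two records on one scaffold may overlap
        for scaf, grp in df.groupby("scaffold"):
            g = grp.sort_values("start")
            prev_end = None
            prev_gene = None
            for _, row in g.iterrows():
                if prev_end is not None and row["start"] <= prev_end:
                    raise GenomeTableError(
                        f"overlap on {scaf}: {prev_gene} and {row['gene']}"
                    )
                prev_end, prev_gene = row["end"], row["gene"]
        self.df = df.sort_values(["scaffold", "start"]).reset_index(drop=True)

    @classmethod
    def read_tsv(cls, path: str | Path, species: str = "") -> "GenomeTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(df, species=species or Path(path).stem)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def scaffold_order(self, scaffold: str) -> list[SignedGene]:
        """Genes of one scaffold in coordinate order, with strand signs."""
        grp = self.df[self.df["scaffold"] == scaffold].sort_values("start")
        return [(g, _STRAND_TO_SIGN[s]) for g, s in zip(grp["gene"], grp["strand"])]

    def scaffold_of(self, gene: str) -> str:
        row = self.df[self.df["gene"] == gene]
        if row.empty:
            raise KeyError(gene)
        return str(row.iloc[0]["scaffold"])

    def __contains__(self, gene: str) -> bool:
        return bool((self.df["gene"] == gene).any())

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class Placement:
    """Where one reference gene landed in a target genome."""

    scaffold: str
    index: int  # rank among mapped reference genes on that scaffold
    sign: int   # strand relative to annotation (+1/-1)


@dataclass(frozen=True)
class SyntenyBlock:
    """Maximal run of present reference genes with conserved target adjacency.

    ``ref_indices`` lists the member genes' reference indices; absent
    reference genes may lie between members without breaking the block.
    """

    ref_indices: tuple[int, ...]
    scaffold: str
    target_indices: tuple[int, ...]
    orientation: str        # "same" | "inverted"

    @property
    def ref_start(self) -> int:
        return self.ref_indices[0]

    @property
    def ref_end(self) -> int:
        return self.ref_indices[-1]

    @property
    def size(self) -> int:
        return len(self.ref_indices)


@dataclass
class DisruptionReport:
    """Summary of one target-vs-reference locus comparison."""

    species: str
    blocks: list[SyntenyBlock]
    inversions: list[tuple[int, int]]
    breakpoints: int
    fates: dict[str, str]                       # gene -> retained_in_locus|salvaged|lost
    disrupted_segments: list[tuple[int, int]]   # maximal ref intervals, longest first

    @property
    def disrupted_segment(self) -> tuple[int, int] | None:
        return self.disrupted_segments[0] if self.disrupted_segments else None

    @property
    def disrupted_segment_size(self) -> int:
        seg = self.disrupted_segment
        return 0 if seg is None else seg[1] - seg[0] + 1

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "blocks": [asdict(b) for b in self.blocks],
            "inversions": [list(iv) for iv in self.inversions],
            "breakpoints": self.breakpoints,
            "fates": self.fates,
            "disrupted_segments": [list(s) for s in self.disrupted_segments],
            "disrupted_segment_size": self.disrupted_segment_size,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass
class LocusExtract:
    """Windowed reference locus around an anchor gene."""

    order: list[SignedGene]
    anchor: str
    truncated_upstream: bool = False
    truncated_downstream: bool = False


def extract_locus(
    genome: GenomeTable, anchor: str, n_up: int, n_down: int
) -> LocusExtract:
    """Return ``n_up`` genes before and ``n_down`` after *anchor* on its scaffold.

    Truncates silently at scaffold ends; truncation is recorded on the result.
    """
    if anchor not in genome:
        raise KeyError(f"anchor gene {anchor!r} not in genome table")
    scaffold = genome.scaffold_of(anchor)
    order = genome.scaffold_order(scaffold)
    idx = [g for g, _ in order].index(anchor)
    lo = max(0, idx - n_up)
    hi = min(len(order), idx + n_down + 1)
    return LocusExtract(
        order=order[lo:hi],
        anchor=anchor,
        truncated_upstream=(idx - n_up < 0),
        truncated_downstream=(idx + n_down + 1 > len(order)),
    )


def map_to_reference(
    reference_order: Sequence[SignedGene], target: GenomeTable
) -> dict[str, Placement | None]:
    """Map each reference gene into the target genome by id.

    The placement index is the gene's rank among *mapped reference genes* on
    its scaffold, in coordinate order: intervening non-reference genes do not
    break adjacency.  Unmapped genes map to ``None``.
    """
    genes = [g for g, _ in reference_order]
    if len(set(genes)) != len(genes):
        raise ValueError("reference gene ids must be unique")
    ref_sign = dict(reference_order)
    present = target.df[target.df["gene"].isin(genes)]
    placements: dict[str, Placement | None] = {g: None for g in genes}
    for scaf, grp in present.groupby("scaffold"):
        g = grp.sort_values("start").reset_index(drop=True)
        for rank, row in g.iterrows():
            gene = row["gene"]
            rel = _STRAND_TO_SIGN[row["strand"]] * ref_sign[gene]
            placements[gene] = Placement(scaffold=str(scaf), index=int(rank), sign=rel)
    return placements


def find_blocks(
    reference_order: Sequence[SignedGene],
    placements: Mapping[str, Placement | None],
) -> list[SyntenyBlock]:
    """Decompose the present reference genes into maximal synteny blocks.

    Consecutive present reference genes extend a block when they sit on the
    same target scaffold at adjacent ranks (index difference d = +1 or -1)
    with consistent relative orientation (d = +1 with relative sign +1 for a
    ``same`` block, d = -1 with relative sign -1 for an ``inverted`` block).
    Singleton blocks take their orientation from the gene's relative sign.
    """
    genes = [g for g, _ in reference_order]
    present = [(i, g) for i, g in enumerate(genes) if placements.get(g) is not None]
    blocks: list[SyntenyBlock] = []
    if not present:
        return blocks

    def close(run: list[tuple[int, str]], direction: int | None) -> None:
        pls = [placements[g] for _, g in run]
        if direction is None:  # singleton
            orientation = "same" if pls[0].sign > 0 else "inverted"
        else:
            orientation = "same" if direction > 0 else "inverted"
        blocks.append(
            SyntenyBlock(
                ref_indices=tuple(i for i, _ in run),
                scaffold=pls[0].scaffold,
                target_indices=tuple(p.index for p in pls),
                orientation=orientation,
            )
        )

    run = [present[0]]
    direction: int | None = None
    for prev, cur in zip(present, present[1:]):
        (pi, pg), (ci, cg) = prev, cur
        pp, cp = placements[pg], placements[cg]
        d = cp.index - pp.index
        # adjacency is judged among present reference genes only: absent
        # reference genes and intervening non-reference genes do not break a run
        joinable = (
            cp.scaffold == pp.scaffold
            and abs(d) == 1
            and pp.sign == cp.sign
            and ((d == 1 and cp.sign == 1) or (d == -1 and cp.sign == -1))
            and (direction is None or d == direction)
        )
        if joinable:
            run.append(cur)
            direction = d
        else:
            close(run, direction)
            run = [cur]
            direction = None
    close(run, direction)
    return blocks


def detect_inversions(blocks: Iterable[SyntenyBlock]) -> list[tuple[int, int]]:
    """Reference intervals of all inverted blocks, sorted by start."""
    return sorted(
        (b.ref_start, b.ref_end) for b in blocks if b.orientation == "inverted"
    )


def count_breakpoints(blocks: Sequence[SyntenyBlock]) -> int:
    """Broken reference adjacencies among present genes.

    Zero iff the present genes form a single block, i.e. the target equals the
    reference up to a global reversal.
    """
    return max(0, len(blocks) - 1)


def classify_fates(
    reference_order: Sequence[SignedGene],
    placements: Mapping[str, Placement | None],
    detected: Mapping[str, bool],
    blocks: Sequence[SyntenyBlock] | None = None,
    *,
    species: str = "",
    max_salvage_block: int = 2,
) -> DisruptionReport:
    """Assign a fate to every reference gene and delimit the disrupted segment.

    ``detected`` maps gene id -> presence call (any evidence tier).  A gene can
    be detected yet unplaced (sequence-level evidence only); such genes are
    salvaged.  A placed gene is retained when its synteny block conserves a
    reference adjacency (size >= 2), unless the block is small
    (<= ``max_salvage_block``) and sits alone on its scaffold -- the "one or
    two genes on a short scaffold" signature of salvage.
    """
    genes = [g for g, _ in reference_order]
    unknown = set(detected) - set(genes)
    if unknown:
        raise ValueError(f"detection calls for genes not in reference: {sorted(unknown)}")
    if blocks is None:
        blocks = find_blocks(reference_order, placements)

    block_of: dict[str, SyntenyBlock] = {}
    for b in blocks:
        for i in b.ref_indices:
            block_of[genes[i]] = b
    scaffold_gene_count: dict[str, int] = {}
    for g in genes:
        p = placements.get(g)
        if p is not None:
            scaffold_gene_count[p.scaffold] = scaffold_gene_count.get(p.scaffold, 0) + 1

    fates: dict[str, str] = {}
    for g in genes:
        if not detected.get(g, False):
            fates[g] = "lost"
            continue
        p = placements.get(g)
        if p is None:
            fates[g] = "salvaged"
            continue
        b = block_of[g]
        isolated_small = (
            b.size <= max_salvage_block
            and scaffold_gene_count[p.scaffold] == b.size
        )
        if b.size >= 2 and not isolated_small:
            fates[g] = "retained_in_locus"
        else:
            fates[g] = "salvaged"

    # maximal contiguous reference intervals with no retained gene
    segments: list[tuple[int, int]] = []
    start = None
    for i, g in enumerate(genes):
        if fates[g] != "retained_in_locus":
            if start is None:
                start = i
        else:
            if start is not None:
                segments.append((start, i - 1))
                start = None
    if start is not None:
        segments.append((start, len(genes) - 1))
    segments.sort(key=lambda s: (-(s[1] - s[0]), s[0]))

    return DisruptionReport(
        species=species,
        blocks=list(blocks),
        inversions=detect_inversions(blocks),
        breakpoints=count_breakpoints(list(blocks)),
        fates=fates,
        disrupted_segments=segments,
    )


def fates_to_tsv(report: DisruptionReport, reference_order: Sequence[SignedGene], path: str | Path) -> None:
    rows = [
        {"gene": g, "fate": report.fates[g]} for g, _ in reference_order
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
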