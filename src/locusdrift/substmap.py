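"""Alignment-level statistics and ancestral substitution mapping.

Operates on an :class:`AlignedSet` (a gapped multiple alignment): gap-column
trimming, pairwise percent identity/similarity, ancestral sequence
reconstruction by Fitch parsimony with a documented deterministic tie-break,
and column-wise classification of ancestor-descendant substitutions as
conservative (positive BLOSUM62 score) or non-conservative (score <= 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AlignedSet",
    "SubstitutionMap",
    "strip_gap_columns",
    "percent_identity",
    "percent_similarity",
    "reconstruct_ancestor",
    "fitch_cost",
    "map_substitutions",
]

GAP = "-"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_score(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


@dataclass
class AlignedSet:
    """Ordered gapped alignment rows with unique ids."""

    ids: list[str]
    rows: list[str]
    alphabet: str = "protein"  # "protein" | "nucleotide"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def column(self, j: int) -> list[str]:
        return [r[j] for r in self.rows]

    @classmethod
    def read_fasta(cls, path: str | Path, alphabet: str = "protein") -> "AlignedSet":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows, alphabet)

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, r in zip(self.ids, self.rows):
                fh.write(f">{i}\n{r}\n")


def strip_gap_columns(aln: AlignedSet, mode: str = "any_gap") -> AlignedSet:
    """Remove gapped columns: every column with >= 1 gap (``any_gap``) or
    with > 50% gaps (``majority_gap``).  Row order is preserved."""
    if mode not in ("any_gap", "majority_gap"):
        raise ValueError(f"unknown mode {mode!r}")
    n = len(aln.rows)
    keep = []
    for j in range(aln.n_columns):
        gaps = sum(1 for r in aln.rows if r[j] == GAP)
        if mode == "any_gap" and gaps == 0:
            keep.append(j)
        elif mode == "majority_gap" and gaps <= n / 2:
            keep.append(j)
    if not keep and aln.n_columns:
        warnings.warn("all columns removed by gap stripping")
    rows = ["".join(r[j] for j in keep) for r in aln.rows]
    return AlignedSet(list(aln.ids), rows, aln.alphabet)


def _compared_columns(a: str, b: str) -> list[int]:
    return [j for j in range(len(a)) if a[j] != GAP and b[j] != GAP]


def percent_identity(a: str, b: str) -> float | None:
    """100 x matches / compared columns; None when nothing is comparable."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    cols = _compared_columns(a, b)
    if not cols:
        return None
    matches = sum(1 for j in cols if a[j] == b[j])
    return 100.0 * matches / len(cols)


def percent_similarity(a: str, b: str, matrix=_BLOSUM62) -> float | None:
    """100 x (matches + positively scoring mismatches) / compared columns."""
    if len(a) != len(b):
        raise ValueError("aligned rows must have equal length")
    cols = _compared_columns(a, b)
    if not cols:
        return None
    similar = sum(
        1 for j in cols if a[j] == b[j] or float(matrix[a[j], b[j]]) > 0
    )
    return 100.0 * similar / len(cols)


def identity_similarity_matrix(aln: AlignedSet) -> pd.DataFrame:
    """Pairwise matrix: similarity above the diagonal, identity below."""
    n = len(aln.ids)
    out = pd.DataFrame(index=aln.ids, columns=aln.ids, dtype=float)
    for i in range(n):
        out.iloc[i, i] = 100.0
        for j in range(i + 1, n):
            out.iloc[j, i] = percent_identity(aln.rows[i], aln.rows[j])
            out.iloc[i, j] = percent_similarity(aln.rows[i], aln.rows[j])
    return out


# ---------------------------------------------------------------------------
# Fitch parsimony


def _parsimony_vector(node, column: dict[str, str], alphabet: list[str]) -> dict[str, float]:
    """Unit-cost (Sankoff) minimum-change vector at *node*.

    Exact for arbitrary arity, which matters because rerooting at an internal
    node creates a polytomy; on binary trees it reduces to Fitch.
    """
    if node.is_leaf():
        obs = column[node.taxon.label]
        return {s: (0.0 if s == obs else math.inf) for s in alphabet}
    child_vectors = [
        _parsimony_vector(c, column, alphabet) for c in node.child_nodes()
    ]
    out = {}
    for s in alphabet:
        total = 0.0
        for cv in child_vectors:
            total += min(cv[t] + (0.0 if t == s else 1.0) for t in alphabet)
        out[s] = total
    return out


def fitch_cost(tree: dendropy.Tree, column: dict[str, str]) -> int:
    """Minimum number of state changes for one column on the tree.

    ``column`` maps tip label -> single-character state.
    """
    alphabet = sorted(set(column.values()))
    vec = _parsimony_vector(tree.seed_node, column, alphabet)
    return int(min(vec.values()))


def _root_candidates(tree: dendropy.Tree, column: dict[str, str]) -> frozenset:
    """States at the root that achieve the minimum parsimony cost."""
    alphabet = sorted(set(column.values()))
    vec = _parsimony_vector(tree.seed_node, column, alphabet)
    best = min(vec.values())
    return frozenset(s for s, v in vec.items() if v == best)


def _resolve(
    candidates: frozenset, tip_states: list[str], use_blosum: bool
) -> str:
    """Deterministic tie-break: majority among tips, then summed BLOSUM62
    similarity to tip states, then alphabetical."""
    def key(state: str):
        majority = sum(1 for t in tip_states if t == state)
        if use_blosum:
            sim = sum(
                blosum62_score(state, t) for t in tip_states if t != GAP and state != GAP
            )
        else:
            sim = 0.0
        return (-majority, -sim, state)

    return sorted(candidates, key=key)[0]


def reconstruct_ancestor(
    aln: AlignedSet, tree: dendropy.Tree | str, node_label: str | None = None
) -> str:
    """Most-parsimonious (Fitch) sequence at an internal node.

    The tree's tips must all be alignment rows.  ``node_label`` selects the
    internal node (``None`` = root).  The candidate state set at the target
    node is obtained by rerooting at that node (Fitch cost is invariant to
    rooting); ambiguity is resolved by the documented tie-break.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", rooting="force-rooted", preserve_underscores=True)
    tree = tree.clone(depth=1)
    tips = {t.taxon.label for t in tree.leaf_node_iter()}
    missing = tips - set(aln.ids)
    if missing:
        raise ValueError(f"tips missing from alignment: {sorted(missing)}")
    if node_label is not None:
        target = None
        for node in tree.preorder_internal_node_iter():
            if node.label == node_label:
                target = node
                break
        if target is None:
            raise KeyError(f"no internal node labelled {node_label!r}")
        if target is not tree.seed_node:
            tree.reroot_at_node(target, update_bipartitions=False)
    states = {t: aln.row(t) for t in tips}
    use_blosum = aln.alphabet == "protein"
    out = []
    tip_list = sorted(tips)
    for j in range(aln.n_columns):
        column = {t: states[t][j] for t in tips}
        root_set = _root_candidates(tree, column)
        tip_states = [states[t][j] for t in tip_list]
        out.append(_resolve(root_set, tip_states, use_blosum))
    return "".join(out)


# ---------------------------------------------------------------------------
# substitution mapping


@dataclass
class SubstitutionMap:
    """Per-column ancestor vs descendant classification."""

    ancestor_id: str
    descendant_id: str
    labels: list[str]            # identical | conservative | nonconservative | indel | skipped
    ancestor: str
    descendant: str
    matrix_name: str = "BLOSUM62"

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": range(1, len(self.labels) + 1),
                "ancestor_state": list(self.ancestor),
                "descendant_state": list(self.descendant),
                "label": self.labels,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def map_substitutions(
    ancestor: str,
    descendant: str,
    matrix=_BLOSUM62,
    ancestor_id: str = "ancestor",
    descendant_id: str = "descendant",
) -> SubstitutionMap:
    """Classify each aligned column of an ancestor-descendant pair.

    identical where states match; conservative where the matrix score is
    strictly positive; nonconservative otherwise; indel where exactly one
    state is a gap.  Columns gapped in both are skipped with a warning.
    """
    if len(ancestor) != len(descendant):
        raise ValueError("aligned pair must have equal length")
    labels = []
    both_gap = 0
    for a, b in zip(ancestor, descendant):
        if a == GAP and b == GAP:
            labels.append("skipped")
            both_gap += 1
        elif a == GAP or b == GAP:
            labels.append("indel")
        elif a == b:
            labels.append("identical")
        elif float(matrix[a, b]) > 0:
            labels.append("conservative")
        else:
            labels.append("nonconservative")
    if both_gap:
        warnings.warn(f"{both_gap} all-gap columns skipped (alignment artifact)")
    return SubstitutionMap(
        ancestor_id=ancestor_id,
        descendant_id=descendant_id,
        labels=labels,
        ancestor=ancestor,
        descendant=descendant,
    )
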