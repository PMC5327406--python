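"""Per-gene substitution-rate estimation and group comparison.

Branch lengths are estimated on a fixed rooted topology by maximising the
Felsenstein-pruning likelihood under JC69 or K80 (uniform base frequencies),
one branch at a time, until convergence.  The evolutionary-rate statistic is
the root-to-tip distance: the total branch length from the ingroup/outgroup
divergence node to a tip, in substitutions/site.

The group comparison reproduces a standard normality-gated procedure: both
samples are tested with the D'Agostino-Pearson omnibus test; if both pass at
alpha = 0.05 (and are large enough for the omnibus test, n >= 8) an
equal-variance two-sample t-test is used, otherwise a Mann-Whitney U test.
Groups with fewer than 3 points are excluded outright.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .substmap import AlignedSet

__all__ = [
    "BranchLengthTree",
    "RateTable",
    "GroupComparison",
    "pruning_loglik",
    "fit_branch_lengths",
    "root_to_tip",
    "dagostino_pearson",
    "compare_groups",
    "jc69_closed_form",
]

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0


def transition_matrix(t: float, model: str = "JC69", kappa: float = 2.0) -> np.ndarray:
    """4x4 substitution probability matrix at branch length *t* (subs/site)."""
    if t < 0:
        raise ValueError("negative branch length")
    if model == "JC69":
        p = 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))
        P = np.full((4, 4), p / 3.0)
        np.fill_diagonal(P, 1.0 - p)
        return P
    if model == "K80":
        e1 = math.exp(-4.0 * t / (kappa + 2.0))
        e2 = math.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
        p_tv = 0.25 - 0.25 * e1
        p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
        same = 1.0 - p_ts - 2.0 * p_tv
        P = np.empty((4, 4))
        # order A, C, G, T; transitions A<->G and C<->T
        for i in range(4):
            for j in range(4):
                if i == j:
                    P[i, j] = same
                elif (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1)):
                    P[i, j] = p_ts
                else:
                    P[i, j] = p_tv
        return P
    raise ValueError(f"unknown model {model!r}")


@dataclass
class BranchLengthTree:
    """Rooted topology with fitted branch lengths and a designated outgroup."""

    tree: dendropy.Tree
    outgroup: str
    converged: bool = True

    def __post_init__(self) -> None:
        tips = {t.taxon.label for t in self.tree.leaf_node_iter()}
        if self.outgroup not in tips:
            raise ValueError(f"outgroup {self.outgroup!r} not a tip")
        for edge in self.tree.preorder_edge_iter():
            if edge.head_node.parent_node is not None and (edge.length or 0.0) < 0:
                raise ValueError("negative branch length")

    @property
    def tips(self) -> list[str]:
        return [t.taxon.label for t in self.tree.leaf_node_iter()]

    def anchor_node(self) -> dendropy.Node:
        """The ingroup/outgroup divergence node (the root-to-tip origin)."""
        root = self.tree.seed_node
        children = root.child_nodes()
        if len(children) == 2:
            for c in children:
                leaves = {t.taxon.label for t in c.leaf_iter()}
                if leaves == {self.outgroup}:
                    other = children[1 - children.index(c)]
                    return other
        return root


def _pattern_compress(aln: AlignedSet, tip_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Unique site patterns (tips x patterns, integer-coded) and their counts."""
    rows = [aln.row(t) for t in tip_order]
    n_col = aln.n_columns
    if n_col == 0:
        raise ValueError("zero-length alignment")
    coded = np.empty((len(rows), n_col), dtype=np.int8)
    for i, r in enumerate(rows):
        for j, c in enumerate(r):
            if c not in _NT_INDEX:
                raise ValueError(f"non-ACGT state {c!r} in row {tip_order[i]} (strip gaps first)")
            coded[i, j] = _NT_INDEX[c]
    patterns, counts = np.unique(coded, axis=1, return_counts=True)
    return patterns, counts.astype(float)


class _PruningEngine:
    """Reusable pruning-likelihood evaluator over compressed site patterns."""

    def __init__(self, tree: dendropy.Tree, aln: AlignedSet, model: str, kappa: float):
        self.tree = tree
        self.model = model
        self.kappa = kappa
        self.tip_order = [t.taxon.label for t in tree.leaf_node_iter()]
        missing = set(self.tip_order) ^ set(aln.ids)
        if missing:
            raise ValueError(f"tree tips and alignment ids differ: {sorted(missing)}")
        self.patterns, self.counts = _pattern_compress(aln, self.tip_order)
        self.n_patterns = self.patterns.shape[1]
        self._tip_row = {t: i for i, t in enumerate(self.tip_order)}

    def loglik(self) -> float:
        """Felsenstein pruning with log-space scaling."""
        logscale = 0.0

        def partial(node) -> np.ndarray:
            nonlocal logscale
            if node.is_leaf():
                row = self.patterns[self._tip_row[node.taxon.label]]
                L = np.zeros((self.n_patterns, 4))
                L[np.arange(self.n_patterns), row] = 1.0
                return L
            L = np.ones((self.n_patterns, 4))
            for child in node.child_nodes():
                Lc = partial(child)
                P = transition_matrix(child.edge.length or 0.0, self.model, self.kappa)
                L *= Lc @ P.T
            m = L.max(axis=1)
            m[m == 0.0] = 1.0
            logscale += float(self.counts @ np.log(m))
            return L / m[:, None]

        L_root = partial(self.tree.seed_node)
        site_lik = 0.25 * L_root.sum(axis=1)
        if (site_lik <= 0).any():
            return -math.inf
        return float(self.counts @ np.log(site_lik)) + logscale


def pruning_loglik(
    tree: dendropy.Tree | str,
    aln: AlignedSet,
    model: str = "JC69",
    kappa: float = 2.0,
) -> float:
    """Log-likelihood of the alignment on the tree under the given model."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick", rooting="force-rooted", preserve_underscores=True)
    return _PruningEngine(tree, aln, model, kappa).loglik()


def fit_branch_lengths(
    topology: dendropy.Tree | str,
    aln: AlignedSet,
    model: str = "JC69",
    kappa: float = 2.0,
    outgroup: str | None = None,
    max_sweeps: int = 100,
    tol: float = 1e-6,
) -> BranchLengthTree:
    """Coordinate-wise ML branch lengths on a fixed topology.

    Each branch in turn is optimised by bounded scalar search on
    [1e-8, 10]; sweeps repeat until the log-likelihood gain falls below
    ``tol``.  The result is flagged not-converged after ``max_sweeps``.
    """
    if isinstance(topology, str):
        tree = dendropy.Tree.get(data=topology, schema="newick", rooting="force-rooted", preserve_underscores=True)
    else:
        tree = topology.clone(depth=1)
    edges = [
        e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None
    ]
    for e in edges:
        if e.length is None or e.length <= 0:
            e.length = 0.05
    engine = _PruningEngine(tree, aln, model, kappa)
    current = engine.loglik()
    converged = False
    for _ in range(max_sweeps):
        sweep_start = current
        for e in edges:
            old_len = e.length

            def neg(t: float, edge=e) -> float:
                edge.length = t
                return -engine.loglik()

            res = optimize.minimize_scalar(
                neg, bounds=(MIN_BRANCH, MAX_BRANCH), method="bounded",
                options={"xatol": 1e-8},
            )
            cand_ll = -float(res.fun)
            if cand_ll >= current:   # monotone ascent by construction
                e.length = float(res.x)
                current = cand_ll
            else:
                e.length = old_len
        if current - sweep_start < tol:
            converged = True
            break
    if not converged:
        warnings.warn("branch-length optimisation did not converge")
    out = outgroup if outgroup is not None else _guess_outgroup(tree)
    return BranchLengthTree(tree=tree, outgroup=out, converged=converged)


def _guess_outgroup(tree: dendropy.Tree) -> str:
    """Default outgroup: a lone tip that is a direct child of the root."""
    for c in tree.seed_node.child_nodes():
        if c.is_leaf():
            return c.taxon.label
    return tree.leaf_node_iter().__next__().taxon.label


def root_to_tip(blt: BranchLengthTree, species: str) -> float:
    """Total branch length from the ingroup/outgroup divergence node to a tip.

    Measured from the ingroup ancestor where the outgroup attaches (the only
    identifiable divergence point under a reversible model); the outgroup
    itself therefore has no root-to-tip value and is excluded upstream.
    """
    tip = blt.tree.find_node_with_taxon_label(species)
    if tip is None:
        raise KeyError(f"unknown tip {species!r}")
    if species == blt.outgroup:
        raise ValueError("root-to-tip is defined for ingroup tips only")
    anchor = blt.anchor_node()
    total = 0.0
    node = tip
    while node is not anchor:
        if node.parent_node is None:
            raise KeyError(f"tip {species!r} is not below the anchor node")
        total += node.edge.length or 0.0
        node = node.parent_node
    return total


def jc69_closed_form(p_hat: float) -> float:
    """Two-taxon ML branch length for an observed mismatch fraction."""
    if p_hat >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p_hat / 3.0)


# ---------------------------------------------------------------------------
# statistics


def dagostino_pearson(x: Sequence[float]) -> tuple[float, float]:
    """D'Agostino-Pearson omnibus normality test (K2, p).

    Combines the skewness and kurtosis z-transforms; p from chi-square with
    2 df.  Requires n >= 8.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"omnibus normality test undefined for n={n} < 8")
    m = x.mean()
    d = x - m
    m2 = (d ** 2).mean()
    m3 = (d ** 3).mean()
    m4 = (d ** 4).mean()
    if m2 == 0:
        raise ValueError("zero variance sample")
    b1 = m3 / m2 ** 1.5
    b2 = m4 / m2 ** 2

    # skewness z (D'Agostino 1970)
    y = b1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n * n + 27 * n - 70) * (n + 1) * (n + 3) / (
        (n - 2.0) * (n + 5) * (n + 7) * (n + 9)
    )
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    y = 0.0 if y == 0 else y
    z_s = delta * math.log(y / alpha + math.sqrt((y / alpha) ** 2 + 1.0))

    # kurtosis z (Anscombe & Glynn 1983)
    e_b2 = 3.0 * (n - 1) / (n + 1)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1) ** 2 * (n + 3) * (n + 5))
    xk = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n * n - 5 * n + 2) / ((n + 7.0) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + math.sqrt(1.0 + 4.0 / sqrt_beta1 ** 2))
    term = (1.0 - 2.0 / a) / (1.0 + xk * math.sqrt(2.0 / (a - 4.0)))
    z_k = ((1.0 - 2.0 / (9.0 * a)) - np.sign(term) * abs(term) ** (1.0 / 3.0)) / math.sqrt(
        2.0 / (9.0 * a)
    )

    k2 = z_s ** 2 + z_k ** 2
    p = float(stats.chi2.sf(k2, df=2))
    return float(k2), p


@dataclass
class GroupComparison:
    n1: int
    n2: int
    mean1: float
    mean2: float
    sem1: float
    sem2: float
    normality_p1: float | None
    normality_p2: float | None
    chosen_test: str  # "t" | "mannwhitney"
    statistic: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "n": [self.n1, self.n2],
            "mean": [self.mean1, self.mean2],
            "sem": [self.sem1, self.sem2],
            "normality_p": [self.normality_p1, self.normality_p2],
            "chosen_test": self.chosen_test,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }


def compare_groups(
    g1: Sequence[float], g2: Sequence[float], alpha_norm: float = 0.05
) -> GroupComparison:
    """Normality-gated two-sample comparison.

    Both groups must have >= 3 points (smaller groups are excluded upstream
    as statistically unusable).  The equal-variance t-test is chosen only
    when both groups pass the omnibus normality test at ``alpha_norm`` (which
    needs n >= 8); otherwise Mann-Whitney U, exact for small tie-free
    samples, normal approximation with tie correction otherwise.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(
            "group with fewer than 3 data points excluded: statistical analysis not possible"
        )
    p1 = p2 = None
    normal = False
    if a.size >= 8 and b.size >= 8:
        try:
            _, p1 = dagostino_pearson(a)
            _, p2 = dagostino_pearson(b)
            normal = (p1 > alpha_norm) and (p2 > alpha_norm)
        except ValueError:
            normal = False
    if normal:
        res = stats.ttest_ind(a, b, equal_var=True)
        chosen, statistic, p = "t", float(res.statistic), float(res.pvalue)
    else:
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            # fully degenerate: identical constant samples carry no evidence
            chosen, statistic, p = "mannwhitney", a.size * b.size / 2.0, 1.0
        else:
            ties = len(np.unique(pooled)) < pooled.size
            method = "exact" if (not ties and max(a.size, b.size) <= 20) else "asymptotic"
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
            chosen, statistic, p = "mannwhitney", float(res.statistic), float(res.pvalue)
    return GroupComparison(
        n1=int(a.size),
        n2=int(b.size),
        mean1=float(a.mean()),
        mean2=float(b.mean()),
        sem1=float(stats.sem(a)),
        sem2=float(stats.sem(b)),
        normality_p1=p1,
        normality_p2=p2,
        chosen_test=chosen,
        statistic=statistic,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# rate table


@dataclass
class RateTable:
    """Per-(gene, species) root-to-tip rates with group labels."""

    df: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["gene_id", "species_id", "root_to_tip", "group"]
        )
    )

    def add(self, gene_id: str, species_id: str, rate: float, group: str) -> None:
        if rate < 0:
            raise ValueError("negative root-to-tip rate")
        key = (self.df["gene_id"] == gene_id) & (self.df["species_id"] == species_id)
        if key.any():
            raise ValueError(f"duplicate entry for ({gene_id}, {species_id})")
        self.df.loc[len(self.df)] = [gene_id, species_id, rate, group]

    def group_values(self, group: str) -> np.ndarray:
        return self.df[self.df["group"] == group]["root_to_tip"].to_numpy(dtype=float)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "RateTable":
        return cls(pd.read_csv(path, sep="\t"))
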