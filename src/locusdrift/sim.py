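"""Locus-evolution simulator with ground-truth event log.

Generates synthetic species genomes that have the statistical structure the
analysis pipeline assumes: a conserved multi-gene locus evolving along a fixed
bird-like phylogeny, rare branch-specific disruption events (an inversion of a
locus interval followed, per gene, by loss or relocation -- "salvage" -- to an
isolated scaffold), post-salvage elevation of the per-gene substitution rate
by a multiplier ``rho``, indel-free nucleotide evolution under JC69 or K80,
and shotgun reads with uniform per-base error.

All randomness flows through a single seeded generator consumed in a
documented order: branch events and per-gene evolution in pre-order over
branches (genes in locus order, paralog last), then reads per tip in tip
order.  Identical config (including seed) therefore yields byte-identical
outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .synteny import GenomeTable, SignedGene

__all__ = [
    "SimGene",
    "SimConfig",
    "SimEvent",
    "SimTruth",
    "SimResult",
    "evolve_sequence",
    "apply_inversion",
    "fragment_reads",
    "simulate",
    "default_config",
]

_NT = np.frombuffer(b"ACGT", dtype="S1")
_NT_INDEX = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
# transition partner of each base (A<->G, C<->T)
_TRANSITION = np.array([2, 3, 0, 1])


class SimConfigError(ValueError):
    """Raised for unsatisfiable simulator configurations."""


@dataclass(frozen=True)
class SimGene:
    gene_id: str
    strand: str = "+"
    length_nt: int = 5001
    base_rate: float = 1.0


@dataclass
class SimConfig:
    """Full description of one simulation scenario.

    ``tree`` is a rooted newick string with branch lengths in expected
    substitutions/site at base rate 1.  ``disruption_branches`` is either an
    explicit set of branch ids (a branch is named after its child node: tip
    label or internal node label) or ``None``, in which case each ingroup
    branch is disrupted independently with probability ``p_disrupt``.
    """

    tree: str
    locus: Sequence[SimGene]
    outgroup: str
    flank_genes: int = 5
    disruption_branches: frozenset[str] | None = None
    p_disrupt: float = 0.0
    inversion_interval: tuple[int, int] | None = None  # indices into locus; None = uniform
    p_loss: float = 0.5
    p_salvage: float = 1.0        # salvage probability for an interval gene that survived
    rho: float = 3.0              # post-salvage rate multiplier
    subst_model: str = "JC69"     # "JC69" | "K80"
    kappa: float = 2.0
    paralog_of: str | None = None  # default: middle locus gene
    paralog_divergence: float = 0.5
    two_gene_salvage: bool = False  # pair salvaged genes two per scaffold
    flank_length_nt: int = 5001
    read_len: int = 100
    coverage: float = 8.0
    err_rate: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_disrupt", "p_loss", "p_salvage", "err_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name}={v} outside [0, 1]")
        if self.rho < 1.0:
            raise SimConfigError(f"rho={self.rho} must be >= 1")
        if not self.locus:
            raise SimConfigError("locus must contain at least one gene")
        for g in self.locus:
            if g.length_nt <= 0 or g.length_nt % 3:
                raise SimConfigError(
                    f"gene {g.gene_id}: length {g.length_nt} must be positive and divisible by 3"
                )
            if g.base_rate < 0:
                raise SimConfigError(f"gene {g.gene_id}: negative base_rate")
            if g.strand not in "+-":
                raise SimConfigError(f"gene {g.gene_id}: bad strand {g.strand!r}")
        ids = [g.gene_id for g in self.locus]
        if len(set(ids)) != len(ids):
            raise SimConfigError("duplicate gene ids in locus")
        if self.subst_model not in ("JC69", "K80"):
            raise SimConfigError(f"unknown substitution model {self.subst_model!r}")
        if self.inversion_interval is not None:
            i, j = self.inversion_interval
            if not (0 <= i <= j < len(self.locus)):
                raise SimConfigError(
                    f"inversion interval {self.inversion_interval} outside locus of {len(self.locus)} genes"
                )
        tree = parse_tree(self.tree)
        tips = {t.label for t in tree.taxon_namespace}
        if len(tips) < 2:
            raise SimConfigError("tree needs at least 2 tips")
        if self.outgroup not in tips:
            raise SimConfigError(f"outgroup {self.outgroup!r} not a tip of the tree")
        if self.paralog_of is not None and self.paralog_of not in ids:
            raise SimConfigError(f"paralog_of {self.paralog_of!r} not in locus")
        if self.read_len <= 0 or self.coverage <= 0:
            raise SimConfigError("read_len and coverage must be positive")

    @property
    def target_gene(self) -> str:
        """The gene whose diverged paralog is always present (the DCC/Neogenin analog)."""
        if self.paralog_of is not None:
            return self.paralog_of
        return self.locus[len(self.locus) // 2].gene_id


@dataclass
class SimEvent:
    branch_id: str
    interval_genes: tuple[str, ...]   # locus genes covered by the inversion, pre-event order
    inverted_interval: tuple[int, int]  # indices into the lineage's pre-event locus order
    lost: frozenset[str]
    salvaged: frozenset[str]


@dataclass
class SimTruth:
    """Ground truth for recovery testing; round-trips losslessly through JSON."""

    events: list[SimEvent]
    rates: dict[str, dict[str, float]]  # gene -> branch -> effective rate multiplier-adjusted rate
    seed: int

    def lost_in(self, species: str, tree: "dendropy.Tree") -> set[str]:
        """Genes absent from *species* due to an ancestral loss event."""
        anc = _ancestor_branches(tree, species)
        return {g for e in self.events if e.branch_id in anc for g in e.lost}

    def salvaged_in(self, species: str, tree: "dendropy.Tree") -> set[str]:
        anc = _ancestor_branches(tree, species)
        return {g for e in self.events if e.branch_id in anc for g in e.salvaged}

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "events": [
                {
                    "branch_id": e.branch_id,
                    "interval_genes": list(e.interval_genes),
                    "inverted_interval": list(e.inverted_interval),
                    "lost": sorted(e.lost),
                    "salvaged": sorted(e.salvaged),
                }
                for e in self.events
            ],
            "rates": self.rates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(
            events=[
                SimEvent(
                    branch_id=e["branch_id"],
                    interval_genes=tuple(e["interval_genes"]),
                    inverted_interval=tuple(e["inverted_interval"]),
                    lost=frozenset(e["lost"]),
                    salvaged=frozenset(e["salvaged"]),
                )
                for e in d["events"]
            ],
            rates={g: dict(v) for g, v in d["rates"].items()},
            seed=d["seed"],
        )

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def read_json(cls, path: str | Path) -> "SimTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def parse_tree(newick: str) -> dendropy.Tree:
    """Parse a rooted newick tree and give unlabeled internal nodes stable ids."""
    tree = dendropy.Tree.get(
        data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True
    )
    k = 0
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        if node.label is None:
            node.label = f"N{k}"
        k += 1
    return tree


def _branch_id(node: dendropy.Node) -> str:
    return node.taxon.label if node.is_leaf() else node.label


def _ancestor_branches(tree: dendropy.Tree, species: str) -> set[str]:
    """Branch ids on the path from the root to *species*, inclusive of the tip branch."""
    tip = tree.find_node_with_taxon_label(species)
    if tip is None:
        raise KeyError(species)
    out = set()
    node = tip
    while node is not None and node.parent_node is not None:
        out.add(_branch_id(node))
        node = node.parent_node
    return out


# ---------------------------------------------------------------------------
# sequence evolution


def _seq_to_array(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype="S1")
    codes = np.full(len(arr), -1, dtype=np.int64)
    for b, i in _NT_INDEX.items():
        codes[arr == b] = i
    if (codes < 0).any():
        pos = int(np.argmax(codes < 0))
        raise ValueError(f"non-ACGT symbol {seq[pos]!r} at position {pos}")
    return codes


def _array_to_seq(codes: np.ndarray) -> str:
    return _NT[codes].tobytes().decode()


def substitution_probability(t_eff: float, model: str = "JC69", kappa: float = 2.0) -> float:
    """Expected fraction of sites differing after time *t_eff* (any change)."""
    if model == "JC69":
        return 0.75 * (1.0 - math.exp(-4.0 * t_eff / 3.0))
    p_ts, p_tv = _k80_probs(t_eff, kappa)
    return p_ts + 2.0 * p_tv


def _k80_probs(t: float, kappa: float) -> tuple[float, float]:
    """K80 per-site probabilities (transition, each transversion) at branch length t."""
    # rates scaled so t is the expected number of substitutions per site
    e1 = math.exp(-4.0 * t / (kappa + 2.0))
    e2 = math.exp(-2.0 * t * (kappa + 1.0) / (kappa + 2.0))
    p_tv = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    return p_ts, p_tv


def evolve_sequence(
    seq: str,
    t_eff: float,
    model: str = "JC69",
    rng: np.random.Generator | None = None,
    kappa: float = 2.0,
) -> str:
    """Evolve *seq* for *t_eff* expected substitutions/site (no indels).

    Each site substitutes independently with the model's closed-form change
    probability; under JC69 every non-identical target base is equally likely,
    under K80 transitions are favoured according to ``kappa``.
    """
    if t_eff < 0:
        raise ValueError(f"negative branch length {t_eff}")
    if rng is None:
        rng = np.random.default_rng()
    codes = _seq_to_array(seq)
    n = len(codes)
    if n == 0 or t_eff == 0.0:
        return seq
    if model == "JC69":
        p = substitution_probability(t_eff, "JC69")
        hit = rng.random(n) < p
        k = int(hit.sum())
        if k:
            # uniformly one of the three other bases
            shift = rng.integers(1, 4, size=k)
            codes[hit] = (codes[hit] + shift) % 4
    elif model == "K80":
        p_ts, p_tv = _k80_probs(t_eff, kappa)
        u = rng.random(n)
        ts = u < p_ts
        tv1 = (u >= p_ts) & (u < p_ts + p_tv)
        tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv)
        new = codes.copy()
        new[ts] = _TRANSITION[codes[ts]]
        # transversion partners: for A/G -> {C,T}; for C/T -> {A,G}
        purine = codes % 2 == 0  # A=0, G=2
        new[tv1] = np.where(purine[tv1], 1, 0)
        new[tv2] = np.where(purine[tv2], 3, 2)
        codes = new
    else:
        raise ValueError(f"unknown substitution model {model!r}")
    return _array_to_seq(codes)


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return _array_to_seq(rng.integers(0, 4, size=length))


# ---------------------------------------------------------------------------
# gene-order operations


def apply_inversion(order: Sequence[SignedGene], i: int, j: int) -> list[SignedGene]:
    """Reverse interval [i..j] of a signed gene order, flipping every strand."""
    n = len(order)
    if not (0 <= i <= j < n):
        raise IndexError(f"inversion interval ({i}, {j}) out of range for {n} genes")
    mid = [(g, -s) for g, s in reversed(order[i : j + 1])]
    return list(order[:i]) + mid + list(order[j + 1 :])


# ---------------------------------------------------------------------------
# reads


def fragment_reads(
    seq: str,
    coverage: float,
    read_len: int,
    err_rate: float,
    rng: np.random.Generator,
) -> list[str]:
    """Shotgun reads at uniform random starts with uniform per-base error."""
    n = len(seq)
    if read_len > n:
        raise ValueError(f"read_len {read_len} exceeds sequence length {n}")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    n_reads = math.ceil(coverage * n / read_len)
    codes = _seq_to_array(seq)
    starts = rng.integers(0, n - read_len + 1, size=n_reads)
    reads = []
    for s in starts:
        r = codes[s : s + read_len].copy()
        if err_rate > 0:
            hit = rng.random(read_len) < err_rate
            k = int(hit.sum())
            if k:
                r[hit] = (r[hit] + rng.integers(1, 4, size=k)) % 4
        reads.append(_array_to_seq(r))
    return reads


# ---------------------------------------------------------------------------
# whole-scenario simulation


@dataclass
class SimResult:
    config: SimConfig
    tree: dendropy.Tree
    reference_order: list[SignedGene]          # flanks + locus, root arrangement
    tables: dict[str, GenomeTable]             # species -> annotations
    seqs: dict[str, dict[str, str]]            # species -> gene -> nucleotide sequence
    reads: dict[str, list[str]]                # species -> read sequences
    truth: SimTruth
    root_seqs: dict[str, str]

    @property
    def species(self) -> list[str]:
        return [t.label for t in self.tree.taxon_namespace]

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for sp in self.species:
            self.tables[sp].write_tsv(out / f"{sp}.genes.tsv")
            with open(out / f"{sp}.fasta", "w") as fh:
                for gene, seq in self.seqs[sp].items():
                    scaf = self.tables[sp].scaffold_of(gene)
                    fh.write(f">{sp}|{gene}|{scaf}\n{seq}\n")
            with open(out / f"{sp}.fastq", "w") as fh:
                for i, r in enumerate(self.reads[sp]):
                    fh.write(f"@{sp}_read_{i}\n{r}\n+\n{'I' * len(r)}\n")
        (out / "tree.nwk").write_text(
            self.tree.as_string(schema="newick", suppress_rooting=True)
        )
        self.truth.write_json(out / "truth.json")


@dataclass
class _LineageState:
    locus_order: list[SignedGene]           # genes still in the ancestral locus
    salvaged: set[str] = field(default_factory=set)
    lost: set[str] = field(default_factory=set)
    seqs: dict[str, str] = field(default_factory=dict)


def simulate(config: SimConfig) -> SimResult:
    """Run the full scenario described by *config*.

    Root sequences are uniform over ACGT; sequences evolve down the tree with
    per-branch effective rates recorded in the truth log; disruption events
    invert an interval of the lineage's current locus order and then, per
    interval gene, remove it (loss) or move it to an isolated scaffold
    (salvage, rate multiplied by ``rho`` on all descendant branches); a
    diverged paralog of the target gene is present in every species.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = parse_tree(config.tree)

    up = [SimGene(f"FLK_U{i+1}", "+", config.flank_length_nt) for i in range(config.flank_genes)]
    down = [SimGene(f"FLK_D{i+1}", "+", config.flank_length_nt) for i in range(config.flank_genes)]
    locus = list(config.locus)
    all_genes: list[SimGene] = up + locus + down
    locus_ids = [g.gene_id for g in locus]
    paralog_parent = config.target_gene
    paralog_id = f"{paralog_parent}_paralog"
    base_rate = {g.gene_id: g.base_rate for g in all_genes}
    base_rate[paralog_id] = base_rate[paralog_parent]
    gene_order_for_rng = [g.gene_id for g in all_genes] + [paralog_id]

    # root sequences (locus order, then flanks' positions are already interleaved)
    root_seqs = {g.gene_id: random_sequence(g.length_nt, rng) for g in all_genes}
    root_seqs[paralog_id] = evolve_sequence(
        root_seqs[paralog_parent], config.paralog_divergence, config.subst_model, rng, config.kappa
    )

    reference_order: list[SignedGene] = [
        (g.gene_id, 1 if g.strand == "+" else -1) for g in all_genes
    ]
    locus_offset = len(up)

    ingroup_branches = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bid = _branch_id(node)
        if bid != config.outgroup:
            ingroup_branches.add(bid)

    events: list[SimEvent] = []
    rates: dict[str, dict[str, float]] = {g: {} for g in gene_order_for_rng}
    states: dict[int, _LineageState] = {}
    root_state = _LineageState(
        locus_order=[(g.gene_id, 1 if g.strand == "+" else -1) for g in locus],
        seqs=dict(root_seqs),
    )
    states[id(tree.seed_node)] = root_state

    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = states[id(node.parent_node)]
        bid = _branch_id(node)
        t = node.edge.length or 0.0
        state = _LineageState(
            locus_order=list(parent.locus_order),
            salvaged=set(parent.salvaged),
            lost=set(parent.lost),
        )

        # decide whether this branch carries a disruption event (rng draw is
        # made for every ingroup branch so explicit/forced configs consume the
        # stream identically)
        disrupted = False
        if bid in ingroup_branches:
            u = rng.random()
            if config.disruption_branches is not None:
                disrupted = bid in config.disruption_branches
            else:
                disrupted = u < config.p_disrupt

        # evolve sequences along the branch (pre-order; genes in locus order)
        for gid in gene_order_for_rng:
            if gid in parent.seqs:
                mult = config.rho if gid in parent.salvaged else 1.0
                t_eff = t * base_rate[gid] * mult
                state.seqs[gid] = evolve_sequence(
                    parent.seqs[gid], t_eff, config.subst_model, rng, config.kappa
                )
                rates[gid][bid] = base_rate[gid] * mult

        if disrupted and state.locus_order:
            n_loc = len(state.locus_order)
            if config.inversion_interval is not None:
                i, j = config.inversion_interval
                if j >= n_loc:
                    raise SimConfigError(
                        f"inversion interval {config.inversion_interval} outside the "
                        f"surviving locus ({n_loc} genes) on branch {bid}"
                    )
            else:
                i = int(rng.integers(0, n_loc))
                j = int(rng.integers(i, n_loc))
            interval_genes = tuple(g for g, _ in state.locus_order[i : j + 1])
            state.locus_order = apply_inversion(state.locus_order, i, j)
            lost, salvaged = set(), set()
            for gid in interval_genes:
                u = rng.random()
                v = rng.random()
                if u < config.p_loss:
                    lost.add(gid)
                elif v < config.p_salvage:
                    salvaged.add(gid)
            state.locus_order = [
                (g, s) for g, s in state.locus_order if g not in lost | salvaged
            ]
            for gid in lost:
                state.seqs.pop(gid, None)
            state.lost |= lost
            state.salvaged |= salvaged
            events.append(
                SimEvent(
                    branch_id=bid,
                    interval_genes=interval_genes,
                    inverted_interval=(i, j),
                    lost=frozenset(lost),
                    salvaged=frozenset(salvaged),
                )
            )

        states[id(node)] = state

    truth = SimTruth(events=events, rates=rates, seed=config.seed)

    # per-tip outputs
    tables: dict[str, GenomeTable] = {}
    seqs: dict[str, dict[str, str]] = {}
    reads: dict[str, list[str]] = {}
    gene_len = {g.gene_id: g.length_nt for g in all_genes}
    gene_len[paralog_id] = gene_len[paralog_parent]
    spacing = 200

    for leaf in tree.leaf_node_iter():
        sp = leaf.taxon.label
        state = states[id(leaf)]
        rows = []
        # main scaffold: flanks in reference arrangement with the surviving
        # locus in the lineage's current order between them
        main = (
            [(g.gene_id, 1 if g.strand == "+" else -1) for g in up]
            + state.locus_order
            + [(g.gene_id, 1 if g.strand == "+" else -1) for g in down]
        )
        pos = 1
        for gid, sign in main:
            rows.append(
                {
                    "gene": gid,
                    "scaffold": "locus_scaffold",
                    "start": pos,
                    "end": pos + gene_len[gid] - 1,
                    "strand": "+" if sign > 0 else "-",
                }
            )
            pos += gene_len[gid] + spacing
        salvaged_sorted = [g for g in locus_ids if g in state.salvaged]
        if config.two_gene_salvage:
            groups = [salvaged_sorted[k : k + 2] for k in range(0, len(salvaged_sorted), 2)]
        else:
            groups = [[g] for g in salvaged_sorted]
        for gi, group in enumerate(groups):
            pos = 1
            scaf = f"salvage_scaffold_{gi+1}"
            for gid in group:
                rows.append(
                    {
                        "gene": gid,
                        "scaffold": scaf,
                        "start": pos,
                        "end": pos + gene_len[gid] - 1,
                        "strand": "+",
                    }
                )
                pos += gene_len[gid] + spacing
        rows.append(
            {
                "gene": paralog_id,
                "scaffold": "paralog_scaffold",
                "start": 1,
                "end": gene_len[paralog_id],
                "strand": "+",
            }
        )
        tables[sp] = GenomeTable(pd.DataFrame(rows), species=sp)
        seqs[sp] = {gid: state.seqs[gid] for gid in gene_order_for_rng if gid in state.seqs}

    # reads last, per tip in taxon-namespace order
    for leaf in tree.leaf_node_iter():
        sp = leaf.taxon.label
        sp_reads: list[str] = []
        for gid, seq in seqs[sp].items():
            if len(seq) >= config.read_len:
                sp_reads.extend(
                    fragment_reads(seq, config.coverage, config.read_len, config.err_rate, rng)
                )
        reads[sp] = sp_reads

    return SimResult(
        config=config,
        tree=tree,
        reference_order=reference_order,
        tables=tables,
        seqs=seqs,
        reads=reads,
        truth=truth,
        root_seqs=root_seqs,
    )


_DEFAULT_TREE = (
    "(outgroup:0.30,(ratite:0.16,(((galliform_A:0.05,galliform_B:0.05)"
    "galliforms:0.06,anseriform:0.10)galloanserae:0.03,(passeriform:0.13,"
    "falconiform:0.11)neoaves:0.04)neognathae:0.03)birds:0.08);"
)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """The reference scenario: a 20-gene locus on a 6-species bird-like tree
    (plus a crocodilian-like outgroup), one forced disruption on the internal
    branch subtending the two galliform-like tips, inversion of a 10-gene
    interval, loss probability 0.5 (survivors salvaged), salvage rate
    multiplier 3, 5 kb indel-free genes under JC69, 100-nt reads at 8x
    coverage with 0.5% uniform error.
    """
    locus = tuple(SimGene(f"G{i+1:02d}") for i in range(20))
    cfg = dict(
        tree=_DEFAULT_TREE,
        locus=locus,
        outgroup="outgroup",
        flank_genes=5,
        disruption_branches=frozenset({"galliforms"}),
        inversion_interval=(5, 14),
        p_loss=0.5,
        p_salvage=1.0,
        rho=3.0,
        subst_model="JC69",
        paralog_of="G10",
        paralog_divergence=0.5,
        read_len=100,
        coverage=8.0,
        err_rate=0.005,
        seed=seed,
    )
    cfg.update(overrides)
    return SimConfig(**cfg)
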