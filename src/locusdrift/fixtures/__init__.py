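"""Bundled worked-example fixtures.

Small, versioned TSV tables transcribing the published comparative maps of
the DCC-containing locus in birds: the reference locus order (human/duck-like
arrangement), chicken and turkey gene orders, a gene x species detection
matrix, and the species survey of target-gene detectability.  Each file is
checksummed in ``manifest.json``; see ``TRANSCRIPTION_NOTE.md`` for what was
transcribed versus reconstructed.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from ..synteny import GenomeTable, SignedGene

__all__ = [
    "fixture_path",
    "load_reference_order",
    "load_genome_table",
    "load_detection_matrix",
    "load_species_survey",
    "load_fixture",
    "GALLIFORM_SPECIES",
    "SALVAGED_GALLIFORM_GENES",
]

GALLIFORM_SPECIES = ("chicken", "quail", "turkey", "guineafowl")
SALVAGED_GALLIFORM_GENES = ("DYNAP", "MBD2", "ME2", "SMAD4", "SKA1")


class FixtureError(ValueError):
    pass


def _root() -> Path:
    return Path(str(resources.files(__package__)))


def fixture_path(name: str) -> Path:
    p = _root() / name
    if not p.exists():
        raise FixtureError(f"no bundled fixture {name!r}")
    _verify(p)
    return p


def _verify(path: Path) -> None:
    manifest = json.loads((_root() / "manifest.json").read_text())
    expect = manifest.get(path.name)
    if expect is None:
        raise FixtureError(f"{path.name} missing from fixture manifest")
    got = hashlib.sha256(path.read_bytes()).hexdigest()
    if got != expect:
        raise FixtureError(f"checksum mismatch for {path.name}: fixtures are versioned")


def load_reference_order() -> list[SignedGene]:
    """The 31-gene reference locus order (9 upstream flank genes, the 17-gene
    segment CCD68..MYO5B, 5 downstream flank genes)."""
    gt = GenomeTable.read_tsv(fixture_path("reference_locus.tsv"), species="reference")
    return gt.scaffold_order("ref_chr18")


def load_genome_table(species: str) -> GenomeTable:
    return GenomeTable.read_tsv(fixture_path(f"{species}.tsv"), species=species)


def load_detection_matrix() -> pd.DataFrame:
    """Gene x species detection tiers; value ``absent`` means not detected."""
    df = pd.read_csv(fixture_path("detection_matrix.tsv"), sep="\t")
    if df.isna().any().any():
        raise FixtureError("detection matrix has missing fields")
    return df.set_index("gene")

def load_species_survey() -> pd.DataFrame:
    """Per-species target-gene detectability across evidence sources."""
    df = pd.read_csv(fixture_path("table1.tsv"), sep="\t")
    if df.isna().any().any():
        raise FixtureError("species survey has missing fields")
    return df


def load_fixture(name: str = "locus"):
    """Load the bundled worked example.

    Returns ``(reference_order, genome_tables, detection_matrix)`` where
    ``genome_tables`` maps species with transcribed gene orders.
    """
    if name != "locus":
        raise FixtureError(f"unknown fixture {name!r}")
    ref = load_reference_order()
    tables = {sp: load_genome_table(sp) for sp in ("chicken", "turkey")}
    return ref, tables, load_detection_matrix()
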