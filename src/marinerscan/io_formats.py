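"""Readers/writers for the formats the pipeline touches, plus configuration
and logging.

Internal coordinates are 0-based half-open everywhere in the package;
conversion to the 1-based inclusive convention happens only here, at the
GFF3/report boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import yaml

logger = logging.getLogger("marinerscan")

NUCLEOTIDE_ALPHABET = set("ACGTN")
# 20 amino acids plus X (unknown) and * (stop)
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

FEATURE_TYPES = ("element", "TIR_left", "TIR_right", "TSD_left", "TSD_right", "ORF")


def configure_logging(level: int = logging.INFO) -> None:
    """Stage-granularity logging to stderr; machine output goes to files only."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class GenomeRecord:
    """A named nucleotide (or protein) sequence with a species label."""

    id: str
    species: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationRow:
    """One feature destined for GFF3; coordinates are 0-based half-open."""

    genome_id: str
    start: int
    end: int
    strand: str
    feature_type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span ({self.start}, {self.end}) for {self.feature_type}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[GenomeRecord]:
    """Read a FASTA file into GenomeRecords.

    Sequences are uppercased and U mapped to T.  In nucleotide mode any
    character outside ACGTN is rejected; in protein mode the 20 amino acids
    plus X and * are accepted.  A ``species=`` key in the description sets
    the species label, otherwise the label defaults to the record id.
    """
    from Bio import SeqIO

    path = Path(path)
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
        bad = set(seq) - allowed
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains characters outside the "
                f"{alphabet} alphabet: {sorted(bad)}")
        species = rec.id
        for token in rec.description.split():
            if token.startswith("species="):
                species = token[len("species="):]
        records.append(GenomeRecord(id=rec.id, species=species, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[GenomeRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.species and rec.species != rec.id:
                header += f" species={rec.species}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def _gff3_attributes(attrs: dict[str, str]) -> str:
    if not attrs:
        return "."
    return ";".join(f"{k}={v}" for k, v in sorted(attrs.items()))


def write_gff3(annotations: list[AnnotationRow], path: str | Path) -> None:
    """Write annotations as GFF3, converting to 1-based inclusive coordinates.

    Rows are ordered deterministically by (genome id, start, feature type).
    """
    path = Path(path)
    rows = sorted(annotations, key=lambda a: (a.genome_id, a.start, a.feature_type))
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for a in rows:
            fh.write("\t".join([
                a.genome_id, "marinerscan", a.feature_type,
                str(a.start + 1), str(a.end), ".", a.strand, ".",
                _gff3_attributes(a.attributes),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Write a tree (evolution.PhyloTree or dendropy.Tree) as newick.

    Branch lengths are printed with 6 decimal places; leaf labels containing
    newick metacharacters are quoted.  Unlabeled leaves are an error.
    """
    path = Path(path)
    dtree = tree.as_dendropy() if hasattr(tree, "as_dendropy") else tree
    for leaf in dtree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unlabeled leaf")
    text = dtree.as_string(schema="newick", real_value_format_specifier=".6f",
                           suppress_rooting=True)
    Path(path).write_text(text)


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def read_newick_string(text: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def write_matrix_tsv(labels: list[str], values, path: str | Path) -> None:
    """Write a labeled square matrix as TSV (labels in first row and column)."""
    import pandas as pd

    pd.DataFrame(values, index=labels, columns=labels).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Every stage threshold with its default.

    Defaults mirror the published mining protocol: translated search at
    E <= 1e-4, 2 kb flanks, transposase >= 200 aa, consensus from >= 5
    copies, copy number at 80% identity / 40% coverage, HT identity gate
    at a strict 70%.
    """

    evalue_threshold: float = 1e-4
    flank_bp: int = 2000
    min_query_aa: int = 30
    min_orf_aa: int = 200
    min_tir_bp: int = 10
    max_tir_mismatch_fraction: float = 0.15
    tir_mismatch_penalty: int = 2
    tsd_pattern: str = "TA"
    tsd_max_mismatches: int = 0
    consensus_min_copies: int = 5
    # representative fallback when too many copies are truncated (not a
    # published threshold; exposed explicitly as this package's own knob)
    max_truncated_fraction: float = 0.8
    copy_number_min_identity: float = 0.80
    copy_number_min_coverage: float = 0.40
    contamination_copy_floor: int = 3
    ht_identity_threshold: float = 0.70
    bootstrap_replicates: int = 1000
    distance_model: str = "k2p"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
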