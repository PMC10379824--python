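"""Synthetic genomes with planted DD37E-family transposon copies.

The generator emulates the evolutionary structure the analysis assumes:
multi-species genomes containing planted transposon copies with TA target
site duplications, terminal inverted repeats, an intact transposase ORF
carrying a D-D-E catalytic triad at configurable spacing, neutral sequence
decay, truncation, and both vertical and horizontal transmission histories
alongside slowly evolving host genes.  Every planted feature is reported in
a truth channel so that recovery can be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import GenomeRecord, logger, write_fasta
from ._pairwise import revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: default host genes used for the horizontal-transfer distance comparison,
#: with CDS lengths typical of the real genes
HOST_GENES: dict[str, int] = {
    "RPL3": 1160,
    "RPL5": 900,
    "Hsc70-4": 1900,
    "Tub3": 1350,
}

_CODON_TABLE: dict[str, str] = {}
_CODONS_FOR_AA: dict[str, list[str]] = {}
STOP_CODONS = ("TAA", "TAG", "TGA")


def _init_codon_tables() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for codon in STOP_CODONS:
        _CODON_TABLE[codon] = "*"
    for codon, aa in _CODON_TABLE.items():
        _CODONS_FOR_AA.setdefault(aa, []).append(codon)
    for codons in _CODONS_FOR_AA.values():
        codons.sort()


_init_codon_tables()

AMINO_ACIDS = sorted(set(_CODON_TABLE.values()) - {"*"})


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator,
                    kappa: float = 1.0) -> str:
    """Apply i.i.d. per-site substitutions at the given rate.

    ``kappa`` weights transitions (A<->G, C<->T) relative to each
    transversion; kappa=1 is the uniform mix.
    """
    if rate <= 0:
        return seq
    if not 0 <= rate < 1:
        raise ValueError("substitution rate must be in [0, 1)")
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    for i in hits:
        base = arr[i]
        if base not in _BASE_INDEX:  # leave N untouched
            continue
        others = [b for b in BASES if b != base]
        weights = np.array([kappa if transition[base] == b else 1.0 for b in others])
        arr[i] = rng.choice(others, p=weights / weights.sum())
    return "".join(arr)


# ---------------------------------------------------------------------------
# Canonical element
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CanonicalProfile:
    """Family-canonical element geometry.

    Defaults follow the reported family statistics: ~1.3 kb total length, a
    ~340 aa transposase with a DD37E catalytic triad confined to the
    C-terminal ~140 aa catalytic domain, TA target site duplications, and
    short TIRs (family-wide TIR lengths range 19-203 bp; 28 bp is used as
    the per-copy default, within the predominant 19-51 bp band).
    """

    element_length: int = 1300
    transposase_aa: int = 340
    tir_length: int = 28
    tsd: str = "TA"
    triad_spacing: int = 37
    catalytic_domain_aa: int = 140
    # 0-based protein indices of D1, D2; E is implied by the spacing rule
    # n = E - D2 - 1, i.e. E = D2 + spacing + 1.
    d1_position: int = 220
    d2_position: int = 270
    kappa: float = 1.0

    @property
    def e_position(self) -> int:
        return self.d2_position + self.triad_spacing + 1

    @property
    def orf_nt(self) -> int:
        # transposase codons plus the stop codon
        return 3 * (self.transposase_aa + 1)

    def validate(self) -> None:
        if self.orf_nt + 2 * self.tir_length > self.element_length:
            raise ValueError(
                f"infeasible profile: ORF ({self.orf_nt} nt) plus two "
                f"{self.tir_length} bp TIRs exceed element length "
                f"{self.element_length}")
        if not 0 < self.d1_position < self.d2_position < self.e_position < self.transposase_aa:
            raise ValueError("triad positions must be strictly increasing within the ORF")
        domain_start = self.transposase_aa - self.catalytic_domain_aa
        if self.d1_position < domain_start:
            raise ValueError("catalytic triad must lie within the C-terminal catalytic domain")


#: the family-canonical transposase is a package constant per geometry:
#: family members are homologous, so every simulated element encodes (a
#: decayed copy of) the same canonical protein, and alignment transfer from
#: the packaged reference domain profile is meaningful.
_FAMILY_PROTEIN_SEED = 37

_family_protein_cache: dict[tuple[int, int, int, int], str] = {}


def family_canonical_protein(transposase_aa: int, d1: int, d2: int, e: int) -> str:
    key = (transposase_aa, d1, d2, e)
    if key not in _family_protein_cache:
        rng = np.random.default_rng(_FAMILY_PROTEIN_SEED)
        protein = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS),
                                                        size=transposase_aa)]
        protein[0] = "M"
        protein[d1] = "D"
        protein[d2] = "D"
        protein[e] = "E"
        _family_protein_cache[key] = "".join(protein)
    return _family_protein_cache[key]


@dataclass
class ElementTruth:
    """Ground truth for one canonical element (element-local coordinates)."""

    sequence: str
    tir_length: int
    orf_span: tuple[int, int]
    protein: str
    triad: tuple[int, int, int]

    @property
    def left_tir_span(self) -> tuple[int, int]:
        return (0, self.tir_length)

    @property
    def right_tir_span(self) -> tuple[int, int]:
        return (len(self.sequence) - self.tir_length, len(self.sequence))


def make_canonical_element(profile: CanonicalProfile,
                           seed: int | np.random.Generator) -> ElementTruth:
    """Build one canonical element: TIR + 5' spacer + ORF + 3' spacer + TIR.

    The right TIR is the reverse complement of the left TIR.  The flanking
    TA TSDs are added at planting time, not stored in the element.  The
    encoded transposase is the family-canonical protein for the profile's
    geometry (family members are homologous); the seed varies codon usage,
    TIR sequence, and spacers.  Two
    ground-truth guards keep the construction well-defined: an in-frame stop
    codon sits immediately 5' of the ORF start (so the longest ORF is
    exactly the planted one), and the three bases just inside each TIR break
    inverted complementarity (so the planted TIR is maximal).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile.validate()

    spacer_total = profile.element_length - profile.orf_nt - 2 * profile.tir_length
    spacer5_len = spacer_total // 2
    spacer3_len = spacer_total - spacer5_len

    protein = family_canonical_protein(profile.transposase_aa,
                                       profile.d1_position,
                                       profile.d2_position,
                                       profile.e_position)

    codons = []
    for aa in protein:
        options = _CODONS_FOR_AA[aa]
        codons.append(options[rng.integers(0, len(options))])
    codons.append(STOP_CODONS[rng.integers(0, len(STOP_CODONS))])
    orf = "".join(codons)

    tir = random_dna(rng, profile.tir_length)
    spacer5 = list(random_dna(rng, spacer5_len))
    spacer3 = list(random_dna(rng, spacer3_len))

    # ORF guard: in-frame stop immediately before the ATG.
    if spacer5_len >= 3:
        spacer5[-3:] = "TAA"

    # TIR maximality guard: break inverted complementarity for the first
    # three positions inside each TIR (compared pairwise left-vs-right).
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for i in range(min(3, spacer5_len, spacer3_len)):
        left = spacer5[i] if i < spacer5_len else None
        forbidden = comp[spacer3[-(i + 1)]]
        if left == forbidden:
            choices = [b for b in BASES if b != forbidden]
            spacer5[i] = choices[rng.integers(0, len(choices))]

    sequence = tir + "".join(spacer5) + orf + "".join(spacer3) + revcomp(tir)
    assert len(sequence) == profile.element_length

    orf_start = profile.tir_length + spacer5_len
    return ElementTruth(
        sequence=sequence,
        tir_length=profile.tir_length,
        orf_span=(orf_start, orf_start + profile.orf_nt),
        protein=protein,
        triad=(profile.d1_position, profile.d2_position, profile.e_position),
    )


# ---------------------------------------------------------------------------
# Planting copies into a background genome
# ---------------------------------------------------------------------------

@dataclass
class PlantedCopy:
    """Truth row for one planted copy (genome coordinates, 0-based half-open)."""

    genome_id: str
    element_span: tuple[int, int]
    left_tir_span: tuple[int, int] | None
    right_tir_span: tuple[int, int] | None
    left_tsd_span: tuple[int, int]
    right_tsd_span: tuple[int, int]
    decay_rate: float
    realized_divergence: float
    truncated: bool
    truncated_side: str | None
    pristine_sequence: str
    planted_sequence: str
    tir_length: int


@dataclass
class SpeciesPairTruth:
    species_a: str
    species_b: str
    relationship: str  # "vertical" or "horizontal"
    host_divergence: float
    te_divergence: float


@dataclass
class SimulationTruth:
    copies: list[PlantedCopy] = field(default_factory=list)
    pairs: list[SpeciesPairTruth] = field(default_factory=list)
    #: the canonical element the copies derive from (None when an explicit
    #: element sequence was planted)
    canonical: "ElementTruth | None" = None

    def to_tsv(self, path: str | Path) -> None:
        import pandas as pd

        rows = [{
            "genome_id": c.genome_id,
            "start": c.element_span[0], "end": c.element_span[1],
            "tir_length": c.tir_length,
            "decay_rate": c.decay_rate,
            "realized_divergence": round(c.realized_divergence, 6),
            "truncated": c.truncated,
            "truncated_side": c.truncated_side or ".",
        } for c in self.copies]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def plant_copies(background_length: int,
                 profile: CanonicalProfile,
                 n_copies: int,
                 decay_rate: float = 0.0,
                 truncation_fraction: float = 0.0,
                 tir_lengths: list[int] | None = None,
                 seed: int | np.random.Generator = 0,
                 genome_id: str = "synthetic",
                 species: str = "synthetic",
                 element: str | None = None,
                 kappa: float | None = None,
                 min_separation: int = 0) -> tuple[GenomeRecord, SimulationTruth]:
    """Plant ``n_copies`` element copies into an i.i.d. uniform background.

    Each copy is inserted with a literal TA duplicated on both sides,
    independently decayed by per-site substitution at ``decay_rate``
    (the TSDs themselves stay literal; decay models post-insertion drift of
    the copy), and a ``truncation_fraction`` of copies is 5'- or 3'-truncated
    at a uniform cut retaining at least 30% of the length.  If ``element``
    is given every copy derives from that sequence; otherwise copies derive
    from a canonical element built from ``profile`` (per-copy TIR lengths
    may be overridden with ``tir_lengths``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_copies < 0:
        raise ValueError("n_copies must be >= 0")
    if not 0 <= decay_rate < 0.5:
        raise ValueError("decay rate must be in [0, 0.5)")
    kappa = profile.kappa if kappa is None else kappa

    if tir_lengths is not None and len(tir_lengths) != n_copies:
        raise ValueError("tir_lengths must have one entry per copy")

    # Build the pristine copy for each slot.
    pristine: list[ElementTruth] = []
    if element is not None:
        for _ in range(n_copies):
            pristine.append(ElementTruth(sequence=element, tir_length=profile.tir_length,
                                         orf_span=(0, 0), protein="", triad=(0, 0, 0)))
    else:
        base = make_canonical_element(profile, rng)
        for k in range(n_copies):
            if tir_lengths is None or tir_lengths[k] == profile.tir_length:
                pristine.append(base)
            else:
                variant = dataclasses.replace(profile, tir_length=tir_lengths[k])
                pristine.append(make_canonical_element(variant, rng))

    total_insert = sum(len(p.sequence) + 4 for p in pristine)
    if n_copies and background_length < total_insert + n_copies:
        raise ValueError(
            f"background of {background_length} bp too short for {n_copies} "
            f"non-overlapping copies ({total_insert} bp of inserts)")

    background = random_dna(rng, background_length)

    def _guard_insertion_site(bg: list[str], site: int, lo: int, hi: int) -> None:
        """Make the planted boundary identifiable: break mirrored TA pairs in
        the flanks.  A TA at offset -d left of the insertion point mirrored by
        a TA at offset +d right of it would let inverted-repeat extension ride
        the planted TIRs from shifted anchors, making a wider, equally valid
        boundary; real data resolves such ambiguity by copy alignment, the
        generator resolves it by construction."""
        for d in range(1, 61):
            if site - d < lo or site + d > hi:
                break
            if "".join(bg[site - d:site - d + 2]) == "TA" and \
                    "".join(bg[site + d - 2:site + d]) == "TA":
                bg[site + d - 2] = "CG"[rng.integers(0, 2)]

    # choose truncated copies
    n_trunc = int(round(truncation_fraction * n_copies))
    trunc_idx = set(rng.choice(n_copies, size=n_trunc, replace=False)) if n_trunc else set()

    # choose ordered non-overlapping insertion points in the background;
    # min_separation (bp of background between insertion points) keeps
    # neighbouring copies out of each other's extraction flanks, emulating
    # the sparse spacing of real genomic copies at desk scale
    sites: list[int] = []
    if n_copies:
        for _ in range(1000):
            draw = sorted(int(s) for s in rng.choice(background_length + 1,
                                                     size=n_copies, replace=False))
            if all(b - a >= min_separation for a, b in zip(draw, draw[1:])):
                sites = draw
                break
        else:
            raise ValueError(
                f"background of {background_length} bp too short for "
                f"{n_copies} copies at min separation {min_separation}")

    bg_list = list(background)
    for idx, site in enumerate(sites):
        lo = sites[idx - 1] if idx > 0 else 0
        hi = sites[idx + 1] if idx + 1 < len(sites) else background_length
        _guard_insertion_site(bg_list, site, lo, hi)
    background = "".join(bg_list)

    pieces: list[str] = []
    truth = SimulationTruth(canonical=pristine[0] if (n_copies and element is None) else None)
    cursor = 0
    offset = 0  # accumulated inserted length
    for k, site in enumerate(sites):
        pieces.append(background[cursor:site])
        cursor = site
        el = pristine[k]
        seq = mutate_sequence(el.sequence, decay_rate, rng, kappa=kappa)
        realized = sum(1 for a, b in zip(seq, el.sequence) if a != b) / len(seq)

        truncated = k in trunc_idx
        side = None
        left_tir: tuple[int, int] | None = el.left_tir_span
        right_tir: tuple[int, int] | None = el.right_tir_span
        if truncated:
            keep = int(rng.integers(int(np.ceil(0.3 * len(seq))), len(seq)))
            side = "5'" if rng.random() < 0.5 else "3'"
            if side == "5'":
                seq = seq[len(seq) - keep:]
                left_tir = None
                shift = len(el.sequence) - keep
                right_tir = (el.right_tir_span[0] - shift, el.right_tir_span[1] - shift)
            else:
                seq = seq[:keep]
                right_tir = None

        start = site + offset + 2  # after the left TA
        end = start + len(seq)
        pieces.append(profile.tsd + seq + profile.tsd)
        offset += len(seq) + 4

        def _shift(span):
            return (span[0] + start, span[1] + start) if span is not None else None

        truth.copies.append(PlantedCopy(
            genome_id=genome_id,
            element_span=(start, end),
            left_tir_span=_shift(left_tir),
            right_tir_span=_shift(right_tir),
            left_tsd_span=(start - 2, start),
            right_tsd_span=(end, end + 2),
            decay_rate=decay_rate,
            realized_divergence=realized,
            truncated=truncated,
            truncated_side=side,
            pristine_sequence=el.sequence,
            planted_sequence=seq,
            tir_length=el.tir_length,
        ))
    pieces.append(background[cursor:])

    record = GenomeRecord(id=genome_id, species=species, sequence="".join(pieces))
    logger.info("planted %d copies into %s (%d bp)", n_copies, genome_id, len(record))
    return record, truth


# ---------------------------------------------------------------------------
# Multi-species simulation
# ---------------------------------------------------------------------------

@dataclass
class SpeciesSet:
    """Output of simulate_species_set."""

    genomes: list[GenomeRecord]
    host_genes: dict[str, dict[str, str]]  # gene -> species -> CDS
    te_master: dict[str, str]              # species -> evolved master element
    te_observed: dict[str, str]            # species -> representative decayed copy
    truth: SimulationTruth
    species_tree_newick: str

    def species(self) -> list[str]:
        return sorted(self.te_master)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genomes, outdir / "genomes.fasta")
        for gene, per_species in self.host_genes.items():
            write_fasta([GenomeRecord(id=f"{gene}_{sp}", species=sp, sequence=s)
                         for sp, s in sorted(per_species.items())],
                        outdir / f"host_{gene}.fasta")
        write_fasta([GenomeRecord(id=f"TE_{sp}", species=sp, sequence=s)
                     for sp, s in sorted(self.te_observed.items())],
                    outdir / "te_observed.fasta")
        (outdir / "species_tree.nwk").write_text(self.species_tree_newick)
        self.truth.to_tsv(outdir / "truth.tsv")


def simulate_species_set(species_tree: str,
                         profile: CanonicalProfile | None = None,
                         host_genes: dict[str, int] | None = None,
                         host_rate: float = 1.0,
                         te_rate_multiplier: float = 1.0,
                         ht_events: list[tuple[str, str]] | None = None,
                         ht_divergence: float = 0.005,
                         copies_per_species: int = 4,
                         copy_decay: float = 0.02,
                         background_length: int = 9000,
                         seed: int | np.random.Generator = 0,
                         emit_genomes: bool = True,
                         kappa: float = 1.0) -> SpeciesSet:
    """Evolve host genes and a transposon along a species tree.

    Host genes evolve along the tree with per-site substitution probability
    ``host_rate * branch_length``; the vertically transmitted transposon
    evolves along the same tree at ``te_rate_multiplier`` times that rate.
    Each horizontal event ``(donor, recipient)`` replaces the recipient's
    transposon with a near-identical copy of the donor's (``ht_divergence``
    substitutions/site).  Planted genomic copies additionally carry
    ``copy_decay`` of post-insertion neutral drift; the first planted copy
    per species is exported as that species' observed element.
    """
    from .io_formats import read_newick_string

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    profile = profile or CanonicalProfile()
    gene_lengths = host_genes or HOST_GENES
    ht_events = ht_events or []

    tree = read_newick_string(species_tree)
    leaf_names = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(leaf_names)) != len(leaf_names):
        raise ValueError("species tree leaf names must be unique")
    for donor, recipient in ht_events:
        for name in (donor, recipient):
            if name not in leaf_names:
                raise ValueError(f"HT event names species {name!r} absent from the tree")

    root_genes = {g: random_dna(rng, n) for g, n in gene_lengths.items()}
    root_te = make_canonical_element(profile, rng).sequence

    genes_at: dict[str, dict[str, str]] = {}
    te_at: dict[str, str] = {}
    path_len: dict[str, float] = {}

    def descend(node, genes, te, depth):
        edge = node.edge.length or 0.0
        if edge > 0:
            p_host = min(host_rate * edge, 0.75)
            p_te = min(te_rate_multiplier * host_rate * edge, 0.75)
            genes = {g: mutate_sequence(s, p_host, rng, kappa) for g, s in genes.items()}
            te = mutate_sequence(te, p_te, rng, kappa)
        depth += edge
        if node.is_leaf():
            name = node.taxon.label
            genes_at[name] = genes
            te_at[name] = te
            path_len[name] = depth
        else:
            for child in node.child_nodes():
                descend(child, genes, te, depth)

    descend(tree.seed_node, root_genes, root_te, 0.0)

    relationship = {}
    for donor, recipient in ht_events:
        te_at[recipient] = mutate_sequence(te_at[donor], ht_divergence, rng, kappa)
        relationship[frozenset((donor, recipient))] = "horizontal"

    truth = SimulationTruth()
    genomes: list[GenomeRecord] = []
    te_observed: dict[str, str] = {}
    for name in sorted(te_at):
        te_observed[name] = mutate_sequence(te_at[name], copy_decay, rng, kappa)
        if emit_genomes:
            record, t = plant_copies(
                background_length, profile, copies_per_species,
                decay_rate=copy_decay, seed=rng, genome_id=f"genome_{name}",
                species=name, element=te_at[name], kappa=kappa)
            genomes.append(record)
            truth.copies.extend(t.copies)

    names = sorted(te_at)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rel = relationship.get(frozenset((a, b)), "vertical")
            d_host = _pairwise_divergence(genes_at[a], genes_at[b])
            d_te = sum(x != y for x, y in zip(te_at[a], te_at[b])) / len(te_at[a])
            truth.pairs.append(SpeciesPairTruth(a, b, rel, d_host, d_te))

    host_out = {g: {sp: genes_at[sp][g] for sp in names} for g in gene_lengths}
    return SpeciesSet(genomes=genomes, host_genes=host_out, te_master=dict(te_at),
                      te_observed=te_observed, truth=truth,
                      species_tree_newick=species_tree)


def _pairwise_divergence(genes_a: dict[str, str], genes_b: dict[str, str]) -> float:
    diffs = total = 0
    for g, sa in genes_a.items():
        sb = genes_b[g]
        diffs += sum(x != y for x, y in zip(sa, sb))
        total += min(len(sa), len(sb))
    return diffs / total if total else 0.0
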