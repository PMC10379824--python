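"""Shared pairwise-alignment primitives.

Thin wrappers around :class:`Bio.Align.PairwiseAligner` that fix the scoring
conventions used throughout the package:

* a gap of length ``k`` costs ``open + k * extend`` (BLAST-style affine);
* protein alignments use BLOSUM62 with stop codons (``*``) acting as hard
  barriers (score -10000, so a local alignment never crosses one) and ``X``
  (codons containing N) scoring -1 against everything;
* nucleotide alignments carry an extra barrier letter ``!`` used to mask
  already-reported hits during iterated Smith-Waterman search.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

STOP = "*"
NT_MASK = "!"

PROTEIN_GAP_OPEN = 11
PROTEIN_GAP_EXTEND = 1

#: nucleotide local-alignment scores (BLAST-n flavoured, used for copy-number
#: estimation and contamination screening)
NT_MATCH = 1
NT_MISMATCH = -2
NT_GAP_OPEN = 5
NT_GAP_EXTEND = 2

#: global nucleotide scores used by the center-star MSA
MSA_MATCH = 2
MSA_MISMATCH = -2
MSA_GAP_OPEN = 6
MSA_GAP_EXTEND = 1

BARRIER = -10000.0


@lru_cache(maxsize=None)
def protein_matrix() -> substitution_matrices.Array:
    """BLOSUM62 with `*` as an alignment barrier and `X` as a mismatch."""
    base = substitution_matrices.load("BLOSUM62")
    arr = substitution_matrices.Array(alphabet=base.alphabet, dims=2)
    for x in base.alphabet:
        for y in base.alphabet:
            arr[x, y] = base[x, y]
    for x in base.alphabet:
        arr["X", x] = -1.0
        arr[x, "X"] = -1.0
        arr[STOP, x] = BARRIER
        arr[x, STOP] = BARRIER
    return arr


@lru_cache(maxsize=None)
def nucleotide_matrix(match: float = NT_MATCH, mismatch: float = NT_MISMATCH) -> substitution_matrices.Array:
    """Simple match/mismatch matrix over ACGTN plus the `!` mask barrier.

    N scores as a mismatch against every base, including N itself
    (conservative handling of assembly gaps).
    """
    alphabet = "ACGTN" + NT_MASK
    arr = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if x == NT_MASK or y == NT_MASK:
                arr[x, y] = BARRIER
            elif x == "N" or y == "N":
                arr[x, y] = mismatch
            else:
                arr[x, y] = match if x == y else mismatch
    return arr


def _make_aligner(matrix, mode: str, gap_open: float, gap_extend: float,
                  free_end_gaps: bool = False) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local" if mode == "local" else "global"
    aligner.substitution_matrix = matrix
    # Biopython's open_gap_score applies to the first gapped position, so the
    # BLAST convention cost(k) = open + k*extend maps to open+extend / extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    if free_end_gaps and mode != "local":
        try:
            aligner.open_end_insertion_score = 0.0
            aligner.extend_end_insertion_score = 0.0
            aligner.open_end_deletion_score = 0.0
            aligner.extend_end_deletion_score = 0.0
        except AttributeError:  # older Biopython naming
            aligner.target_end_open_gap_score = 0.0
            aligner.target_end_extend_gap_score = 0.0
            aligner.query_end_open_gap_score = 0.0
            aligner.query_end_extend_gap_score = 0.0
    return aligner


@dataclass
class PairwiseResult:
    """One pairwise alignment in (target, query) orientation."""

    score: float
    target_span: tuple[int, int]
    query_span: tuple[int, int]
    aligned_target: str
    aligned_query: str

    @property
    def columns(self) -> int:
        return len(self.aligned_target)

    @property
    def matches(self) -> int:
        return sum(1 for a, b in zip(self.aligned_target, self.aligned_query)
                   if a == b and a != "-")

    @property
    def identity(self) -> float:
        """Matches over alignment columns (gap columns included), BLAST-style."""
        return self.matches / self.columns if self.columns else 0.0


def _run(aligner: Align.PairwiseAligner, target: str, query: str,
         local: bool) -> PairwiseResult | None:
    score = aligner.score(target, query)
    if local and score <= 0:
        return None
    best = next(iter(aligner.align(target, query)))
    coords = best.coordinates
    return PairwiseResult(
        score=float(score),
        target_span=(int(coords[0][0]), int(coords[0][-1])),
        query_span=(int(coords[1][0]), int(coords[1][-1])),
        aligned_target=str(best[0]),
        aligned_query=str(best[1]),
    )


def local_protein(target: str, query: str,
                  gap_open: float = PROTEIN_GAP_OPEN,
                  gap_extend: float = PROTEIN_GAP_EXTEND) -> PairwiseResult | None:
    """Best local protein alignment, or None when no positive-scoring one exists."""
    aligner = _make_aligner(protein_matrix(), "local", gap_open, gap_extend)
    return _run(aligner, target, query, local=True)


def local_protein_score(target: str, query: str) -> float:
    aligner = _make_aligner(protein_matrix(), "local",
                            PROTEIN_GAP_OPEN, PROTEIN_GAP_EXTEND)
    return float(aligner.score(target, query))


def global_protein(target: str, query: str,
                   gap_open: float = PROTEIN_GAP_OPEN,
                   gap_extend: float = PROTEIN_GAP_EXTEND,
                   free_end_gaps: bool = False) -> PairwiseResult:
    aligner = _make_aligner(protein_matrix(), "global", gap_open, gap_extend,
                            free_end_gaps=free_end_gaps)
    return _run(aligner, target, query, local=False)


def local_nucleotide(target: str, query: str) -> PairwiseResult | None:
    aligner = _make_aligner(nucleotide_matrix(), "local", NT_GAP_OPEN, NT_GAP_EXTEND)
    return _run(aligner, target, query, local=True)


def global_nucleotide(target: str, query: str,
                      match: float = MSA_MATCH, mismatch: float = MSA_MISMATCH,
                      gap_open: float = MSA_GAP_OPEN,
                      gap_extend: float = MSA_GAP_EXTEND) -> PairwiseResult:
    aligner = _make_aligner(nucleotide_matrix(match, mismatch), "global",
                            gap_open, gap_extend)
    return _run(aligner, target, query, local=False)


def global_nucleotide_score(target: str, query: str) -> float:
    aligner = _make_aligner(nucleotide_matrix(MSA_MATCH, MSA_MISMATCH), "global",
                            MSA_GAP_OPEN, MSA_GAP_EXTEND)
    return float(aligner.score(target, query))


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
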