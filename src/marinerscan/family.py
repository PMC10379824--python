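"""Per-species family models: consensus reconstruction and copy number.

A species' family model is the majority-rule consensus of its element
copies when at least five well-bounded copies exist; otherwise the
best-scoring mined locus stands in as the representative.  Copy number is
the count of nucleotide local-alignment hits of the model against the
genome at >= 80% identity covering >= 40% of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import _pairwise
from ._pairwise import revcomp
from .io_formats import GenomeRecord, logger

CONSENSUS_MIN_COPIES = 5
COPY_NUMBER_MIN_IDENTITY = 0.80
COPY_NUMBER_MIN_COVERAGE = 0.40


@dataclass
class FamilyModel:
    species: str
    sequence: str
    method: str                     # "consensus" or "representative"
    n_copies_used: int
    copy_number: int | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method == "consensus" and self.n_copies_used < CONSENSUS_MIN_COPIES:
            raise ValueError("consensus models require >= 5 copies")
        if self.method == "representative" and self.n_copies_used != 1:
            raise ValueError("representative models use exactly 1 locus")


# ---------------------------------------------------------------------------
# Center-star multiple alignment
# ---------------------------------------------------------------------------

def center_star_msa(copies: list[str]) -> list[str]:
    """Center-star multiple alignment (gapped strings of equal length).

    The center is the sequence maximizing the summed pairwise global
    alignment score (match +2, mismatch -2, gap open -6, extend -1); every
    other sequence is aligned to the center pairwise and gaps are merged by
    the standard center-star projection.  Rows are returned in input order.
    """
    if len(copies) < 2:
        raise ValueError("center_star_msa needs >= 2 sequences")

    n = len(copies)
    totals = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            s = _pairwise.global_nucleotide_score(copies[i], copies[j])
            totals[i] += s
            totals[j] += s
    center = max(range(n), key=lambda i: (totals[i], -i))

    pair_alignments = []
    for j in range(n):
        if j == center:
            continue
        aln = _pairwise.global_nucleotide(copies[center], copies[j])
        pair_alignments.append((j, aln.aligned_target, aln.aligned_query))

    # Merge: maintain the master gap pattern of the center; whenever a new
    # pairwise alignment opens a gap in the center that the master lacks
    # (or vice versa), insert the missing gap column into all rows.
    master_center: list[str] = list(copies[center])
    rows: dict[int, list[str]] = {center: list(copies[center])}

    for j, aln_center, aln_other in pair_alignments:
        merged_other: list[str] = []
        mi = 0  # index into master_center
        pi = 0  # index into aln_center
        while mi < len(master_center) or pi < len(aln_center):
            m_gap = mi < len(master_center) and master_center[mi] == "-"
            p_gap = pi < len(aln_center) and aln_center[pi] == "-"
            m_done = mi >= len(master_center)
            p_done = pi >= len(aln_center)
            if not m_done and not p_done and not m_gap and not p_gap:
                merged_other.append(aln_other[pi])
                mi += 1
                pi += 1
            elif m_gap and p_gap:
                merged_other.append(aln_other[pi])
                mi += 1
                pi += 1
            elif m_gap:  # master has a gap this alignment lacks
                merged_other.append("-")
                mi += 1
            else:        # new gap column from this pairwise alignment
                master_center.insert(mi, "-")
                for row in rows.values():
                    row.insert(mi, "-")
                merged_other.append(aln_other[pi])
                mi += 1
                pi += 1
        rows[j] = merged_other

    width = len(master_center)
    out = []
    for idx in range(n):
        row = rows[idx]
        assert len(row) == width
        out.append("".join(row))
    return out


def build_consensus(alignment: list[str], min_copies: int = CONSENSUS_MIN_COPIES
                    ) -> tuple[str, list[int]]:
    """Strict per-column majority consensus of a multiple alignment.

    Columns where gaps outnumber bases are dropped; base ties are broken
    alphabetically and reported in the returned tie-column list (indices
    into the consensus).  The consensus contains no gaps.
    """
    if len(alignment) < min_copies:
        raise ValueError(
            f"consensus needs >= {min_copies} aligned copies "
            f"(got {len(alignment)}); use pick_representative instead")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("alignment rows must have equal length")
    consensus: list[str] = []
    ties: list[int] = []
    for col in range(width):
        column = [row[col] for row in alignment]
        gaps = column.count("-")
        bases = [c for c in column if c in "ACGT"]
        if gaps > len(column) - gaps or not bases:
            continue
        counts = sorted(((bases.count(b), b) for b in set(bases)),
                        key=lambda t: (-t[0], t[1]))
        if len(counts) > 1 and counts[0][0] == counts[1][0]:
            ties.append(len(consensus))
        consensus.append(counts[0][1])
    return "".join(consensus), ties


@dataclass
class RepresentativeCandidate:
    genome_id: str
    sequence: str
    score: float
    species: str = ""


def pick_representative(candidates: list[RepresentativeCandidate]) -> FamilyModel:
    """Best-scoring locus; ties by longest element, then lexicographic genome id."""
    if not candidates:
        raise ValueError("no candidate loci")
    best = min(candidates,
               key=lambda c: (-c.score, -len(c.sequence), c.genome_id))
    return FamilyModel(species=best.species or best.genome_id,
                       sequence=best.sequence, method="representative",
                       n_copies_used=1)


# ---------------------------------------------------------------------------
# Copy number
# ---------------------------------------------------------------------------

@dataclass
class CopyHit:
    start: int
    end: int
    strand: str
    score: float
    identity: float
    coverage: float

    def qualifies(self, min_identity: float, min_coverage: float) -> bool:
        return self.identity >= min_identity and self.coverage >= min_coverage


def _iterated_nt_hits(model: str, target: str, strand: str, target_len: int,
                      stop_score: float, max_hits: int = 500) -> list[CopyHit]:
    work = target
    hits: list[CopyHit] = []
    while len(hits) < max_hits:
        aln = _pairwise.local_nucleotide(work, model)
        if aln is None or aln.score < stop_score:
            break
        t0, t1 = aln.target_span
        cov = (aln.query_span[1] - aln.query_span[0]) / len(model)
        if strand == "+":
            start, end = t0, t1
        else:
            start, end = target_len - t1, target_len - t0
        hits.append(CopyHit(start=start, end=end, strand=strand, score=aln.score,
                            identity=aln.identity, coverage=cov))
        work = work[:t0] + _pairwise.NT_MASK * (t1 - t0) + work[t1:]
    return hits


def estimate_copy_number(model: str, genome: GenomeRecord,
                         min_identity: float = COPY_NUMBER_MIN_IDENTITY,
                         min_coverage: float = COPY_NUMBER_MIN_COVERAGE
                         ) -> tuple[int, list[CopyHit]]:
    """Count genomic copies of the model at the identity/coverage thresholds.

    Nucleotide local alignment (match +1, mismatch -2, open -5, extend -2)
    on both strands with iterated masking; hits overlapping by > 50% of the
    shorter hit are merged keeping the higher-scoring one.  Coverage is the
    fraction of the *model* aligned (query coverage).
    """
    if len(model) < 100:
        raise ValueError("family model shorter than 100 bp")
    n = len(genome.sequence)
    stop_score = max(20.0, 0.08 * len(model))
    hits = _iterated_nt_hits(model, genome.sequence, "+", n, stop_score)
    hits += _iterated_nt_hits(model, revcomp(genome.sequence), "-", n, stop_score)

    hits.sort(key=lambda h: -h.score)
    merged: list[CopyHit] = []
    for h in hits:
        absorbed = False
        for m in merged:
            lo, hi = max(h.start, m.start), min(h.end, m.end)
            ov = max(0, hi - lo)
            shorter = min(h.end - h.start, m.end - m.start)
            if shorter > 0 and ov > 0.5 * shorter:
                absorbed = True  # keep the higher-scoring (already in merged)
                break
        if not absorbed:
            merged.append(h)
    merged.sort(key=lambda h: h.start)
    count = sum(1 for h in merged if h.qualifies(min_identity, min_coverage))
    logger.info("copy number vs %s: %d qualifying of %d merged hits",
                genome.id, count, len(merged))
    return count, merged


def copy_number_report(models: list[FamilyModel], path: str | Path) -> None:
    import pandas as pd

    rows = [{
        "species": m.species, "method": m.method,
        "copies_used": m.n_copies_used,
        "copy_number": m.copy_number if m.copy_number is not None else ".",
        "min_identity": m.parameters.get("min_identity", COPY_NUMBER_MIN_IDENTITY),
        "min_coverage": m.parameters.get("min_coverage", COPY_NUMBER_MIN_COVERAGE),
    } for m in models]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
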