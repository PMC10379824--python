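"""Translated homology mining of transposase queries against genomes.

A Smith-Waterman search with iterated masking stands in for TBlastN: every
frame of the genome is scanned exhaustively, locally optimal hits are peeled
off best-first by masking, and hits are kept when their Karlin-Altschul
expectation E = K*m*n*exp(-lambda*S) falls at or below the threshold
(gapped BLOSUM62/11/1 constants, lambda=0.267, K=0.041).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from . import _pairwise
from ._pairwise import revcomp
from .io_formats import GenomeRecord, logger
from .synthetic_data import _CODON_TABLE

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041

DEFAULT_EVALUE = 1e-4
DEFAULT_FLANK = 2000
MIN_QUERY_AA = 30

FRAMES = (1, 2, 3, -1, -2, -3)


def translate(dna: str) -> str:
    """Translate a forward frame; codons containing N give X, stops give *."""
    out = []
    for i in range(0, len(dna) - len(dna) % 3, 3):
        codon = dna[i:i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE.get(codon, "X"))
    return "".join(out)


def six_frame_translate(dna: str) -> dict[int, str]:
    """All six conceptual translations keyed by frame (+1..+3, -1..-3).

    Frames +1..+3 read the forward strand with offsets 0..2; -1..-3 read the
    reverse complement with offsets 0..2.  Trailing partial codons are
    dropped.
    """
    rc = revcomp(dna)
    frames = {}
    for off in range(3):
        frames[off + 1] = translate(dna[off:])
        frames[-(off + 1)] = translate(rc[off:])
    return frames


@dataclass
class AlignmentHit:
    """One translated hit, reported on the forward strand of the genome."""

    query_id: str
    genome_id: str
    start: int            # genome coordinates, 0-based half-open, forward strand
    end: int
    strand: str
    frame: int
    score: float
    evalue: float

    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class HitLocus:
    """A hit widened by up to ``flank`` bp per side and oriented for coding."""

    hit: AlignmentHit
    sequence: str         # transposase-coding orientation
    flank: int
    genome_start: int     # forward-strand slice coordinates
    genome_end: int
    clipped_left: bool    # in locus orientation
    clipped_right: bool

    @property
    def left_flank_length(self) -> int:
        if self.hit.strand == "+":
            return self.hit.start - self.genome_start
        return self.genome_end - self.hit.end

    @property
    def right_flank_length(self) -> int:
        if self.hit.strand == "+":
            return self.genome_end - self.hit.end
        return self.hit.start - self.genome_start

    @property
    def core_span(self) -> tuple[int, int]:
        """The hit (ORF core) in locus coordinates; the element contains it."""
        return (self.left_flank_length,
                len(self.sequence) - self.right_flank_length)

    def locus_to_genome(self, span: tuple[int, int]) -> tuple[int, int]:
        """Map a locus-coordinate span back to forward-strand genome coordinates."""
        s, e = span
        if self.hit.strand == "+":
            return (self.genome_start + s, self.genome_start + e)
        return (self.genome_end - e, self.genome_end - s)


def evalue(score: float, query_len: int, genome_len: int) -> float:
    return KARLIN_K * query_len * genome_len * math.exp(-KARLIN_LAMBDA * score)


def _stop_free_segments(target: str):
    start = 0
    for i, c in enumerate(target):
        if c == _pairwise.STOP:
            if i > start:
                yield start, target[start:i]
            start = i + 1
    if len(target) > start:
        yield start, target[start:]


def local_align_protein(query: str, target: str):
    """Optimal local protein alignment under BLOSUM62 with affine gaps.

    The alignment never crosses a ``*`` in the target: stop codons are hard
    barriers (the target is aligned segment-wise between stops, so not even
    a deletion gap can bridge one).  Returns None when no positive-scoring
    alignment exists.
    """
    best_score = 0.0
    best_segment = None
    for offset, segment in _stop_free_segments(target):
        score = _pairwise.local_protein_score(segment, query)
        if score > best_score:
            best_score, best_segment = score, (offset, segment)
    if best_segment is None:
        return None
    offset, segment = best_segment
    aln = _pairwise.local_protein(segment, query)
    aln.target_span = (aln.target_span[0] + offset,
                       aln.target_span[1] + offset)
    return aln


def search_genome(query: GenomeRecord | str, genome: GenomeRecord,
                  evalue_threshold: float = DEFAULT_EVALUE,
                  query_id: str | None = None) -> list[AlignmentHit]:
    """Scan all six frames for local hits of a protein query.

    Per frame, non-overlapping locally optimal hits are recovered by
    iterated masking of the best hit; hits with E <= threshold are reported
    in forward-strand genome coordinates.
    """
    if isinstance(query, GenomeRecord):
        qid, qseq = query.id, query.sequence
    else:
        qid, qseq = (query_id or "query"), query
    if len(qseq) < MIN_QUERY_AA:
        raise ValueError(f"query {qid!r} shorter than {MIN_QUERY_AA} aa")

    n = len(genome.sequence)
    hits: list[AlignmentHit] = []
    for frame, prot in six_frame_translate(genome.sequence).items():
        if not prot:
            continue
        work = prot
        while True:
            aln = local_align_protein(qseq, work)
            if aln is None:
                break
            e = evalue(aln.score, len(qseq), n)
            if e > evalue_threshold:
                break
            p0, p1 = aln.target_span
            offset = abs(frame) - 1
            if frame > 0:
                g0, g1 = offset + 3 * p0, offset + 3 * p1
                strand = "+"
            else:
                g0, g1 = n - (offset + 3 * p1), n - (offset + 3 * p0)
                strand = "-"
            hits.append(AlignmentHit(
                query_id=qid, genome_id=genome.id, start=g0, end=g1,
                strand=strand, frame=frame, score=aln.score, evalue=e))
            work = work[:p0] + _pairwise.STOP * (p1 - p0) + work[p1:]
    hits.sort(key=lambda h: (h.start, h.end, -h.score))
    logger.info("search %s vs %s: %d hits at E<=%g", qid, genome.id, len(hits),
                evalue_threshold)
    return hits


def extract_locus(hit: AlignmentHit, genome: GenomeRecord,
                  flank: int = DEFAULT_FLANK) -> HitLocus:
    """Slice the hit with up to ``flank`` bp per side, clipped at genome ends.

    Minus-strand hits are reverse complemented so the element is always in
    transposase-coding orientation.
    """
    n = len(genome.sequence)
    s = max(0, hit.start - flank)
    e = min(n, hit.end + flank)
    seq = genome.sequence[s:e]
    clipped_start = s == 0 and hit.start - flank < 0
    clipped_end = e == n and hit.end + flank > n
    if hit.strand == "-":
        seq = revcomp(seq)
        clipped_left, clipped_right = clipped_end, clipped_start
    else:
        clipped_left, clipped_right = clipped_start, clipped_end
    return HitLocus(hit=hit, sequence=seq, flank=flank, genome_start=s,
                    genome_end=e, clipped_left=clipped_left,
                    clipped_right=clipped_right)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """True when spans overlap by >= 50% of each span's length."""
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    ov = max(0, hi - lo)
    return ov >= 0.5 * (a[1] - a[0]) and ov >= 0.5 * (b[1] - b[0])


def iterate_search(initial_queries: list[GenomeRecord],
                   genomes: list[GenomeRecord],
                   max_rounds: int = 3,
                   evalue_threshold: float = DEFAULT_EVALUE,
                   flank: int = DEFAULT_FLANK,
                   min_orf_aa: int = 200) -> list[HitLocus]:
    """Iterative query expansion: new hits' ORFs join the query pool.

    Each round searches only the queries added in the previous round; loci
    are deduplicated by >= 50% reciprocal hit-span overlap.  Stops when a
    round adds no new locus or ``max_rounds`` is reached.
    """
    from .transposase import find_orf

    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    loci: list[HitLocus] = []
    seen_queries = {q.sequence for q in initial_queries}
    new_queries = list(initial_queries)
    for round_no in range(1, max_rounds + 1):
        added: list[HitLocus] = []
        for q in new_queries:
            for genome in genomes:
                for hit in search_genome(q, genome, evalue_threshold):
                    if any(l.hit.genome_id == hit.genome_id
                           and l.hit.strand == hit.strand
                           and _reciprocal_overlap(l.hit.span(), hit.span())
                           for l in loci + added):
                        continue
                    added.append(extract_locus(hit, genome, flank))
        logger.info("iterate_search round %d: %d new loci", round_no, len(added))
        if not added:
            break
        loci.extend(added)
        new_queries = []
        for locus in added:
            orf = find_orf(locus.sequence, min_length_aa=min_orf_aa)
            if orf is not None and orf.protein not in seen_queries:
                seen_queries.add(orf.protein)
                new_queries.append(GenomeRecord(
                    id=f"iter{round_no}_{locus.hit.genome_id}_{locus.hit.start}",
                    species=locus.hit.genome_id, sequence=orf.protein))
        if not new_queries:
            break
    return loci


def screen_contamination(locus: HitLocus, copy_count: int,
                         genome: GenomeRecord,
                         related_genomes: list[GenomeRecord] | None = None,
                         copy_floor: int = 3,
                         min_identity: float = 0.80,
                         min_coverage: float = 0.50) -> str:
    """Validate low-copy loci by mapping their flanks back to host genomes.

    Applied only when ``copy_count`` is below ``copy_floor``; a locus is
    validated when at least one flank maps with >= 80% identity over >= 50%
    of its length to its own genome (excluding the locus itself) or to a
    related genome.  Returns "validated", "contamination", or
    "indeterminate" (both flanks clipped away).
    """
    if copy_count >= copy_floor:
        return "validated"
    lf, rf = locus.left_flank_length, locus.right_flank_length
    flanks = []
    if lf > 0:
        flanks.append(locus.sequence[:lf])
    if rf > 0:
        flanks.append(locus.sequence[len(locus.sequence) - rf:])
    if not flanks:
        return "indeterminate"

    masked_self = (genome.sequence[:locus.genome_start]
                   + _pairwise.NT_MASK * (locus.genome_end - locus.genome_start)
                   + genome.sequence[locus.genome_end:])
    targets = [masked_self]
    for g in related_genomes or []:
        targets.append(g.sequence)

    for flank_seq in flanks:
        for target in targets:
            for candidate in (target, revcomp(target.replace(_pairwise.NT_MASK, "N"))):
                aln = _pairwise.local_nucleotide(candidate, flank_seq)
                if aln is None:
                    continue
                cov = (aln.query_span[1] - aln.query_span[0]) / len(flank_seq)
                if aln.identity >= min_identity and cov >= min_coverage:
                    return "validated"
    return "contamination"


def hits_to_tsv(hits: list[AlignmentHit], path: str | Path) -> None:
    """TSV hit report with 1-based inclusive coordinates."""
    import pandas as pd

    rows = [{
        "query": h.query_id, "genome": h.genome_id,
        "start": h.start + 1, "end": h.end, "strand": h.strand,
        "frame": h.frame, "score": h.score, "evalue": f"{h.evalue:.3g}",
    } for h in hits]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def loci_to_fasta(loci: list[HitLocus], path: str | Path) -> None:
    """FASTA of extracted loci, coordinates encoded as id:start-end:strand."""
    recs = [GenomeRecord(
        id=f"{l.hit.genome_id}:{l.genome_start + 1}-{l.genome_end}:{l.hit.strand}",
        species=l.hit.genome_id, sequence=l.sequence) for l in loci]
    from .io_formats import write_fasta
    write_fasta(recs, path)
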