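"""Staged pipeline driver: mine -> boundaries -> transposase -> family.

Thin orchestration over the stage modules, shared by the CLI and by
reproduction scripts.  Each stage is independently runnable through its own
module; this driver only wires their inputs and outputs together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import boundaries, family, mining, transposase
from .io_formats import GenomeRecord, PipelineConfig, logger


@dataclass
class AnnotatedElement:
    locus: mining.HitLocus
    tir_call: boundaries.TIRCall | None
    element_sequence: str | None
    annotation: transposase.TransposaseAnnotation | None
    status: str = "truncated"

    @property
    def element_id(self) -> str:
        h = self.locus.hit
        return f"{h.genome_id}:{h.start + 1}-{h.end}:{h.strand}"


@dataclass
class GenomeAnnotation:
    genome: GenomeRecord
    elements: list[AnnotatedElement] = field(default_factory=list)
    family_model: family.FamilyModel | None = None


def annotate_genome(genome: GenomeRecord, queries: list[GenomeRecord],
                    config: PipelineConfig | None = None,
                    build_family_model: bool = True) -> GenomeAnnotation:
    """Run the full per-genome pipeline with the configured thresholds."""
    config = config or PipelineConfig()
    out = GenomeAnnotation(genome=genome)

    loci = mining.iterate_search(queries, [genome], max_rounds=3,
                                 evalue_threshold=config.evalue_threshold,
                                 flank=config.flank_bp,
                                 min_orf_aa=config.min_orf_aa)
    for locus in loci:
        call = boundaries.detect_tsd_tir(
            locus.sequence,
            min_tir_length=config.min_tir_bp,
            max_mismatch_fraction=config.max_tir_mismatch_fraction,
            mismatch_penalty=config.tir_mismatch_penalty,
            tsd_pattern=config.tsd_pattern,
            tsd_max_mismatches=config.tsd_max_mismatches,
            core_span=locus.core_span)
        element_seq = None
        annotation = None
        if call is not None:
            s, e = call.element_span
            element_seq = locus.sequence[s:e]
            annotation = transposase.annotate_transposase(
                element_seq, min_orf_aa=config.min_orf_aa)
        status = boundaries.classify_completeness(call, annotation is not None)
        out.elements.append(AnnotatedElement(
            locus=locus, tir_call=call, element_sequence=element_seq,
            annotation=annotation, status=status))

    out.elements = _collapse_duplicate_elements(out.elements)

    logger.info("genome %s: %d loci, %d with boundaries, %d intact",
                genome.id, len(out.elements),
                sum(1 for e in out.elements if e.tir_call),
                sum(1 for e in out.elements if e.status == "intact"))

    if build_family_model:
        out.family_model = build_species_model(out, config)
        if out.family_model is not None:
            count, _ = family.estimate_copy_number(
                out.family_model.sequence, genome,
                min_identity=config.copy_number_min_identity,
                min_coverage=config.copy_number_min_coverage)
            out.family_model.copy_number = count
    return out


def _genome_span(el: AnnotatedElement) -> tuple[int, int]:
    if el.tir_call is not None:
        return el.locus.locus_to_genome(el.tir_call.element_span)
    return el.locus.hit.span()


def _collapse_duplicate_elements(elements: list[AnnotatedElement]
                                 ) -> list[AnnotatedElement]:
    """Merge loci that resolved to the same element.

    A pseudogenized copy yields several stop-respecting HSPs, each of whose
    loci boundary-calls to the same element span; one element per span is
    kept (preferring annotated, then bounded, then higher mining score)."""
    def rank(el: AnnotatedElement):
        return (el.annotation is not None, el.tir_call is not None,
                el.locus.hit.score)

    kept: list[AnnotatedElement] = []
    for el in sorted(elements, key=rank, reverse=True):
        span = _genome_span(el)
        duplicate = False
        for other in kept:
            o = _genome_span(other)
            lo, hi = max(span[0], o[0]), min(span[1], o[1])
            ov = max(0, hi - lo)
            if ov >= 0.5 * (span[1] - span[0]) and ov >= 0.5 * (o[1] - o[0]):
                duplicate = True
                break
        if not duplicate:
            kept.append(el)
    kept.sort(key=lambda e: _genome_span(e))
    return kept


def build_species_model(annotation: GenomeAnnotation,
                        config: PipelineConfig) -> family.FamilyModel | None:
    """Consensus when >= 5 bounded copies (and not too many truncated),
    otherwise the best-scoring locus as representative."""
    bounded = [e for e in annotation.elements if e.element_sequence]
    if not annotation.elements:
        return None
    truncated_fraction = 1 - len(bounded) / len(annotation.elements)
    if len(bounded) >= config.consensus_min_copies and \
            truncated_fraction <= config.max_truncated_fraction:
        msa = family.center_star_msa([e.element_sequence for e in bounded])
        consensus, _ = family.build_consensus(msa, min_copies=config.consensus_min_copies)
        return family.FamilyModel(
            species=annotation.genome.species, sequence=consensus,
            method="consensus", n_copies_used=len(bounded),
            parameters={"min_identity": config.copy_number_min_identity,
                        "min_coverage": config.copy_number_min_coverage})
    candidates = [family.RepresentativeCandidate(
        genome_id=annotation.genome.id,
        sequence=e.element_sequence or e.locus.sequence,
        score=e.locus.hit.score,
        species=annotation.genome.species) for e in annotation.elements]
    return family.pick_representative(candidates)
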