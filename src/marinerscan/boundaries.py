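"""Element boundary definition: locating the TIR pair and flanking TA TSDs.

The boundary signal of a cut-and-paste element is a pair of short inverted
repeats immediately inside a duplicated TA target site.  The detector
enumerates candidate TSD anchors (TA occurrences in the outer halves of the
locus), extends inverted complementarity inward from each anchor pair, and
returns the best-scoring call.

Extension semantics: positions are added until three consecutive mismatches
accumulate; the reported TIR is then the best-scoring prefix that ends on a
match and keeps the cumulative mismatch fraction within tolerance.  The
3-in-a-row terminator makes recovery on undecayed copies exact, while the
fraction bound lets proportionate decay through for both 19 bp and 203 bp
repeats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationRow, logger
from ._pairwise import revcomp

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # complement codes; N -> N

MAX_CONSECUTIVE_MISMATCHES = 3
_PREFILTER_WINDOW = 6
_PREFILTER_MIN_MATCHES = 3


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, 4) for c in seq], dtype=np.int8)


@dataclass
class TIRCall:
    """One boundary call, all spans in locus coordinates (0-based half-open)."""

    left_tir: tuple[int, int]
    right_tir: tuple[int, int]
    tir_length: int
    mismatches: int
    left_tsd: tuple[int, int]
    right_tsd: tuple[int, int]
    element_span: tuple[int, int]
    score: float

    @property
    def element_length(self) -> int:
        return self.element_span[1] - self.element_span[0]


def _tsd_anchor_positions(codes: np.ndarray, pattern: np.ndarray,
                          max_mismatch: int, lo: int, hi: int) -> np.ndarray:
    """Start positions p in [lo, hi) where codes[p:p+len(pattern)] matches."""
    k = len(pattern)
    if hi - lo < k:
        return np.empty(0, dtype=np.int64)
    window = np.lib.stride_tricks.sliding_window_view(codes[lo:hi], k)
    mism = (window != pattern[None, :]).sum(axis=1)
    return np.flatnonzero(mism <= max_mismatch) + lo


def detect_tsd_tir(locus: str,
                   min_tir_length: int = 10,
                   max_mismatch_fraction: float = 0.15,
                   mismatch_penalty: int = 2,
                   tsd_pattern: str = "TA",
                   tsd_max_mismatches: int = 0,
                   core_span: tuple[int, int] | None = None) -> TIRCall | None:
    """Best TSD/TIR boundary call for a locus, or None.

    Candidate left anchors are TSD-pattern occurrences left of the locus
    midpoint, right anchors right of it; when ``core_span`` is given (the
    mined hit, i.e. the transposase ORF, in locus coordinates) anchors must
    flank the core instead — the element necessarily contains its ORF, and
    clipped loci need not be centred on it.  For each anchor pair, inverted
    complementarity is extended inward from the left TSD end and the right
    TSD start; calls are scored ``length - mismatch_penalty * mismatches``
    and ties are broken by longer TIR, then by larger element span
    (outermost anchors).
    """
    L = len(locus)
    k = len(tsd_pattern)
    if L < 2 * (min_tir_length + k):
        return None
    codes = _encode(locus)
    pattern = _encode(tsd_pattern)

    # The anchor split is symmetric under reverse complementation of the
    # locus (with a mirrored core_span).
    anchors = _tsd_anchor_positions(codes, pattern, tsd_max_mismatches, 0, L)
    if core_span is not None:
        left = anchors[anchors + k <= core_span[0]]
        right = anchors[anchors >= core_span[1]]
    else:
        left = anchors[2 * (anchors + k) <= L]
        right = anchors[2 * anchors >= L]
    if left.size == 0 or right.size == 0:
        return None

    comp = _COMP[codes]
    W = _PREFILTER_WINDOW
    # inner starts: left extension reads codes[p+k + i]; right extension
    # reads comp[q-1-i] (i.e. complement of the base just inside the right TSD).
    lstart = left + k
    valid_l = lstart + W <= L
    valid_pairs = []

    lwin = np.stack([codes[p:p + W] for p in lstart[valid_l]]) \
        if np.any(valid_l) else np.empty((0, W), dtype=np.int8)
    lpos = left[valid_l]
    rwin_list = []
    rpos = []
    for q in right:
        if q - W >= 0:
            rwin_list.append(comp[q - W:q][::-1])
            rpos.append(q)
    if not rwin_list or lwin.shape[0] == 0:
        return None
    rwin = np.stack(rwin_list)
    rpos = np.array(rpos)

    # pairwise match counts over the first W inner positions
    matches = (lwin[:, None, :] == rwin[None, :, :]).sum(axis=2)
    span_ok = (rpos[None, :] - (lpos[:, None] + k)) >= 2 * min_tir_length
    cand_i, cand_j = np.nonzero((matches >= _PREFILTER_MIN_MATCHES) & span_ok)

    best: TIRCall | None = None
    best_key = None
    for ci, cj in zip(cand_i, cand_j):
        p = int(lpos[ci])
        q = int(rpos[cj])
        call = _extend_pair(codes, comp, p, q, k, min_tir_length,
                            max_mismatch_fraction, mismatch_penalty)
        if call is None:
            continue
        key = (call.score, call.tir_length,
               call.element_span[1] - call.element_span[0])
        if best_key is None or key > best_key:
            best, best_key = call, key
    return best


def _extend_pair(codes: np.ndarray, comp: np.ndarray, p: int, q: int, k: int,
                 min_tir: int, max_frac: float, penalty: int) -> TIRCall | None:
    """Extend inverted complementarity inward from anchor pair (p, q)."""
    l0 = p + k          # first base of the left TIR
    cap = (q - l0) // 2  # TIRs must not cross the element midpoint
    mism = 0
    run = 0
    cum = []            # cumulative mismatches after each position
    i = 0
    while i < cap:
        if codes[l0 + i] != comp[q - 1 - i] or codes[l0 + i] == 4:
            mism += 1
            run += 1
        else:
            run = 0
        cum.append(mism)
        i += 1
        if run >= MAX_CONSECUTIVE_MISMATCHES:
            break

    best_n, best_score, best_m = 0, None, 0
    m_prev = 0
    for n in range(1, len(cum) + 1):
        m = cum[n - 1]
        matched_last = m == m_prev
        m_prev = m
        if not matched_last or n < min_tir:
            continue
        if m > max_frac * n:
            continue
        score = n - penalty * m
        if best_score is None or score > best_score or \
                (score == best_score and n > best_n):
            best_n, best_score, best_m = n, score, m
    if best_score is None:
        return None
    return TIRCall(
        left_tir=(l0, l0 + best_n),
        right_tir=(q - best_n, q),
        tir_length=best_n,
        mismatches=best_m,
        left_tsd=(p, p + k),
        right_tsd=(q, q + k),
        element_span=(l0, q),
        score=float(best_score),
    )


def classify_completeness(tir_call: TIRCall | None,
                          transposase_present: bool) -> str:
    """"intact" iff both TIRs are called and a triad-bearing ORF >= 200 aa exists."""
    return "intact" if (tir_call is not None and transposase_present) else "truncated"


def boundary_logo_matrix(elements: list[tuple[str, TIRCall]],
                         flank: int = 10, tsd: int = 2, tir: int = 30):
    """Per-column base frequencies and information content of the boundary logo.

    Each element with a TIR call contributes two windows of
    ``flank + tsd + tir`` columns: its left end read forward and its right
    end reverse complemented, so both boundaries are read in the same
    orientation (flank, then TSD, then TIR).  Information content is
    ``2 - H`` bits per column with H the Shannon entropy (base 2) of the
    gap-excluded base frequencies.

    Returns a pandas DataFrame with columns A, C, G, T, bits, n indexed by
    1-based column number.
    """
    import pandas as pd

    if len(elements) < 2:
        raise ValueError("boundary_logo_matrix needs >= 2 elements with TIR calls")
    width = flank + tsd + tir
    windows: list[str] = []
    for locus, call in elements:
        lt = call.left_tsd
        ls = locus[max(0, lt[0] - flank):lt[0]].rjust(flank, "-")
        lseq = ls + locus[lt[0]:lt[1]].ljust(tsd, "-") \
            + locus[call.left_tir[0]:call.left_tir[0] + tir].ljust(tir, "-")
        rt = call.right_tsd
        rflank = revcomp(locus[rt[1]:rt[1] + flank]).rjust(flank, "-")
        rtsd = revcomp(locus[rt[0]:rt[1]]).ljust(tsd, "-")
        rtir = revcomp(locus[max(call.right_tir[0],
                                 call.right_tir[1] - tir):call.right_tir[1]]).ljust(tir, "-")
        rseq = rflank + rtsd + rtir
        windows.extend([lseq[:width], rseq[:width]])

    n_seqs = len(windows)
    rows = []
    for col in range(width):
        counts = {b: 0 for b in "ACGT"}
        for w in windows:
            c = w[col]
            if c in counts:
                counts[c] += 1
        total = sum(counts.values())
        if total == 0:
            freqs = {b: 0.0 for b in "ACGT"}
            bits = 0.0
        else:
            freqs = {b: counts[b] / total for b in "ACGT"}
            h = -sum(f * np.log2(f) for f in freqs.values() if f > 0)
            bits = 2.0 - h
        rows.append({**freqs, "bits": bits, "n": total})
    df = pd.DataFrame(rows, index=pd.RangeIndex(1, width + 1, name="column"))
    logger.info("boundary logo over %d end windows (%d elements)", n_seqs, len(elements))
    return df


def tir_call_to_gff(genome_id: str, call: TIRCall, locus, element_id: str,
                    status: str = ".") -> list[AnnotationRow]:
    """GFF3 rows (element + TIR/TSD children) in genome coordinates."""
    strand = locus.hit.strand

    def g(span):
        return locus.locus_to_genome(span)

    el = g(call.element_span)
    rows = [AnnotationRow(genome_id, el[0], el[1], strand, "element",
                          {"ID": element_id, "status": status})]
    for feature, span in (("TIR_left", call.left_tir), ("TIR_right", call.right_tir),
                          ("TSD_left", call.left_tsd), ("TSD_right", call.right_tsd)):
        gs = g(span)
        if strand == "-" and feature in ("TIR_left", "TIR_right", "TSD_left", "TSD_right"):
            # locus orientation flips left/right on the forward strand
            feature = {"TIR_left": "TIR_right", "TIR_right": "TIR_left",
                       "TSD_left": "TSD_right", "TSD_right": "TSD_left"}[feature]
        rows.append(AnnotationRow(genome_id, gs[0], gs[1], strand, feature,
                                  {"Parent": element_id}))
    return rows
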