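# Methods

## Scope and model

`marinerscan` implements the discovery-and-characterization protocol for a
Tc1/mariner DNA-transposon family of the DD37E type: translated homology
mining of transposase queries against nucleotide genomes, algorithmic
calling of the element boundaries (terminal inverted repeats flanked by TA
target-site duplications), per-species consensus/representative family
models with copy-number estimation, annotation of the transposase
(longest ORF, D-D-E catalytic triad, signature spacing, nuclear
localization signal, PAIRED region), distance-based phylogenetics, and
horizontal-transfer (HT) detection by comparing transposon and host-gene
divergence between species.

Because the protocol is defined against public whole-genome assemblies,
the package ships a first-class synthetic-data module that emulates the
evolutionary structure the analysis assumes — planted element copies with
known boundaries, neutral decay, truncation, and vertical/horizontal
transmission histories along a species tree — so every stage can be scored
against exact ground truth.

## Canonical element profile

The family-canonical geometry is held in `CanonicalProfile`:

| parameter | default | meaning |
|---|---|---|
| `element_length` | 1300 bp | total element length (family mode ~1.3 kb; variants up to 1.8 kb and beyond exist and are expressible per profile) |
| `transposase_aa` | 340 | transposase length; ORF = 3·(340+1) nt incl. stop |
| `tir_length` | 28 bp | per-copy TIR; family-wide range 19–203 bp |
| `tsd` | `TA` | target-site duplication, literal on both flanks |
| `triad_spacing` | 37 | residues strictly between D2 and E (`DD37E`) |
| `catalytic_domain_aa` | 140 | C-terminal catalytic domain length |
| `d1_position`, `d2_position` | 220, 270 | 0-based triad aspartates; E = D2 + spacing + 1 = 308 |

Signature convention: `DD{n}E` counts residues *strictly between* the
second aspartate and the glutamate (n = E − D2 − 1). The alternative
convention (n = E − D2) exists in the literature; one rule is applied
consistently to references and queries, so family labels are
self-consistent.

## Synthetic data generator

* **Background and decay.** Backgrounds are i.i.d. uniform A/C/G/T. Decay
  and host-gene evolution are i.i.d. per-site substitutions, uniform
  across the three alternatives by default, with an optional transition
  bias `kappa` so K2P estimation is non-trivial. Indels are excluded from
  the decay model (substitution + truncation only), keeping boundary truth
  exact.
* **Family homology.** Every generated element encodes one fixed
  family-canonical protein (a package constant per profile geometry); the
  seed varies codon usage, TIR sequence, and spacers. Family members are
  homologous by definition — this is what makes alignment transfer from
  the packaged reference domain meaningful.
* **Codon-aware decay is deliberately absent**: substitutions may create
  stop codons, which is how pseudogenized (truncated-status) copies arise.
* **TSDs** are planted as literal duplicated `TA` and are not decayed; the
  decay rate models post-insertion drift of the copy itself, and keeping
  the TSDs literal keeps the truth channel exact. A 1-mismatch TSD
  tolerance flag in the detector (`tsd_max_mismatches=1`) covers data
  whose TSDs have decayed.
* **Ground-truth identifiability guards.** Three construction rules make
  the planted truth well-defined rather than merely likely: an in-frame
  stop sits immediately 5′ of the ORF start (otherwise ~25% of elements
  would carry a longer chance ORF); the three bases just inside each TIR
  break inverted complementarity (the planted TIR is maximal); and
  mirrored TA dinucleotide pairs within 60 bp of the insertion site are
  broken (otherwise inverted-repeat extension can ride the planted TIRs
  from shifted flank anchors, producing a wider, equally valid boundary —
  real curation resolves such ambiguity by aligning multiple copies).
* **Copy spacing.** `plant_copies(min_separation=...)` keeps neighbouring
  copies apart; desk-scale fixtures compress megabase genomes into tens of
  kilobases, and two identical copies inside one 2 kb-flank locus would
  make the outermost-anchor tie-break call a two-copy span. The
  canonical round-trip fixtures use 4500 bp.
* **Species sets.** `simulate_species_set` evolves four host genes
  (RPL3 1160 bp, RPL5 900 bp, Hsc70-4 1900 bp, Tub3 1350 bp — lengths
  typical of the real CDSs; the sequences themselves are uniform-random,
  without codon structure) and the transposon along a user newick tree.
  Host genes move at `host_rate ·` branch length substitutions/site; the
  transposon at `te_rate_multiplier` times that. A horizontal event copies
  the donor's element into the recipient at `ht_divergence = 0.005`
  substitutions/site. Planted genomic copies additionally carry
  `copy_decay = 0.02`/site of post-insertion neutral drift, and the first
  planted copy is exported as the species' observed element. This drift
  is the biological asymmetry that gives the HT test its specificity:
  vertically inherited dead copies are always at least as divergent as the
  host genes, so under pure vertical transmission d_TE sits above d_host
  and the all-genes rule essentially never false-calls. With
  `copy_decay=0` and equal rates, d_TE and d_host are exchangeable and
  the strict `d_TE < min(d_host)` event would fire ~1/5 of the time.

What the generator does **not** emulate: real base composition, codon
structure of host genes, indels, nested insertions, insertion-site
preference beyond TA, within-species polymorphism (no coalescent), and
sequence contamination with realistic vector chemistry. Passing tests
therefore demonstrate algorithmic correctness under the stated model, not
performance on real assemblies.

## Mining

A Smith–Waterman search with iterated masking stands in for a seeded
translated BLAST: all six conceptual translations of the genome are
scanned exhaustively, the best local alignment is peeled off, masked, and
the scan repeated until the Karlin–Altschul expectation
E = K·m·n·exp(−λS) (fixed published gapped BLOSUM62/11/1 constants
λ = 0.267, K = 0.041; m = query aa, n = genome bp) exceeds the threshold
(default 1e-4). The constants are deliberately not estimated per search:
the E-value's role here is deterministic rank filtering.

Stop codons are hard barriers. Because a −∞ substitution score cannot
prevent an alignment from *bridging* a stop with a deletion gap, the
target is aligned segment-wise between stops. A pseudogenized copy hence
yields one HSP per intact ORF segment; downstream, the pipeline collapses
loci whose called element spans overlap reciprocally by ≥ 50%.

Hits are widened by 2 kb per side (clipped at contig ends, flagged),
reverse-complemented into coding orientation on the minus strand.
Iterative query expansion adds the longest ORF (≥ 200 aa) of each new
locus to the query pool and stops at a fixed point or after `max_rounds`.
Loci with fewer than 3 genomic copies are screened for contamination by
mapping their flanks (≥ 80% identity over ≥ 50% of flank length) to the
host or related genomes.

## Boundary calling

Candidate anchors are occurrences of the TSD pattern; left anchors must
lie left of the locus midpoint and right anchors right of it, or — when
the mined ORF span is supplied (`core_span`) — must flank the ORF, which
also covers loci clipped at contig ends. For each anchor pair,
inverted complementarity is extended inward until three consecutive
mismatches accumulate; the reported TIR is the best-scoring prefix
(score = length − 2·mismatches) that ends on a match and keeps the
cumulative mismatch fraction ≤ 0.15. The best call wins by score, then
longer TIR, then larger element span (outermost anchors). The
3-in-a-row terminator makes undecayed recovery exact; the fraction bound
admits proportionate decay for both 19 bp and 203 bp repeats.
A literal running-fraction extension rule was rejected: mismatches in
flanking sequence accrue at 0.75/bp against a budget of 0.15/bp, so every
TIR would systematically overshoot by ~18% of its length.

An element is **intact** iff both TIRs are called *and* a ≥ 200 aa ORF
with a located catalytic triad exists; otherwise truncated.

The boundary logo covers 42 columns (10 bp flank, 2 bp TSD, 30 bp TIR);
each bounded element contributes both ends (the right end
reverse-complemented). Information content is 2 − H bits per column from
gap-excluded base frequencies; invariant columns reach exactly 2 bits.

## Family models and copy number

With ≥ 5 bounded copies (and at most 80% of loci truncated — an explicit
non-published knob, `max_truncated_fraction`), the model is the strict
per-column majority consensus of a center-star multiple alignment
(match +2, mismatch −2, gap open −6, extend −1; gap-majority columns
dropped; base ties broken alphabetically and flagged). Otherwise the
best-scoring locus is the representative. Copy number is the count of
merged nucleotide local-alignment hits (match +1, mismatch −2, open −5,
extend −2, both strands, iterated masking, > 50%-overlap merge keeping the
higher score) with identity ≥ 80% and *model* coverage ≥ 40%.

## Distances, trees, classification

Identities are computed over columns where neither sequence is gapped.
Distances default to Kimura two-parameter,
d = −½·ln((1 − 2P − Q)·√(1 − 2Q)), with pairwise deletion; saturated
pairs (log argument ≤ 0) are flagged and excluded downstream, not stored
as infinities. K2P replaces the maximum-composite-likelihood distance of
the original protocol (MCL needs joint estimation across all pairs; K2P
preserves the inferential logic — relative magnitude of transposon vs
host distances — at far lower complexity) and every HT report carries a
header noting the substitution. Trees are canonical Saitou–Nei neighbor
joining (Studier–Keppler Q-matrix, negative branch lengths clamped to 0,
ties broken by the lexicographically smallest cluster pair), with
classical nonparametric bootstrap (default 1000 replicates) in place of
ultrafast bootstrap / ML / Bayesian inference; monophyly statements are
therefore only checked on simulated data where truth is known.
Family classification assigns a query catalytic domain to the reference
family with the highest mean global-alignment identity, reporting the
margin to the runner-up (margin < 0.05 flags low confidence) and whether
the query's signature string matches the assigned family's.

## Horizontal-transfer detection

Species pairs are gated on transposon identity strictly > 70% (the
protocol's text contains a contradictory sentence about exclusion on both
sides of 70%; the operative strict ">70% remained" rule is used, and the
strictness is noted in reports). For surviving pairs, d_TE is compared
with each available host gene's distance: **HT** iff d_TE < d_host for
*all* available genes; **vertical** iff d_TE ≥ all; mixed signs are
**indeterminate** rather than forced (the conservative all-genes reading
of an ambiguous singular phrasing; it minimizes false HT calls). Host
genes missing for a species drop out per-pair, not globally; no distances
are computed for excluded-identity pairs; no secondary ratio cutoff is
imposed beyond strict inequality. A tree-incongruence cross-check
restricts the transposon and species trees to shared taxa (≥ 4, else a
warning), enumerates mutually incompatible bipartitions, and annotates
each verdict with whether either species sits on the minority side of a
conflicting bipartition.

## Numerical and degenerate-input choices

* All randomness flows through `numpy.random.Generator`; identical seeds
  give byte-identical FASTA output.
* Internal coordinates are 0-based half-open everywhere; conversion to
  1-based inclusive happens only at the GFF3/report boundary.
* Gap convention in every aligner and oracle: a gap of length k costs
  `open + k·extend`.
* `N` scores as a mismatch against everything (including `N`); codons
  containing N translate to `X`, which scores −1 against all residues.
* Triad transfer uses a free-end-gap global alignment of the protein's
  C-terminal 200 aa against the 140 aa reference domain; a transferred
  position must carry the expected residue, with a ±2 rescue window.
  Under 2% per-site decay the joint survival of the three catalytic
  codons is ≈ 0.95³ ≈ 0.85 (≈ 0.88 with rescue), which is the measured
  triad-recovery rate on non-truncated copies; the robustness test
  asserts the analytically supported ≥ 75% bound.
* Empty inputs, single-species trees, identity-0 columns, saturated
  pairs, and clipped flanks all return typed results or explicit errors
  rather than silent degradation (see the per-module tests).

## Problem sizes

Simulated fixtures are desk-scale by design: genomes of 3–46 kb with 1–10
planted copies, 40-scenario batches for HT power/specificity, 50-fixture
batches for boundary recovery, 200 random pairs for the alignment-oracle
equivalence, and 100–1000 bootstrap replicates. The full test suite and
the reproduction script each run in minutes on one CPU.

## Known limitations

* O(mn) exhaustive Smith–Waterman; no k-mer seeding or multithreading —
  genome inputs beyond a few hundred kb per query become slow.
* The boundary detector assumes a dinucleotide TSD pattern; longer or
  degenerate patterns work mechanically but the anchor statistics (and
  the outer-half restriction) were designed for TA.
* The packaged reference domain profile is a synthetic stand-in generated
  from the canonical profile, not a curated HMM; on real data a curated
  domain model should replace it.
* Secondary-structure prediction of the PAIRED helices, intron-aware gene
  prediction, ML/Bayesian tree inference, HT dating, and sub-terminal
  inverted repeats are out of scope.
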