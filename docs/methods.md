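# Methods

This note documents the models and procedures `trfkit` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Discovery model

Reads are assumed pre-trimmed, sense-strand, 15–30 nt (the sequencing window
of the original 454 experiment; tRNA halves of 31–40 nt are outside it by
design and are not called). Alignment is ungapped sliding-window Hamming
comparison against mature tRNA sequences, CCA included, with
`max_mismatches = 2` — enough to keep fragments carrying sequencing errors or
modification-induced RT errors. T and U are identical for mismatch counting;
N matches nothing, including another N. All placements at or under the
budget are reported, ordered by (reference, start). The aligner is
property-tested against an exhaustive Hamming-scan oracle.

Calling quantifies two published criteria:

- **Abundance** — a fragment must be cloned *more than* `min_count = 3`
  times. The threshold is strict (4 reads call, 3 do not) and applied per
  input table.
- **Dominance** — the fragment must be the modal fragment of its mature tRNA
  and hold at least `dominance_threshold = 0.5` of the read mass aligned to
  it. Majority share is the weakest quantification of "dominated by" that is
  still a property of the read distribution; it is a configurable knob. A
  modal tie means no fragment dominates, so no call is made (logged).

Reads whose best alignments reach k distinct mature sequences contribute
count/k to each (fractional assignment); identical-sequence isodecoders are
collapsed before accounting, and a fragment supported by several references
of one isoacceptor family yields one call for that family. End classes use
`end_slack = 1` nt at both termini — printed fragments sit flush at the tRNA
ends, and 1 nt absorbs non-templated/CCA ambiguity without admitting internal
fragments. A fragment covering ≥ 90 % of its mature tRNA is classified
mature-like and never called (unreachable under the default length window,
but enforced for safety).

## Dataset mining

The published mining procedure ran BLAST per tRF against processed GEO
tables. Because the queries are 18–30 nt and every divergence the study
reports is pure 3′-length variation (fragments 1–4 nt longer or shorter in
other species and tissues), `trfkit` replaces the external aligner with
exact anchored matching: a 5′tRF query matches a table sequence sharing its
5′ end (0 anchor mismatches by default, configurable) whose length differs
by at most `length_tolerance = 4`; 3′tRFs use the suffix rule. Overlapping
queries are disambiguated deterministically (fewest anchor mismatches,
longest overlap, smallest length difference, panel order), so no table
sequence is counted twice.

Profiles keep aggregates with *more than* 50 reads (strict; the per-variant
breakdown is always reported because the published wording does not resolve
whether the filter applied per sequence or per aggregate). Abundance is
normalized to reads per million total small-ncRNA reads — the study
normalizes to total sncRNA reads without naming a unit, and RPM is the field
standard. Ratios are computed on normalized abundances (libraries differ in
depth), never raw counts; a zero-count control makes the ratio undefined
rather than infinite.

Variant spectra are summarized as position-frequency matrices anchored at
the 5′ end, 3′-padded to the longest variant and weighted by cloning
frequency. Columns are normalized by total profile depth: positions covered
by every variant sum to 1, trailing positions sum to the fraction of reads
long enough to reach them (this is the convention that makes a 50/50 mix of
n and n+1 mers put weight 0.5 in the last column, which is what a logo of
3′-end heterogeneity should show).

## Target prediction and sensor design

The seed is tRF positions 2–7. The study's operational description uses
2–7 while its narrative once says 2–8; the operational wording wins here and
the range is a parameter (`seed_range`). Pairing is strict Watson–Crick —
G:U wobble counts as a mismatch (configurable) because the rule demands a
*perfect* seed match. Scanning is sense-strand only with fixed-length
windows (tRF length); up to `max_nonseed_mismatches = 6` elsewhere.

Thermodynamic screening is a nearest-neighbor stack-sum: adjacent paired
positions contribute the Xia 1998 Watson–Crick RNA stack free energy
(kcal/mol, 37 °C) keyed by the guide dinucleotide; terminal dangles are
ignored. The default `mismatch_penalty` is 0.0 kcal/mol, so a duplex with no
complementary positions scores exactly 0, any stacked pair is strictly
stabilizing, and converting a mismatch to a pair can never raise the energy;
a positive penalty is available as a knob for users who want internal loops
penalized. The confirmation threshold defaults to −15 kcal/mol — the study
names no number, and this is a common hybridization-screen default —
and unconfirmed sites are flagged rather than dropped so the caller decides.

The sensor cassette plants two copies of the complement site around an
EcoRV-bearing spacer inside XhoI/NheI overhangs; mutation maps address the
site base facing each tRF position (site position p ↔ tRF position
L−p+1). The shipped Pro-CGG maps reproduce the published 5′-mutant and
3′-mutant primer pairs byte-exactly, and all five published pairs (control
included) are regression-locked in the test suite.

## Shape probabilities

The folding model is intentionally minimal: additive per-pair energies
(GC −3, AU −2, GU −1, arbitrary units), hairpin loops of at least 3 nt, no
loop penalties, pseudoknots excluded, lonely pairs allowed. The point is the
*shape-probability mechanism* — P(shape) as summed Boltzmann mass over all
structures falling into the shape — with correctness guaranteed by oracle
equivalence, not numeric reproduction of any external thermodynamic
parameter set. Published shape-probability figures obtained with full
thermodynamics are therefore treated as qualitative expectations only.

Shapes are abstracted at the coarsest informative level (every helix-nested
unit → `[]`), which distinguishes exactly the hairpin-vs-cloverleaf question.
The primary computation is an interval dynamic program whose cell value maps
each realizable shape forest to the log of its summed Boltzmann weight;
log-space accumulation keeps very low `temperature_scale` values (sharp
Boltzmann limits) from overflowing. Enumeration (≤ 30 nt) is the independent
oracle; both paths agree to 1e-9 on random sequences.

The DP is exact, and its cost grows with the number of *realizable shapes*,
which for unstructured random sequences of ~76 nt reaches 10^5 and minutes
of runtime. Designed or strongly structured transcripts are far cheaper
(hundreds of shapes). The shipped demonstrations and acceptance runs
therefore fold designed hairpin- and cloverleaf-prone transcripts of 28 and
48 nt (sub-second, exhaustively checkable); folding full-length tRNA
transcripts works but is a minutes-scale computation per sequence.

A transcript is *hairpin-prone* when P(`[]`) exceeds every other single
shape's probability, with a strong-call flag above 0.7.

## Synthetic libraries

The generator defines the conditions every downstream test runs under:

- **Reference fixture.** Ten deterministic 76-nt mature tRNAs, each hosting
  one published zebrafish tRF at its declared end (5′tRFs as exact prefixes,
  3′tRFs as exact suffixes). The two Glu-CTC fragments sit on two
  same-anticodon isodecoders, so each dominates its own mature sequence —
  matching the study's observation that both derive from tRNA-Glu. Reference
  bodies are pseudo-random but fixed (seeded per reference id), end in CCA
  except where the embedded 3′tRF lacks the tail, and are verified to host
  each fragment uniquely at ≤ 2 mismatches.
- **Spikes.** Exact fragment copies at specified cloning frequencies.
  Optional end jitter emulates the observed 3′-length heterogeneity: a
  fraction (default 30 %) of spike reads get a length delta drawn from a
  symmetric truncated geometric (p = 0.5) over ±1..±jitter, capped at ±4 —
  the largest variant observed when the panel was chased through public
  datasets. Jitter acts at the fragment's *free* end (3′ for 5′tRFs, 5′ for
  3′tRFs): the anchored end is the tRNA terminus, and a 3′tRF cannot extend
  past it with templated bases. Deltas that would leave the reference or the
  read-length window fall back to the exact fragment.
- **Degradation background.** Fragment start positions uniform over the
  reference, lengths uniform over the read-length window, reference chosen
  by an assignable copy-number weight (uniform default). This is the natural
  random-degradation null the discovery rules exist to reject.
- **Decoys.** Fragments of deterministic non-tRNA ncRNA sequences
  (rRNA/snRNA/snoRNA), exercising the class-partition step.
- **Condition pairs.** Per-spike counts are negative binomial with
  Var = μ + αμ² and dispersion α = 0.05 (the study used single libraries, so
  any overdispersion choice is ours; 0.05 is a standard mild value).
  Background and decoy mass enters both totals as untabulated sncRNA reads,
  as in real processed tables.

All randomness flows through one seeded generator per call; identical
spec + seed reproduce identical bytes, and every library carries a
machine-readable truth record.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing error (454 homopolymer artifacts),
quality scores, modification-induced mismatch patterns, realistic tRNA
sequence similarity between isoacceptors (bodies are random, so cross-family
multi-mapping is rarer than in a real genome), and any biological structure
in the degradation background.

## Problem sizes and recovery conditions

Recovery experiments use spikes of 100 reads per tRF over a 60-reference set
(the 10 fixture hosts plus 50 unspiked tRNAs emulating a genome-scale gene
set), chosen so the dominance statistic faces a realistic multi-reference
background: at 5× background (5 000 uniform reads), the expected per-
reference background mass (~83 reads) sits just below the spike (100), so
majority dominance holds with probability ≈ 0.97 per fragment — clean
libraries recover precision and recall 1.0, and recall stays ≥ 0.9 under 5×
background (50 replicates). These runs use `max_mismatches = 0` (exact
assignment, zero jitter), isolating the calling statistics from alignment
fuzz. Fold-change recovery uses an expected count of 10 000 against a 10^6-
read background over 100 replicates, summarized by the geometric mean of
recovered ratios (the arithmetic mean of a ratio is biased upward by ~CV²,
about 5 % at this dispersion, which would say nothing about the estimator).
The background-collision check for the >3-read rule runs 10 000 reads over
800 × 80-nt references, where the uniform-positioning analysis puts the
chance of any fragment exceeding 3 copies near 10⁻³ per library.

## Known limitations

- Gapped alignment, genome-wide mapping, pre-tRNA trailer fragments
  (tRF-1/3′U-tRF) and tRNA halves are out of scope.
- Anchored matching cannot find mining variants with internal mismatches
  unless `max_anchor_mismatches` is raised.
- The duplex energy has no loop/dangle terms; it ranks duplexes by stacking
  only.
- The shape DP's exactness makes long unstructured sequences expensive; there
  is no sampling fallback.
- Discovery applies its thresholds per input table; pooling across libraries
  is the caller's responsibility.
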