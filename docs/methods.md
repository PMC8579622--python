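# Methods

`spretrace` reimplements, as a tested library, a two-step discovery analysis
for a short retroviral RNA element (the SPRE: a 17-nt core motif,
`TCAGCAGGAAGCAGTTA`, flanked by two C-rich motifs) in repeat-family
consensus libraries and genomes. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## The two-step search

A 17-nt motif is too short to search sensitively on its own: exact matching
has no tolerance for divergence, and relaxed matching of so few positions
drowns in chance hits. The pipeline therefore works in two steps.

**Step 1 (seed).** Exact string matching of the core motif over every
consensus in the library, on both strands. Each hit is expanded into a
fixed-width anchored window: 40 nt of 5' flank + 17-nt core + 40 nt of 3'
flank = 97 columns, read in the hit's orientation and gap-padded where the
consensus ends early. Because the windows are fixed-width and core-anchored,
the first alignment is produced by simply stacking them (core fixed at
columns 41–57); a general-purpose multiple aligner would add nothing to
sequences that are already anchored, and the anchor-based alignment is
deterministic.

Step-1 matching searches both strands by default; a `both_strands=False`
flag restricts to the plus strand for users who want single-strand
behaviour.

**Step 2 (refine).** A profile HMM is estimated from the alignment and
searched against the whole library. Hits below the E-value threshold
(1e-5 throughout) are realigned in model-column coordinates, a new model is
built from them, and the cycle repeats (default 10 cycles). The cycle with
the most hits is adopted, with ties broken toward the earliest cycle.
Iteration stops early when a cycle yields no hits or exactly reproduces the
previous hit set — under the tie rule an early stop cannot change the
selected cycle. Hit counts typically rise as the model absorbs true family
variation and then fall as realignment noise dilutes it; the package
records every cycle so the phenomenon can be examined, but asserts no
mechanism.

## The profile HMM

Plan-7-style local architecture: match states `M_1..M_M` with
position-specific emissions over {A,C,G,T}, insert states `I_1..I_{M-1}`,
silent deletes `D_2..D_M`. No flanking self-loop segment; multiple hits per
target come from masking accepted spans and rescanning.

*Estimation.* Alignment columns with gap fraction < 0.5 (parameter
`gap_threshold`) become match states. Emissions and transitions use
background-proportional additive pseudocounts with weight 1.0 (parameter
`pseudocount`): `p = (counts + w·q) / (total + w)`. This is the stable
textbook choice for the small first-cycle alignments (tens of rows). `N`
characters are missing data: they contribute to no counts and score 0
(background) during search. Plan-7 forbids I↔D transitions; the rare
alignment-derived counts of those pairs are folded into I→M / D→M.

*Local entry/exit.* Entry puts probability 0.5 on `M_1` and spreads the
rest uniformly over `M_2..M_M`; every internal match state exits with
probability 0.01 (`exit_prob`), and `M_M` exits with probability 1. The
split entry makes a 5'-truncated alignment (late entry, ≈ −7.6 bits at
M = 97) cost about the same as a 3'-truncated one (early exit, −6.6 bits).
With uniform entry, late entry would be free while early exit is penalised,
and alignment midpoints drift measurably toward the 3' end — an artefact
that would contaminate the position-bias statistic below.

*Scoring.* Bit score = log2(best local path probability / background
probability of the aligned span). A single-match-state model emitting its
residue with probability 1 scores exactly 2 bits on that residue against a
uniform background. Viterbi uses numba-compiled kernels (an O(M)-memory
scoring pass over long targets, plus a windowed full-traceback pass around
each reported end cell, widened automatically if the optimum is not
reproduced inside the window). The forward implementation is plain Python,
kept as the slow reference; both are checked against exhaustive path
enumeration on tiny models in the test suite.

## E-values

Best-per-sequence local Viterbi bit scores on i.i.d. background sequences
(default 1,000 samples of 200 nt, drawn from the model background) are
fitted to a Gumbel distribution by maximum likelihood
(`scipy.stats.gumbel_r.fit`); then

    E(s) = N_eff · (1 − exp(−exp(−λ(s − μ)))).

`N_eff` is the number of database sequences × 2 strands in library mode and
total scanned residues / model length in genome mode. Calibration scores
one strand per sample — the strand multiplicity of a real search enters
through `N_eff`. The model is recalibrated each cycle (same seed), because
its length and information content change as it refines.

These statistics honour the analysis's E < 1e-5 reporting threshold,
E-value monotonicity, and a tail-accuracy check (empirical exceedance of
the P = 0.01 score within a factor of 3 on fresh background); they are not,
and cannot be, numerically interchangeable with any external search tool's
internal calibration. Published hit counts obtained with a specific tool
and database are therefore reproduction targets only with that tool and
database; the package's own acceptance checks run against synthetic truth.

Background composition is estimated from the searched database and floored
at 0.05 per base, which keeps calibration stable on skewed synthetic
backgrounds.

## Genome scanning

Long targets are scanned in overlapping chunks (default 100 kb, 500 nt
overlap; the overlap must be ≥ model length so no hit is split). Chunk
coordinates are lifted to target coordinates; identical spans are
deduplicated and same-strand hits overlapping by ≥ 1 nt are merged keeping
the lower E-value, which also absorbs boundary-truncated alignments of an
element straddling a chunk edge. E-values use the global background and the
whole-scan `N_eff`, so they do not depend on chunk size; the test suite
checks that 50 kb and 200 kb chunkings give identical hit sets. Hits with
1e-5 ≤ E < 0.01 are reported separately as near-threshold candidates and
excluded from the main table.

## Downstream analytics

*Relative position score.* For a hit at 1-based inclusive positions [S, E]
in a sequence of length L: `[(S + E)/2]/L`, and `1 − [(S + E)/2]/L` on the
minus strand. The reflection interprets strand awareness as measuring
position along the element's own 5'→3' reading, so values near 1 always
mean 3'-terminal placement; `--no-strand-reflect` gives the unreflected
value for users who prefer the plus-strand convention.

*Interval extension and intersection.* Extensions (default 50 nt) are
strand-aware: 3' grows the end on plus-strand features and past the start
on minus-strand features, clamped to the sequence. Intersection requires
≥ 1 nt overlap on the same sequence (and strand, by default) and reports
both records of every overlapping pair; it is backed by interval trees and
verified against an all-pairs oracle. Per-repeat tallies count annotation
records, not hit elements, when one hit spans several annotations.

*Codon usage.* Relative synonymous codon frequencies: within each amino
acid's synonymous family, codon counts normalised to sum to 1 (standard
genetic code via Biopython); unused families report 0. Internal stop
codons are rejected, a terminal stop is counted in the stop family.

## Synthetic data: what it emulates, and what it does not

The generator plants a tripartite element — 5' C-rich motif (`CCTCCCC`),
3–6 nt spacer, 17-nt core, 3–6 nt spacer, 3' C-rich motif (`CCCACCC`) —
into a consensus library, a genome, and decoy sets, with machine-readable
truth. The C-rich motif strings are synthetic stand-ins chosen for their
composition class; they are configuration, not claims about the real
element's consensus.

Default library conditions: 50 families of 800–1,200 nt, 20% carriers
(predominantly LTR-class), flank/spacer substitution rate 0.10, cores
intact. The element's midpoint position along its own 5'→3' reading is
drawn from Beta(5, 1.5) (mean ≈ 0.77), a declared stand-in for a strongly
3'-biased placement; for a minus-strand element the genomic position is
reflected so the strand-aware score recovers the Beta draw. A
`core_max_mutations` knob plants copies with slightly mutated cores — these
are invisible to step-1 exact matching and are how the profile search's
sensitivity gain over exact matching is exercised.

The genome generator inserts non-overlapping diverged copies of whole
family consensuses on both strands and writes RepeatMasker-style
annotations covering each insertion. A separate constructor places elements
exactly 30 nt upstream (5') of LTR-labelled annotations on the same strand,
the configuration in which unextended hits overlap nothing and 50-nt
3'-extended hits overlap everything. Decoy sets contain plain background,
core-only negatives (exact core, no C-rich flanks — found by exact match,
scored well below full elements) and shuffled-core negatives.

What passing tests on these data do **not** show: robustness to
phylogenetically structured divergence (the generator mutates sites
i.i.d.), to recombination between families, to genome-scale repeat
nesting/fragmentation, or to real base-composition heterogeneity. Library
sizes are desk-scale (tens to ~1,100 families, 0.4–1 Mb genomes), chosen so
the full suite runs in minutes on one CPU; sensitivity at these sizes does
not bound sensitivity on a 273k-family database.

## Numerical choices and degenerate inputs

- All randomness flows through explicit seeds (`numpy` Generators); default
  seed 42. Identical inputs + seeds give identical outputs, including
  byte-identical pipeline run directories.
- Log-space scores use −1e30 as the impossible-path sentinel (safe under
  addition, no NaN from ∞−∞ in the kernels).
- Tie-breaks: equal-score traceback prefers match over insert/delete
  continuation (first-listed predecessor); equal peak hit counts select the
  earlier cycle; merged overlapping hits keep the lower E-value.
- Degenerate inputs raise early: empty alignments, all-gap alignments,
  uncalibrated models in E-value paths, zero-variance calibration score
  distributions, chunk overlap below model length.
- Model serialization is a documented plain-text key/value + matrix format
  (HMMER3-like layout, deliberately not byte-compatible with any external
  tool); floats are written at full precision so save/load round-trips
  reproduce scores exactly.

## Known limitations

- E-values extrapolate a Gumbel fitted from ~10³ background maxima into
  deep tails; they are honest thresholds, not calibrated tail probabilities
  beyond the tested factor-of-3 regime.
- The mask-and-rescan multi-hit scheme cannot report two overlapping hits
  on the same strand by construction.
- The EMBL reader covers the Dfam-style ID/NM/DE/CC/SQ subset only, and the
  classification string is exposed raw so users can apply their own
  class mapping.
- `forward_local` is a quadratic-time reference implementation; use it on
  short targets.
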