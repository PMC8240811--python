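# Methods

This note documents the models and conventions behind `junctionlab`, the
choices made where the underlying analysis design was genuinely open, and
what the synthetic test bed does and does not establish.

## Coordinates and sequence conventions

All internal coordinates are 0-based half-open; user-facing tables default
to 1-based inclusive (genome-browser style) and the convention is switchable
per read/write call. A deletion `[s, e)` means bases `s..e-1` are absent and
the carrier's junction sequence is `R[0, s) + R[e, len)`. Sequences are
uppercase DNA over `{A, C, G, T, N}`; `N` never matches any base in any
metric, motif scan, or microhomology comparison (including `N` vs `N`), and
never participates in a base pair. This is deliberately conservative:
ambiguity can only reduce reported homology, never inflate it.

"Distal" follows transcriptional orientation: for a minus-strand gene the 3′
(distal) end of an intron is the *lower* genomic coordinate, so
`distal_subinterval` places the distal window at the low end when the caller
asserts minus strand, and at the high end otherwise. Strand is never guessed.

## Junction fine structure

Microhomology is defined as the breakpoint ambiguity length: `mh_right` is
the maximal run with `R[s+i] == R[e+i]`, `mh_left` the maximal run with
`R[s-1-j] == R[e-1-j]`, and every placement of the breakpoint within
`[s - mh_left, s + mh_right)` yields the identical joined sequence (this is
asserted against a brute-force junction-slide oracle). Published breakpoint
studies often report a single "matching nucleotides" count without defining
the scan; the two-sided ambiguity length is the standard, side-agnostic
convention and is what the package reports. Scans are capped at 50 bp per
side (with a `capped` flag); since the top mechanism class begins above
20 bp, the cap cannot change any classification.

`resolve_junction` anchors an observed junction consensus to the reference
by exact 30-bp seed-and-extend on both ends. If the two flank matches
overlap within the consensus, the overlap is the microhomology; if they
leave a gap, the gap is the inserted sequence. Matching is exact by design —
the consensus is assumed to be error-corrected upstream (e.g. by partial
order alignment of junction-spanning reads), and a mismatch-tolerant mode is
deliberately not provided, so a failure is loud (`UnresolvableJunctionError`)
rather than silently approximate.

Mechanism classification follows the standard junction-signature table:
0–1 bp matching → NHEJ; 2–20 bp → MMEJ; >20 bp → extensive homology
(NAHR-like); 1–10 bp inserted → AROR (re-replication of nearby template);
>10 bp → large insertion. Insertion takes precedence: the "no additional
sequence" and "additional sequence" categories are disjoint, so residual
flank matching next to an insertion is reported in a diagnostic field but
never changes the class. Cohort percentages are formatted to one decimal,
round-half-up (8/22 → 36.4).

## Motif scanning

Palindromes are reverse-complement palindromes (necessarily even length),
found by center expansion and reported only at maximal extent; hits nested
inside a longer hit are suppressed. No mismatch or spacer tolerance is
allowed — the class is defined by a length floor (default 6) only.
Polypyrimidine tracts are maximal `{C,T}` runs (default floor 7). The two
fixed hexamers (TTTAAA and TG(A/G)(A/G)(G/T)(A/C)) are reported at every
occurrence, overlaps included, since downstream use is presence near a
junction. Scans run on the presented 5′→3′ strand; an opt-in flag adds
reverse-complement scanning for the two fixed motifs (palindromes are
strand-symmetric by definition and the pyrimidine alphabet is
strand-specific as printed). Enrichment uses the exact two-sided binomial
test of the observed count against `scanned_bp × background_rate`, with
1/1420 bp as the default TTTAAA genome background.

## Similarity metrics and the Monte Carlo null

Four metrics: longest common substring (contiguous), longest common
subsequence, unit-cost Levenshtein distance, and Hamming distance (defined
only for equal lengths; unequal lengths are an error, never a silent
truncation). The per-pair implementations are plain dynamic programs; the
Monte Carlo null uses an equivalent numpy formulation vectorized across
pairs (tests assert elementwise agreement, and an independent edit-distance
library is used as an external oracle).

The null draws `n_pairs` (default 10,000) independent pairs of i.i.d.
**uniform** random DNA sequences per window length and records mean, SD
(population convention, so a single pair gives SD 0) and the samples.
Uniform composition is used because the expected Hamming distance under
uniformity is `3n/4` — 75.0 at n=100 — which matches the published control
row (75.13/100), whereas a genome-like AT-rich null (GC ≈ 0.36, provided as
an option) would give ≈ 73/100. Randomness is derived per window length from
`SeedSequence([master_seed, window_length])`, so adding a window never
perturbs the draws of the others.

Root segments of a hypothetical deletion-spanning hairpin are the window
downstream of the start breakpoint and the window upstream of the end
breakpoint; the second is reverse-complemented before comparison, because a
hairpin stem pairs antiparallel strands. A literal base-wise-complement mode
is provided for comparison with analyses that describe the operation as
"conversion to the complementary sequence" without reversal.

Per-sample values are flagged by z-score against the null (tiers at |z| ≥ 2
and ≥ 3). The cohort-level test is Welch's two-sample t-test of patient
values against the null samples — the published analysis does not name its
test, so the choice is recorded in the output metadata, and a permutation
alternative is available behind a flag.

## Secondary-structure proxy

Breakpoint windows (100 bp, breakpoint at center) are folded by Nussinov
base-pair maximization: nested structures, Watson–Crick pairs (G·T wobble
off by default in a DNA duplex context), minimum hairpin loop 3 nt. A
thermodynamic free-energy model is intentionally **not** implemented: the
only downstream consumer is the loop/stem taxonomy of the breakpoint
position, which maximum pairing supports with a fully deterministic,
testable traceback (pairing preferred over leaving the leftmost base
unpaired; smallest admissible partner on ties). Consequences: pair counts
are exact against exhaustive enumeration, dot-bracket output is
reproducible, but predicted structures are not energy-optimal and
loop/stem fractions from this proxy are not comparable to
thermodynamic-fold results on real cohorts. Context taxonomy: a paired
breakpoint is STEM; unpaired and enclosed by a pair whose region contains
no other pair is HAIRPIN_LOOP; unpaired and enclosed otherwise is
BULGE_OR_INTERIOR; unenclosed is EXTERIOR. Both breakpoints of each
deletion are folded, so a 22-sample cohort contributes 44 contexts.

## Cohort statistics

The clustering scan reports both the maximum number of start points in any
half-open window of the configured width (default 500 bp) and the minimum
pairwise distance, because "no clustering below 500 bp" admits either
reading; both are checked against brute-force enumeration. Repeat content
clips annotations to the region and merges overlaps within a repeat class
so a base counts once per class; results are invariant to annotation order
and to splitting annotations. Breakpoint–element membership uses the base
at the breakpoint's 0-based start position (half-open tie-break). The
start-vs-end element contingency test is Fisher's exact test for 2×2
collapses and chi-square otherwise, falling back to a seeded permutation
of column labels when expected counts drop below 5; the report records
which test was used.

## Synthetic cohorts: what they emulate and what they don't

The generator plants deletions on one random contig with the junction
structure under the analyst's control: a right-anchored microhomology of
exactly k bp (the k bases after the start breakpoint are copied to the k
bases after the end breakpoint), or a 1–10 bp insertion copied from
reference sequence at a known offset from the start breakpoint. Guard bases
on the deleted side of each breakpoint are forced to mismatch, so planted
lengths are exact rather than lower bounds and round-trip recovery tests
can assert equality, not inequality. A 200-bp-per-flank junction consensus
is emitted for every call. The default mechanism mix is 8 NHEJ : 13 MMEJ :
1 AROR over 22 samples — the composition of the motivating patient cohort —
apportioned exactly by largest remainder and shuffled per seed.

Default geometry is desk-scale: deletion lengths 1–3 kb with ≥600 bp
spacing on a synthetic contig, versus tens to hundreds of kb in real
cohorts. Every junction-level analysis in the package depends only on
sequence within ≤200 bp of a breakpoint, so deletion size does not affect
the quantities under test; the distribution statistics scale trivially.
Sequence composition defaults to uniform (a genome-like AT-rich option
exists). The generator does not simulate reads, sequencing error, capture
bias, or repeat-element mosaics — so passing round-trip tests establishes
correctness of the junction arithmetic, not robustness to consensus errors
(which are out of scope by the exact-matching design above).

## Numerical and reproducibility choices

- All stochastic stages consume an explicit integer seed; cohort
  generation, the Monte Carlo null, and the full pipeline are
  byte-reproducible per seed (asserted in tests).
- Percentages use decimal round-half-up at one decimal everywhere.
- Monte Carlo defaults (10,000 pairs) run in seconds thanks to the batched
  DP; tests also exercise a 2,000-pair reduced mode.
- Degenerate inputs fail loudly: empty cohorts, zero-variance test groups,
  zero-SD nulls, all-`N` GC content, and unresolvable junction consensus
  sequences all raise typed exceptions rather than returning defaults.

## Known limitations

- Exact matching in junction resolution: a single consensus error near the
  junction shifts the reported microhomology/insertion; use error-corrected
  consensus sequences.
- The fold proxy ranks structures by pair count, not free energy; its
  loop/stem fractions should be interpreted only relative to this model.
- Mechanism labels are rule-based signatures, not probabilistic calls;
  junctions that genuinely arose by one pathway can carry another's
  signature by chance.
- Low-copy-repeat discovery and genome-scale repeat annotation are out of
  scope; repeat summaries require an externally produced RepeatMasker file.
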