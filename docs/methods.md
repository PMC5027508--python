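# Methods

## Nomenclature and the adenine position index

Alleles are written on the G-rich strand as `GmXGn` (first run of *m*
guanines, one interrupting base X ∈ {A, C, T}, second run of *n* guanines) or
`Gk` for a continuous tract. Parsing and rendering are a bijection on
canonical names; `reverse_complement_name` converts to and from the
polyC-T-polyC spelling of the printed reference strand (an involution).

The adenine position index describes where the interrupting base sits
relative to the tract midpoint:

```
position = 0                      if m = n
position = sign(m − n) · ⌈|m − n| / 2⌉   otherwise
```

Positive means the interrupt lies towards the 3′ end of the G-rich tract
(first run longer), negative towards the 5′ end. Zero is only attainable for
even total guanine counts; odd totals have no zero position and their
half-integer offsets are labelled by the next integer away from zero (so
G9AG6 → +2, G6AG7 → −1, G6AG9 → −2). Rounding away from zero is a
convention choice; it is isolated in `adenine_position` so an alternative
reading is a one-line change. It was retained because it reproduces every
worked value and the population-level groupings (the −1 group holding the
three dominant alleles, the −2 group dominated by 15-guanine tracts) that the
descriptive statistics rely on. The index is antisymmetric under swapping the
runs, which is property-tested over the full grid.

## Coordinates

User-facing positions are 1-based inclusive rCRS numbering; internal
intervals are 0-based half-open on the scanned strand. The variable tract is
rCRS 303–315 inside the 294–325 anchor window. Light-strand transcription
runs towards decreasing rCRS coordinates, so a transcript of length L from a
start site T ends at `T − (L − 1)`; a spacer of i nt inserted between the
tract and the downstream terminator increases the length needed to reach any
fixed downstream residue by exactly i. The TSS is deliberately a
configuration value (default nowhere hard-coded; the examples use 407), since
coordinate conversion should not silently assume a promoter position.

## Search-string library and scanning

One search string per candidate allele: `upstream flank + tract + downstream
flank`, with flanks taken from the packaged anchor configuration (reverse
complements of rCRS 316–325 and 294–302, with extension context out to rCRS
340/279). Because the upstream flank ends with a non-G base and the
downstream flank starts with one, no library string can occur inside another;
this is re-verified pairwise at build time and makes hit assignment
unambiguous. Matching is plain exact substring search — the survey's
100%-identity criterion treated as what it is operationally, an exact-match
engine; word size and e-value of the original BLAST configuration are
provenance, not behaviour.

Search strings must be at least `min_length` (default 25 nt, the minimum
query size of the original search). Short alleles (e.g. G1AG1, 22 nt with
the bare flanks) would violate this, so flanks are extended symmetrically
(alternating sides) from the packaged reference context until the shortest
library string meets the floor; the extension is applied uniformly to the
whole library and logged. Both strands are scanned by default and results
are always reported in G-rich nomenclature. Records with several loci are
counted per locus with a warning; `once_per_record` switches to strict
counting. An N anywhere in a candidate window simply prevents a match, and
the anchored classifier returns "complex" rather than guessing — imperfect
loci are never imputed.

The anchored run-length classifier (`classify_locus`) finds the flank pair,
run-length-parses the enclosed segment and accepts exactly the shapes `G^k`
and `G^m X G^n` (single-base interruption). It is deliberately an
independent code path from the library scanner; their agreement over the
whole 12×12×{A,C,T} + G1–G24 grid is an acceptance-level test.

## Survey statistics

- `totals_by_total_g` pools cells along anti-diagonals m + n = constant.
- `sample_skewness` defaults to the adjusted Fisher–Pearson estimator
  `N/((N−1)(N−2)) · Σ((x−x̄)/s)³` (the spreadsheet `SKEW` definition used in
  the original analysis); the plain moment estimator is available via
  `adjusted=False`. Both are cross-checked against
  `scipy.stats.skew(bias=...)` in the tests.
- `quadrant_counts` partitions cells around a pivot (default: modal cell) in
  (first-run, second-run) coordinates, *not* figure-panel orientation, which
  is stated in output headers. Cells sharing a coordinate with the pivot are
  reported separately (`on_axes`) and also folded into the inclusive quadrant
  totals, because "fraction in a quadrant" statements are ambiguous about the
  bisecting row/column; both tallies are always emitted.
- `position_spectrum` pools interrupted hits by adenine position.
- `cumulative_tp_curve` orders occupied alleles by ascending TP% and
  accumulates hit fractions; alleles missing from the TP table are excluded
  with a warning, never imputed. The packaged TP table ships only values
  printed as numbers in the running text of the source study, each with a
  provenance string; heat-map-only values are not transcribed.

## Densitometry

"First-order Lagrange curve" calibration is implemented as piecewise-linear
interpolation between adjacent ladder knots — a single global line cannot
pass through more than two bands of a 25 bp ladder; a global least-squares
line remains available (`fit_ladder_global_line`) for sensitivity checks.
Beyond the knot hull the edge segments are extended linearly and flagged.

TP% is the density over pixels whose calibrated length falls in the TP window
(default 92–140 nt) as a percentage of the total lane density from the well
down to the ~100 nt marker. Since the window's lower edge (92 nt) lies just
below that marker, the effective total-window cutoff is
`min(lower_cutoff, tp_lo)` so the numerator is always a subset of the
denominator. Whether the marker pixel itself and the well material count
towards the total are explicit toggles (defaults: both included), because
the original procedure does not state either. Background subtraction is not
applied by default (none is described in the source procedure); a rolling
minimum option exists.

Peak calling uses `scipy.signal.find_peaks` with a prominence threshold
expressed as a fraction of the lane maximum, refined to sub-pixel accuracy by
a three-point parabolic fit, then mapped to lengths and (given a TSS) to rCRS
3′-end positions. With the 25 bp ladder, piecewise-linear calibration of the
logarithmic migration model carries a curvature error of up to ~0.3 nt
mid-segment; tests assert planted-band recovery at 0.5 nt with the coarse
ladder and at 0.1 nt with a 5 nt knot spacing, which demonstrates the error
source is ladder curvature, not the peak caller.

## Synthetic data: what it emulates, and what it does not

`simulate_survey` emulates a public-database download of mtDNA control
regions: each record either lacks the locus entirely (default 25%, standing
in for partial submissions such as HV1-only fragments) or carries an allele
drawn from the spectrum, embedded in the reference anchor context with random
flanking sequence; records are emitted on either strand (default 50/50).
The default spectrum is the four dominant discontinuous alleles
(G6AG7 0.40, G6AG8 0.35, G5AG7 0.15, G6AG9 0.10). Noise models are a
per-base substitution rate outside the locus footprint and a ±1
run-length slippage applied per G-run (the characteristic failure mode of
sequencing homopolymers); slippage is applied before truth is recorded, so
ground truth always describes the emitted sequence. Defaults for both noise
rates are 0 (the survey round-trip condition); they exist to study
robustness, and raising slippage demonstrably smears matrix mass to adjacent
cells symmetrically.

Not emulated: read-level error models (quality scores, chromatograms),
haplogroup covariance between the tract and the rest of the molecule, real
database redundancy (duplicate submissions of one individual), and
non-reference flanking variation that would defeat exact matching — the
original search itself notes such hits are overlooked. Passing round-trip
tests therefore shows the pipeline is correct on its own terms, not that the
exact-match strategy is unbiased on real archives.

`simulate_gel` renders Gaussian bands through `pixel = a + b·ln(length)`
(b < 0; defaults a = 1300, b = −200 over 700 pixels, placing 25–300 nt
inside the lane) with band width given in nt and converted through the local
slope |b|/length; the ladder is rendered noise-free through the same model.
Wet-lab TP percentages cannot be recomputed from sequence, so the
densitometry acceptance surface is recovery of planted quantities from
synthetic lanes, never biochemical values.

## Determinism and problem sizes

All stochastic steps consume a single `numpy.random.default_rng(seed)`
threaded through the generator specs; re-running any command with the same
config and seed is byte-identical. The shipped tests use problem sizes a
desk check warrants: 2,000-record surveys for spectrum recovery (class
fractions asserted against exact binomial 99% intervals), the full
456-string grid for scanner/classifier equivalence, 1,000 random vectors for
the skewness oracle, and 700-pixel lanes for densitometry.

## Known limitations

- Exact matching only: a SNP inside the flank window hides a locus, as in the
  original strategy; the anchored classifier relaxes this only to the flank
  sequences themselves.
- The quadrant and skewness summaries describe one interrupting base at a
  time (A by default); cross-base pooling is available only through
  `totals_by_total_g` and `position_spectrum`.
- Circular-record scanning handles the origin junction but assumes the locus
  appears at most once per junction copy.
- The packaged anchor context covers rCRS 279–340; scans with much larger
  `min_length` values will exhaust the extension context and fail loudly
  rather than invent sequence.
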