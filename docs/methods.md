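# Methods

## The measurement model

`ptrcat` treats a polymorphic tandem repeat (PTR) call as a comparison
between two assembled haploid-consensus sequences: a reference locus and the
segment of a target assembly enclosed by the same flanking sequence. There is
no read-level or genotype-likelihood model; heterozygosity is out of scope by
construction, as each assembly contributes one consensus allele.

### Locating the locus

A repeat sequence is a poor anchor — it is rarely unique and its length is
exactly what varies — so each reference TR is located on a target by its two
flanks of up to 250 bp (a size that balances placement specificity against
sensitivity to incidental SNPs/indels in the flank). Flank hits come from a
Smith–Waterman local alignment (+1/−1/−1, linear gaps) vectorised row-wise
in numpy. A placement is accepted only when:

* each flank has exactly one qualifying hit — identity ≥ 90% over alignment
  columns, within 5% of the best hit's score (two near-best hits mean a
  segmental-duplication-style ambiguity and the locus is rejected as
  MULTI_MAPPED);
* the left hit precedes the right hit;
* the two hits together match ≥ 90% of the available flank bases
  (450 of 500 for full flanks; scaled proportionally when a flank is clipped
  at a sequence end).

The enclosed segment runs between the flank extremities *extrapolated to the
full flank extents*: a substitution at the flank base adjacent to the repeat
would otherwise be trimmed by the local alignment and shift the repeat
boundary by a base. A zero-length segment (flanks adjacent) is a legal
placement meaning complete loss of the repeat, measured as Δ = −units_ref.

### Measuring the change

With S the shorter and T the longer of (reference TR, enclosed segment),
n = |S|, m = |T|, the Sellers evolutionary distance H() is a unit-cost edit
distance with a leftmost-truncation rule (unequal strings are aligned on
their first symbol and the longer is truncated). Test 1 requires
H(S, T(1,n)) ≤ k, k = ⌊0.1·n⌋; Test 2 requires H(S, T(n+1,m)) ≤ k′,
k′ = ⌊0.1·min(n, m−n−1)⌋. The k′ formula is used verbatim although the
residual has length m−n, not m−n−1; the off-by-one only tightens the budget
by at most one unit near the boundary. Failing either test forces quality
low.

Unit counts come from match counting, not sequence length, so alignment gaps
do not over-count: units of the longer string = round((matches₁ +
matches₂)/motif size), rounding half away from zero. When the residual is
longer than S, the second alignment cannot cover it after truncation (it
would cap measurable expansion at 2n), so alignment 2 is iterated over
successive length-n chunks of the residual and the matches summed; for
residuals shorter than S — the dominant case, as most deltas are within a
few units — this is exactly one alignment of the truncated pair. On the
contraction side the target is the fully matched prefix and its units are
matches₁/motif size. Fractional motif sizes from fuzzy detectors are used
unrounded in the divisor. Equal-length pairs are non-polymorphic by
definition: substitution-only variation is not a repeat-number change.

### Grading (Test 3)

Let S₁/T₁ and S₂/T₂ be the matched spans of the two alignments (highest
score, leftmost on tie — the traceback prefers diagonal, then query-gap
moves). **high**: T₁ and T₂ adjacent and S₁, S₂ overlapping. **medium**: a
small gap between T₁ and T₂ — one motif length by default, configurable;
one unit of drift is the natural tolerance — with S₁, S₂ still overlapping,
and, for motifs ≤ 4 bp with a second alignment shorter than 8 bp, more than
half of the shorter aligned string matched (tiny second alignments of small
motifs match by chance too easily otherwise). Everything else is **low**,
and low-quality measurements never enter the catalog.

When one TR maps to several target loci (overlapping reference transcripts
can map apart in a target), measurements are ranked by quality class, then
decreasing |Δ|, then leftmost position, and the top measurement is the
locus's value. A TR is cataloged when that best measurement is high/medium
with Δ ≠ 0; each genome's own best measurement decides per-genome
attribution.

## Candidate consolidation

Inputs from several detectors are merged by exact identity on (interval,
motif, unit count), unioning tool provenance. Finishing filters flag:
≥ 10 consecutive N in the locus; motif size 1; duplicate spans (identical
nucleotides, different parameters — the candidate whose motif×units best
predicts the span survives, smaller motif on tie); and spurious detector
output, defined here as unit count < 2 or a motif matching the locus below
50% identity in every cyclic frame (a declared heuristic — detectors do not
agree on what "spurious" means). Heavily overlapping survivors are removed
iteratively: if two TR overlap by more than 50% of the shorter's size
(configurable to require both members), the shorter — on a size tie, the
larger-motif — candidate is removed; pairs are processed by decreasing
overlap fraction with leftmost tie-breaks so the fixed point is
deterministic.

## The built-in detector

A seed-and-extend scanner stands in for external TR discovery tools so the
pipeline runs end to end: a seed is an exact adjacent doublet of a candidate
motif (period 2–100); extension proceeds unit by unit, scored +1 per
matching and −2 per mismatching base so that units with more than one third
mismatches score negative and random flanking sequence is not absorbed; the
chosen end maximises the score subject to a global mismatch budget of
⌊0.15·span⌋ (per-unit budgets cannot reproduce the 21-nt worked example,
whose accepted units carry 1-in-3 mismatches). Harmonic calls (period a
multiple of a smaller period over the same span) are suppressed. Because the
seed is the first exact doublet in scan direction, output legitimately
depends on direction — which is why merged regions are kept per strand.
The detector makes no claim of item-for-item agreement with TRF or mreps and
does no statistical significance scoring.

## The fixture generator

`simulate` builds reference/target pairs with a planted, known truth. The
repeat is mutated **once** — at 3% per unit by default, one substitution per
affected unit — and shared by reference and target, which then differ by
the planted delta (pristine motif copies appended to, or units removed from,
the repeat's end) plus target-only flank noise: 1% per-base substitutions by
default, optional single-base indels, and an optional target-only per-unit
divergence (default 0). This shared-ancestry model mirrors two assemblies
descending from one haplotype; mutating the two repeat copies independently
would instead model deep divergence and systematically bias match-based unit
counts low. Flank background is i.i.d. uniform DNA; options plant an
N-stretch (to exercise the N filter) or a duplicate left flank (to exercise
MULTI_MAPPED).

What passing tests on these fixtures does **not** show about real data:
uniform random flanks have no genome-scale repeat structure or segmental
duplications, so real placement ambiguity rates will be higher; indels are
single-base; there is no heterozygosity or assembly error model.

## Statistics utilities

Catalog comparison counts source entries with a Jaccard-threshold match in a
target catalog; "above a threshold j" is strict (>), except j = 1.0 where ≥
is used, else identity could never match. PTR/TR ratios per (motif-size,
unit-count) stratum carry percentile-bootstrap 95% CIs over resampled loci
(≥ 100 replicates, seeded; the interval is widened to contain the point
estimate in degenerate resamples). The SNP correlation tiles analysed
regions with non-overlapping windows (5–50 kb, left-aligned, partial
trailing windows dropped), correlates per-window mean reference unit count
of cataloged PTR with per-window SNP count by Spearman's ρ (average ranks on
ties, large-sample p-value), and requires ≥ 3 non-empty windows. Only the
unit-count property is correlated; windows without a PTR are skipped since
their mean is undefined.

## Numerical and scale choices

* Internal coordinates are 0-based half-open; TRF `.dat` and catalog TSV are
  1-based inclusive at the boundary only; BED stays 0-based.
* Dynamic programs are row-vectorised; the left-neighbour dependency is
  resolved with a cumulative min/max pass, and exact string equality
  short-circuits to the trivial alignment.
* Rounding is half away from zero everywhere a unit count is rounded.
* Test problem sizes: the recovery study uses 1,000 fixtures with deltas in
  [−5, 5] \ {0} plus 500 null fixtures (motifs 2–6 bp, 8–30 units, 400 bp
  flanks); the pure-repeat sweep covers motifs 2–20 bp and unit counts 2–40
  exhaustively; distance oracles are checked on 10,000 random short pairs.
  These sizes were chosen to estimate the ≥ 95% recovery criteria with
  sub-percent resolution while keeping the suite quick on a laptop.

## Known limitations

* Expansion measurement beyond 2× relies on the chunked second alignment;
  quality grading still uses only the first chunk's spans.
* The 450-of-500 combined rule can only fail independently of the 90%
  identity gate when hits are clean but short (eroded flank images); with
  full-length noisy flanks the two gates nearly coincide.
* Linear gap costs (+1/−1/−1) let local alignments chain short spurious
  match runs through unrelated sequence, mildly inflating match counts at
  degraded flank ends; affine gaps would sharpen this at the cost of
  departing from the measurement's stated weights.
* `iterative_overlap_removal` is quadratic per pass and intended for
  per-region candidate sets, not whole-genome lists in one call.
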