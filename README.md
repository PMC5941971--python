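# ptrcat

Tools for building catalogs of **polymorphic tandem repeats (PTR)** from
assembled genomes.

A tandem repeat (TR) is a stretch of DNA in which a motif of 2–100 bp repeats
back to back. A TR locus is *polymorphic* when the number of repeat units in
an individual's assembly differs from the reference genome — the class of
variation behind repeat-expansion diseases (Huntington disease, many ataxias)
and a workhorse of forensics and population genetics. `ptrcat` is aimed at
researchers compiling locus catalogs to guide downstream genotyping of short
(STR) and long (VNTR) repeats alike: it consolidates TR candidates on a
reference, anchors each locus on target assemblies by its flanking sequence,
and measures the unit-count change with an alignment-based procedure,
emitting a deduplicated, provenance-annotated catalog plus comparison and
summary statistics.

## Method

For a reference TR sequence *S* (|S| = n) and the corresponding target locus
*T* (|T| = m), oriented so that *S* is the shorter, let *H*() be the Sellers
evolutionary distance: a unit-cost edit distance computed by a
Needleman–Wunsch dynamic program, where unequal-length strings are aligned
on their leftmost symbol and the longer is truncated to the shorter's length.
Two tests decide whether the pair is a credible copy-number variant of one
locus:

* **Test 1** (shared prefix): H(S, T(1, n)) ≤ k with k = ⌊0.1·n⌋
* **Test 2** (residual continues the repeat): H(S, T(n+1, m)) ≤ k′ with
  k′ = ⌊0.1·min(n, m−n−1)⌋

The target's unit count is the rounded ratio of the matched bases in the two
alignments (scored +1 match, −1 mismatch, −1 gap) over the motif size, and
Δ = units_target − units_ref (positive = expansion). A third test grades each
measurement **high / medium / low** from the mutual consistency of the two
alignments' matched spans (adjacency on *T*, overlap on *S*); only high and
medium measurements with Δ ≠ 0 enter the catalog.

Upstream of the measurement: overlapping same-strand transcripts are merged
(opposite strands stay separate, because seed-based TR detectors are
direction sensitive), candidate lists from multiple detectors are
consolidated (exact dedup, N-stretch / single-base-motif / duplicate-span /
spurious filters, iterative >50%-overlap removal), and each TR is located on
a target by uniquely aligning its two 250 bp flanks (identity ≥ 90% per
flank, ≥ 450 of 500 bases matched combined, unique and correctly ordered
hits).

## Worked example

The direction-sensitivity example sequence `ATT ATT ATC ATC ATT ATT ATC`
differs from seven exact copies of its consensus motif `ATT` at exactly
three positions:

```python
>>> import ptrcat
>>> ptrcat.evolutionary_distance("ATTATTATCATCATTATTATC", "ATT" * 7)
3
>>> [c.unit_count_ref for c in ptrcat.detect_tandem_repeats("ATTATTATCATCATTATTATC")]
[7.0]
>>> [c.interval.length for c in ptrcat.detect_tandem_repeats(
...     "ATTATTATCATCATTATTATC", direction="right_to_left")]
[18]
```

Scanned left to right the whole 21 bp string is one TR of 7 units; scanned
right to left the seed lands differently and one unit is dropped — the
reason the pipeline never merges transcripts across strands.

A full measurement on a synthetic locus:

```python
>>> from ptrcat import (FixtureSpec, make_fixture, extract_flanks,
...                     place_flanks, measure_polymorphism)
>>> t = make_fixture(FixtureSpec(motif="CAG", units_ref=10, delta_units=2,
...                              seed=1))
>>> tr = t.reference_candidate()
>>> pl = place_flanks(extract_flanks(tr, t.reference_sequence),
...                   t.target_sequence)
>>> pl.status, len(pl.target_sequence)
('PLACED', 36)
>>> m = measure_polymorphism(tr, pl)
>>> m.delta_units, m.units_target, m.quality, m.matches_aln1, m.matches_aln2
(2, 12, 'high', 30, 6)
```

The CAG×10 reference locus is found expanded to CAG×12 in the target
(Δ = +2): 30 bases match in the first alignment, 6 in the second, and
36/3 = 12 units, graded high quality because the two matched segments are
adjacent on the target and overlap on the reference.

The same pipeline is available from the shell:

```bash
ptrcat simulate --motif CAG --units 15 --delta 3 --seed 4 -o fix
ptrcat detect fix.ref.fa --max-motif 10 -o trs.tsv
ptrcat measure fix.ref.fa trs.tsv fix.target.fa -o catalog.tsv
ptrcat stats catalog.tsv
```

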