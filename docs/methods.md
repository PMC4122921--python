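# Methods

## Model

The estimator assumes approximately even sequencing coverage across the
genome: the expected number of fragments overlapping a locus is proportional
to the number of genomic copies of that locus times its length. Conserved
single-copy housekeeping genes (CEGMA-like) anchor the depth of unique
sequence; the ratio of a repeat superfamily's pooled FPKM to the median
housekeeping FPKM estimates the average copy-number inflation of that
superfamily's assembled loci, and multiplies the assembled base pairs into a
corrected content estimate. Working at superfamily level (not per element)
assumes superfamilies are divergent enough that reads rarely cross-map between
them, while elements within a superfamily may.

### Counting contract

* Best-hit, end-to-end placements only; each fragment appears at most once.
* A fragment overlapping (≥ 1 bp) intervals of exactly one feature increments
  that feature; several intervals of one repeat ID count once; overlap with
  two or more distinct features makes the fragment ambiguous and it is
  discarded from feature counts (union-style counting; an
  intersection-strict mode is deliberately not offered).
* FPKM(f) = count(f) / (length(f)/1000) / (aligned/10⁶). "Aligned" means
  aligned fragments (assigned + ambiguous + no-feature), not raw reads.
* The TE read fraction keeps ambiguous and featureless fragments in its
  denominator — they are aligned reads — and unaligned fragments out of it.

### Scaling factor

Two numerator readings are provided. `length_weighted` (default) pools the
superfamily: (Σ counts / Σ length in kb) / (aligned/10⁶). This is the
copy-number-consistent estimator: splitting one consensus into two repeat IDs
does not change it. `literal_sum` adds the per-repeat-ID FPKMs instead; it
grows with the number of repeat IDs and is retained as a switch for
comparison with sum-over-elements conventions. With `floor_at_one` (default)
S_t is floored at 1, because assembled copies are a lower bound on true
content; the pre-floor value is always reported alongside (it is the
diagnostic for hemizygosity, where it sits near 0.5).

The corrected genome size is the non-TE assembled bp plus the summed
corrected TE bp, and all corrected fractions are taken against it. How
per-superfamily corrections combine into one genome-level percentage is a
design choice of this package; it has the property that a fully assembled
genome is returned unchanged.

### Boundary effects

Under the ≥ 1 bp overlap rule a feature of length F also captures fragments
straddling its boundaries, inflating its count by roughly (L−1)/F relative to
L-fragment tiling. Housekeeping spans (1.5–3 kb) are shorter than TE consensus
loci (≈ 5–6.6 kb), so the inflation is larger for genes and the pre-floor S_t
in a fully assembled genome sits deterministically just below 1 — the floor
returns exactly 1. Conversely, copies deleted by collapse lose their
boundary-straddling fragments (those span assembly breakpoints and cannot
align end-to-end), so a ten-fold collapsed family yields S_t slightly below
10 (≈ 9.92 at L = 10 bp, F = 5 kb). Both effects shrink linearly with the
fragment length and are second-order at realistic L/F ratios.

## Synthetic data

The generator emulates exactly the features the estimator depends on:

* **Genome**: i.i.d. random background plus TE families, each a random
  consensus with `copy_number` copies independently substituted at rate
  `divergence` per site (length-preserving; no indels). Copies and ≥ 50
  multi-exon gene models are placed uniformly without overlap (spacings
  construction, minimum gap 200 bp by default) — infeasible requests fail
  immediately as "genome overfull".
* **Collapse**: within each family, copies are grouped by single-linkage on
  pairwise identity ≥ the threshold (default 0.97, matching the chaining
  behaviour of k-mer assemblers on near-identical repeats). Identity is
  computed exactly from the substitution records, not by realignment. One
  representative (the left-most copy) is retained per group; the other loci
  are deleted and the sequence splits into separate scaffolds at every
  deletion breakpoint.
* **Fragments**: `exact` tiling places n = coverage·G/L fragment starts on a
  regular grid; `sampled` draws starts uniformly. The genome is treated as
  circular for fragment generation, which makes the even-coverage assumption
  exact under tiling (no edge ramp); origin-wrapping fragments are clipped at
  the scaffold end (single-scaffold assemblies) or unaligned (they would span
  a scaffold junction). Fragments from deleted copies are placed on their
  group representative; fragments spanning deletion breakpoints are emitted
  unaligned. In `hemizygous_te` mode, fragments whose midpoint falls in a
  flagged copy are emitted at half rate (alternating under exact tiling,
  Bernoulli(½) under sampling), with the removed half reported unaligned so
  the fragment-conservation identity stays exact.
* **Truth**: per-family copy numbers, per-superfamily bp and fractions, and
  the collapse map (every copy → its representative; representatives map to
  themselves).

All randomness derives from one master seed through named
`numpy.random.SeedSequence` child streams (consensus, placement, background,
mutation, hemizygosity, fragments), so runs are bit-reproducible.

What the simulator does **not** model: sequencing errors and quality,
GC/PCR bias, paired-end insert-size structure, indel divergence, nested or
truncated insertions, and real assembler behaviour. Passing recovery tests
therefore demonstrates the estimator's correctness under its own assumptions
(even coverage, best-hit placement, clean annotations), not robustness to
those additional artifacts of real libraries.

### Reference scenarios (`tedepth.scenarios`)

Problem sizes are chosen so each scenario is informative at desk scale:

* `calibration` — 2 Mb genome (1.4 Mb background + 3 superfamilies × 40
  copies × 5 kb at divergence 0.03, pairwise identity ≈ 0.94: nothing
  collapses), exact 30× tiling with 30 bp fragments. Expected: S_t exactly 1
  everywhere, corrected ≡ assembled.
* `collapsed_decade` — 95 kb background + 10 identical 5 kb copies, exact 10×
  tiling, 10 bp fragments, 50 genes of 1.2–1.5 kb. Expected: assembled 5.0 %,
  S_t ≈ 9.9, corrected within 0.5 points of the true 34.5 %.
* `stochastic` — 3.25 Mb background + per superfamily one young family
  (73 copies, divergence 0.004 — always collapses to one representative) and
  one old family (44 copies, divergence 0.05 — never collapses): true TE
  fraction ≈ 35 % with 5/8 of copies collapsible, sampled 30× coverage,
  100 bp fragments. Expected: TE read fraction within 3 points of truth,
  corrected fraction within 15 % relative, assembled fraction at least
  two-fold below truth.
* `hemizygous` — 0.7 Mb genome, every TE copy on one haplotype only, genes on
  both haplotypes assembled once, exact 30× tiling. Expected: pre-floor
  S_t ≈ 0.5, TE log2 relative coverage ≈ −1.

## Annotation handling

* **Overlap resolution** processes hits best-first (percent identity, then
  score, then length, then repeat ID — the ladder beyond identity exists only
  to make ties deterministic) and lets each hit claim the bases not already
  claimed. Losers are trimmed to their non-overlapping remainder; contiguous
  remainders shorter than 80 bp (echoing the 80-80-80 floor) are dropped from
  the output but still shadow their interval against worse hits — this is
  what makes "the retained annotation at any base is the best input covering
  it" a theorem rather than a heuristic. A `trim=False` mode drops overlapped
  losers whole. The operation is idempotent.
* **Pairwise identity** uses local (Smith-Waterman) alignment — standard for
  truncated repeat copies — with match +1, mismatch −1, gap open −2, extend
  −1. Identity is matches over alignment columns; coverage is the aligned
  span on the *shorter* sequence over its length (the "80 % of the sequence"
  clause is read against the shorter sequence, the query-fraction
  convention). Both strands are tried.
* **Clustering** is greedy centroid: elements longest-first, each joins the
  first (oldest) family whose representative satisfies all three thresholds,
  else founds a family. Determinism comes from the fixed ordering (length
  descending, ties lexicographic). The representative is the founder, hence
  always a longest member.

## Phylogeny

Maximal monospecific clades are the deepest nodes whose leaf set is
single-species while the parent's is not; they are pairwise disjoint and
partition the leaves (asserted on every call). Multifurcations are allowed: a
multifurcating node is monospecific iff all children are. Input trees that
arrive unrooted (trifurcating root) are midpoint-rooted when branch lengths
exist, unless an outgroup species is given, in which case the tree is rooted
at the outgroup's stem edge. No bootstrap-support filtering is applied.

## Known limitations

* The correction assumes the assembled representative is a faithful consensus
  of its collapsed copies; highly diverged copies that still cross-map in
  real data would violate the superfamily-specificity assumption.
* Coverage unevenness (GC bias, library artifacts) feeds directly into S_t;
  the housekeeping median absorbs genome-wide shifts but not locus-specific
  bias.
* The hemizygosity scenario treats haplotype structure as a per-copy flag;
  how often heterozygous insertions assemble onto one versus two scaffolds in
  real dikaryons is unknown, so the hemizygous fraction is a free simulation
  parameter, not a calibrated one.
* Indel-free divergence makes within-family identity computable exactly from
  substitution records; real copies also diverge by indels and truncation,
  which would lower alignment coverage before identity.
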