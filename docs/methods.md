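# Methods

## In-silico PCR-RFLP

**Primer search.** Primers are matched IUPAC-aware on both strands: a
position matches when the base sets denoted by the two codes intersect,
and at most `max_mismatch` positions may fail. The amplicon runs from
the first base of the forward-primer hit to the last base of the
reverse-primer hit (primers included), which is the convention under
which the diagnostic COI product is 866 bp. When several hit pairs
exist, the pair whose product length is nearest the expected length
wins. Primer sequences are never hardcoded — they are configuration —
and a sequence that is already exactly the expected length passes
through flagged `pre_cut`, so pipelines can run on pre-trimmed amplicons
without primer knowledge.

**Digestion.** An enzyme is a recognition string plus a plus-strand cut
offset (ApoI: `RAATTY`, offset 1, i.e. R^AATTY). Cut positions are
reported as 1-based prefix lengths (bases 5′ of the cut), fragments as
the successive differences including both end pieces; this reproduces
the published fragment arithmetic exactly (252 + 44 + 266 + 92 + 212 =
866 for the MEDQ1 pattern). Double-strand overhangs are ignored.
Overlapping recognition matches each contribute a cut; duplicates
collapse. Ambiguity codes are handled by decidability: a window that
matches under every expansion cuts, one that matches under some but not
all expansions raises a digestion error naming the position, and one
that matches under no expansion is ignored.

**Classification.** Three match modes: `cut_set_exact` (identical cut
sets; the default for sequence-derived digests), `fragment_multiset`,
and `gel_visible_fragments`, which discards fragments shorter than
`gel_min_visible` from both the digest and the pattern before comparing
— emulating what a gel shows. The default `gel_min_visible` is 25 bp,
chosen because the smallest diagnostic fragment known to be invisible on
a 2% gel is 18 bp and the smallest visible one is 44 bp; any threshold
in (18, 44] behaves identically on the MED library. A label is assigned
only on a unique distance-0 match; ties report both candidates and
classify as `unclassified`. The built-in library carries the three MED
patterns (MEDQ1, Sardinian MEDQ1, MEDQ2); a MEAM1 pattern is not
published alongside them and must be supplied via configuration.

## Synthetic populations

The generator emulates the genetic structure of a typed field survey;
it is how the test suite exercises every stage without external data.

**Templates.** A template is a uniform-random ACGT sequence into which
one concrete realisation of each requested recognition site is planted;
a repair loop re-randomises bases of any spurious site (outside planted
footprints) until digestion yields exactly the requested cut set.
Uniform base composition is used because no downstream statistic in
scope depends on composition. `derive_template` produces a sister
template at a configurable divergence (default 2%/site, a realistic
intra-species mitochondrial haplogroup distance) carrying a different
cut set, for cross-haplogroup tree and network checks.

**Populations.** Haplotype 0 is the template; each further haplotype
carries its own private substitutions at positions drawn without
replacement from the non-site, non-primer interior. Consequently the
distance between haplotypes i and j is exactly mᵢ + mⱼ (a star
genealogy), and both Hd (a function of the frequency vector only) and π
(a function of frequencies and mutation counts) are analytically exact
per dataset, not merely in expectation. Mutations avoid recognition
sites by default so every specimen retains its haplogroup's RFLP
pattern; a config flag can disable this. Each specimen sequence is
flank + amplicon + flank (default 100 bp flanks); the primer pair is
the amplicon's first/last 20 bp, so the PCR stage is exercised end to
end. Seeding: one master seed spawns per-haplotype child streams, so
output is byte-identical for a given config + seed.

**Solvers.** `frequencies_for_target_hd` enumerates all h-part
partitions of n (exact, for n ≤ 60; hill-climbing beyond) and returns
the composition whose exact Nei Hd is nearest the target.
`mutations_for_target_pi` assigns integer per-haplotype mutation counts
by round-robin increments until the implied π is as close as possible to
the target — round-robin keeps the load even, preserving the star shape.

**Presets.** The MEDQ1-like preset (n=31, h=13, target Hd 0.908, target
π 0.004/site over 866 bp) and MEDQ2-like preset (n=23, frequencies
19/3/1 — the 3-part composition of 23 whose exact Hd, 0.3123, is nearest
0.312 — target π 0.0004) encode the survey structure the generator
emulates. What the generator does *not* emulate: transition/transversion
bias, codon structure, indels, recombination (absent in mtDNA anyway),
back-mutation and homoplasy. Passing tests therefore demonstrate correct
*arithmetic* on realistic structures, not robustness to every feature of
real chromatogram-derived data.

## Population genetics

All statistics operate on equal-length sequences under an explicit
column policy. Default `complete_deletion`: a column is used only if
every sequence has an unambiguous base there (the common DnaSP default);
`pairwise_deletion` restricts per pair. Which policy a published DnaSP
run used is usually unstated, so the policy is switchable and reported.

- **Hd** (Nei 1987): n/(n−1)(1 − Σpᵢ²); SD from Nei's sampling variance
  V = 2/(n(n−1)) {2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²}.
- **π**: mean proportion of differing used sites over all pairs; SD from
  the no-recombination variance V(π) = (n+1)π/(3(n−1)L) +
  2(n²+n+3)π²/(9n(n−1)).
- **Tajima's D** (Tajima 1989): standard a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂
  constants; D = (θ̂π − S/a₁)/√(e₁S + e₂S(S−1)). Undefined (reported as
  `None` with a note, never 0) when S = 0.
- **Fu's Fs** (Fu 1997): θ̂ is the mean number of pairwise differences
  per sequence (θ̂π, *not* per site — the estimator DnaSP uses);
  S′ = Pr(K ≥ k_obs) under the Ewens sampling formula,
  Pr(K=k) = |s(n,k)| θᵏ / Π(θ+i); Fs = ln(S′/(1−S′)). Stirling numbers
  |s(n,k)| are exact Python integers from the triangular recurrence
  (`math.log` accepts arbitrary-precision integers, so log-space
  evaluation is exact-up-to-float); the test suite cross-checks them
  against coefficients of the rising factorial polynomial and the
  distribution against exact fractions. Undefined when there is no
  variation.
- No p-values for D or Fs are computed: published values come from the
  analysis package's internal tables, and coalescent-simulation p-values
  are out of scope here.

## Median-joining networks

Following Bandelt, Forster & Röhl (1999): (1) restrict to segregating
columns; (2) build the ε-relaxed minimum-spanning network — an edge
(u,v) is admitted when d(u,v) ≤ bottleneck(u,v) + ε, where the
bottleneck (minimax) distance comes from an MST, which at ε = 0 yields
exactly the union of all MSTs; (3) from every connected node triple,
compute the per-column majority (median) vector — where all three states
differ, the state of the first node in processing order is kept; (4) add
the candidate median that most reduces the minimum spanning cost over
the node set (lexicographic tie-break) and iterate; each accepted median
strictly decreases an integer cost, so the loop terminates; (5) prune
median nodes of degree ≤ 2 that lie on no Hamming geodesic between
observed nodes. ε defaults to 0 (the common drawing-tool default; the
source surveys rarely state it). Determinism everywhere by lexicographic
sequence order. Observed nodes carry specimen counts and optional trait
(e.g. region) compositions; medians have size 0. Exports: GraphML
(lossless round trip), NEXUS with a PopART-style Traits block, TSV edge
list. An optional edge-cut grouping (components after removing edges
heavier than a threshold) is provided as a labelled convenience; it is
*not* the hand-drawn group annotation seen in published figures.

## Distances and trees

TN93 uses the closed form with empirical base frequencies from the
pooled pair and separate A↔G / C↔T transition classes. Gamma rate
heterogeneity is deliberately not implemented; likewise ML inference,
bootstrap and model selection are out of scope — the tree stage exists
to check that haplogroups form coherent clusters, and full ML tree
engines are mature external tools. Saturated pairs (non-positive log
argument) return NaN with a warning; matrix construction turns that into
a data error. Neighbor-joining is the standard Saitou–Nei agglomeration
with a trifurcating root, Q-criterion ties broken by label order,
negative branch lengths clamped to 0 with a log note, and an all-zero
matrix returning a star tree in label order. On additive matrices leaf
path lengths reproduce the input to 1e−9 (tested, including against an
independent library implementation).

## Pipeline

`run_pipeline` validates its configuration (unknown keys rejected),
joins FASTA to metadata, extracts/digests/classifies, computes per-label
statistics, builds the focal-label network (most frequent label by
default) and a pooled NJ tree, and writes a composition summary plus a
JSON manifest (config echo, version, seed, per-stage counts). Specimen
conservation — n(input) = n(classified) + n(failed) — is asserted.
Stage failures are recorded per specimen (extraction/digestion) or per
stage (network/tree) and flagged in a `FAILED` marker file; the pipeline
continues. Percentages in reports are printed to one decimal place.

## Problem sizes and tolerances

Test fixtures use the preset population sizes (n = 31 and 23, 866-bp
amplicons), 200-bp sequences for digestion-oracle sweeps (1,000
replicates), Ewens distributions up to n = 200, and 100 generator seeds
for the emulation-recovery check — sizes chosen to exercise every code
path at the scale the statistics are actually used, while keeping the
default suite fast. Exact-fraction oracles are matched to 1e−12;
distance/path reconstructions to 1e−9/1e−10.

## Known limitations

- Classification is only as good as the pattern library; patterns absent
  from it (e.g. MEAM1, whose ApoI pattern is published elsewhere) must be
  supplied via configuration or specimens report `unclassified`.
- The Fs implementation follows the Ewens-based definition; for very
  large θ and n the tail probability S′ can underflow toward the (0,1)
  boundary, in which case Fs is reported undefined rather than ±inf.
- The median-joining implementation documents its exact median rule
  (first-node state on three-way ties) rather than reproducing any one
  drawing tool's refinements (e.g. quasi-median steps); published network
  topologies built with unstated settings are therefore not an exactness
  target.
- `pairwise_deletion` haplotype collapsing compares each sequence to
  group representatives; with heavy ambiguity the relation is not
  transitive and grouping is first-fit. Complete deletion (the default)
  has no such caveat.
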