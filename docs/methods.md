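# Methods

This note records the models behind `pinemap`, the defaults and why they
hold, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Pedigrees and segregation model

Two pedigree types are modelled. A **CP cross** is a full-sib family of
two outbred parents with unknown linkage phases; each SNP is one of
three JoinMap-style segregation types: `lmxll` (heterozygous seed
parent, 1:1 in calls `ll`/`lm`), `nnxnp` (heterozygous pollen parent,
1:1, `nn`/`np`) and `hkxhk` (both parents heterozygous, 1:2:1,
`hh`/`hk`/`kk`). An **F2** is the selfed progeny of a single
heterozygous F1; all markers are codominant with calls `a`/`h`/`b`.
Missing data is `--` (CP) or `-` (F2); readers also accept `.`.

The genotype file dialect (header `name`/`popt`/`nloc`/`nind`, one locus
block per marker, CP loci tagged `<code>`) follows the JoinMap `.loc`
convention. The exact convention is a documented choice of this
package, not something the file format itself pins down; the writer is
canonical so write∘read round-trips byte-identically.

## Two-point estimation

For a pair of markers the likelihood is built from parental gamete
frequencies: a parent heterozygous at both markers transmits a
parental-type gamete with probability (1−r)/2 and a recombinant with
r/2 under a given phase; a parent informative at only one marker
contributes a factor ½; homozygous transmissions are deterministic.

* Same-parent testcross pairs have the closed-form ML estimate
  r̂ = min(R, n−R)/n over the two phases, and
  LOD = n log₁₀2 + R log₁₀ r̂ + (n−R) log₁₀(1−r̂).
* `hkxhk`×`hkxhk` and F2 pairs use EM on the joint class table. Each
  observed class is expanded into its compatible gamete combinations
  with coefficients const·((1−r)/2)^(K−b)(r/2)^b, where K is the number
  of doubly-informative meioses per offspring (2 for F2 and for
  intercross×intercross, else 1) and b counts recombinant meioses; the
  E-step takes posterior expectations of b, the M-step sets
  r = E[recombinants]/(nK). Convergence: relative log-likelihood change
  < 1e-8 or 200 iterations; r̂ clamped to [0, 0.5].
* All phase configurations (2 per doubly-informative parent; one shared
  phase for the two F2 gametes) are evaluated; the max-likelihood one is
  kept, ties resolved toward coupling.
* `lmxll`×`nnxnp` pairs share no informative meiosis and are returned as
  uninformative (r = 0.5, LOD = 0) — the reason CP data yield separate
  maternal and paternal maps bridged only by `hkxhk` markers.

An F2 matrix and the CP testcross blocks take vectorized all-pairs
paths (class-count matrices via indicator products, EM iterated on
whole matrices); `hkxhk` rows fall back to the per-pair engine. The
per-pair and vectorized paths are cross-checked against each other and
against a brute-force 1e-4 likelihood grid in the tests.

## Grouping, ordering, framework/accessory

Grouping is single linkage: connected components of the graph joining
pairs with LOD ≥ 3 (default). Note the multiple-testing consequence:
under the null the max-phase LRT gives P(LOD ≥ 3) ≈ 2×10⁻⁴ per pair
(measured on simulated unlinked pairs, n = 200), so a table of P pairs
is expected to contain ~2×10⁻⁴·P spurious links, and single linkage
propagates any one of them into a cross-chromosome merge. With hundreds
of markers this is a when-not-if event; the seeded recovery test in the
acceptance suite therefore fixes the study design and seed, and real
analyses should treat LOD 3 grouping of large tables as a first pass.

Ordering is regression-style sequential insertion. Distances are
Kosambi transforms of pairwise r̂; each pair is weighted by the inverse
variance of its distance estimate (delta method:
var(d) = (dd/dr)²·r(1−r)/n_meioses with dd/dr = 100/(1−4r²)), so the
goodness-of-fit — the weighted mean squared residual per pair between
least-squares map positions and two-point distances — is a mean
chi-square, ≈1 when residuals are pure sampling noise. The algorithm
seeds with the highest-LOD pair, inserts the unplaced marker with
strongest linkage at the best-fitting slot, ripples a window of 3
around each insertion, defers a marker if the gof rises by more than
`gof_jump_threshold` (default 5.0, i.e. gross misfit on the chi-square
scale) or if its best LOD to the placed map is below the grouping
threshold, retries deferred markers once, and finally demotes them to
accessory status anchored at their max-LOD framework marker with the
anchor's r and LOD reported. Output positions are the least-squares
solution, oriented canonically and made non-decreasing.

Weighting by estimated precision rather than LOD² matters twice: an
unlinked marker has near-zero weight everywhere, so only the explicit
LOD floor can demote it; and the mapping-function mismatch described
below produces small systematic residuals that a precision-scaled
statistic absorbs without false demotions.

## Consensus and heterogeneity

For a pair informative in both pedigrees the homogeneity of
recombination is tested with the likelihood ratio
2[ℓ₁(r̂₁)+ℓ₂(r̂₂) − max_r(ℓ₁(r)+ℓ₂(r))] on χ²₁. The pooled r̂ maximizes
the summed log-likelihood (bounded Brent, xatol 1e-7) with each
population's phase fixed at its own ML configuration. Under
homogeneous simulation the empirical size at α = 0.01 is compatible
with 1% (tested on 500 pairs). The consensus table pools every pair
informative in either pedigree (single-population estimates pass
through) and is grouped and ordered with the machinery above. A group
without any shared marker cannot merge, so sparse anchoring yields more
consensus groups than chromosomes — expected, not an error.

## Genome length, coverage, physical distance

Method-3 genome length is G = N(N−1)X/K with N framework markers, K the
number of framework pairs at LOD ≥ z, and X the maximum observed
distance among those pairs (the transform of the extreme pair's r̂).
The mapping function for X is a parameter. Kosambi is the default and
the right choice on real data, where crossover interference operates.
For validation against this package's own simulator the Haldane
transform is used instead, because the simulator is deliberately
interference-free: at the r ≈ 0.30 detection limit that a LOD-3
threshold implies with ~90 offspring, the Kosambi transform reads
~25% short of the no-interference metric, which would show up as a
systematic undershoot of the known simulated length. This is a
metric-consistency requirement, not a tuning knob. A map-position
reading of X was evaluated and rejected: pairs that clear the LOD
threshold by sampling noise contribute their full map separation, and
the maximum over ~10³ pairs inherits that selection bias upward.

Coverage c = 1 − e^(−2dn/L) (d = coverage radius in cM, n markers,
L genome length); marker number n = ⌈log(1−p)/log(1−2c/k)⌉, where 2c is
the maximum spacing between adjacent markers. The two published uses of
this formula employ different conventions for c (a 20 cM spacing enters
as c = 10; a "within 4 cM" criterion enters as c = 4), so the function
takes c directly and the caller owns the convention. Mb/cM =
(pg/2C ÷ 2)·(Mb/pg)/L with the round 1,000 Mb/pg conversion as default
(978, the Doležel constant, as an option — the two differ by ~2%).

## Error-rate estimator

A *data point* is one offspring × one adjacent within-contig marker
pair with both calls non-missing and phase-resolvable; double
heterozygotes (`hk`, `h`) are excluded because the transmitted gametes
cannot be read off the call. Every resolvable call projects to a single
0/1 allele (testcross calls are one meiosis; homozygous calls carry the
same allele on both gametes), so a pair's discordance is a simple
mismatch, the pair's phase is chosen as the orientation implying fewer
recombinants (true within-contig recombination being null), and each
discordant offspring counts one *event*. The rate is events/points,
reported in percent at one decimal. With per-call error e, a testcross
pair shows an apparent recombinant with probability 2e(1−e) (either
call flipped); the recovery test checks the estimator against that
enumeration. CP pairs informative in different parents contribute
nothing, and pairs of `hkxhk` with a testcross marker are read through
the shared parent.

## Discovery and array-design conventions

Masking: Phred < 30 → N; a base at exactly 30 is kept; gap cells carry
the sentinel −1 and are never masked. SNP columns need exactly two
bases among non-N characters, depth ≥ 4 and minor count ≥ 2. Indels are
maximal gap runs of identical extent, 1–6 columns, scored
presence/absence and anchored at the run start; runs that only
partially overlap another sequence's gap are skipped rather than
guessed. Spacing is measured in ungapped coordinates (columns where at
least half the sequences carry a base). Selection order: score floor,
then spacing (priority: MAF desc, score desc, leftmost), then LD against
already-kept candidates (haplotype r² on the discovery sequences),
then the per-gene cap (default 2) — every rejection carries its rule.
The designability score is consumed as metadata because the real score
comes from the array vendor's design tool; `surrogate_design_score` is
a clearly-labelled synthetic GC/complexity heuristic for fixtures only.

## COS clustering

Markov clustering is implemented directly on the dense adjacency
matrix: self-loops at each node's maximum incident weight (1 for
isolated nodes), column normalization, then expansion (squaring) and
inflation (elementwise power, default 2.0 — the common TribeMCL
default — then renormalize) until the matrix changes by < 1e-6 or 100
iterations; entries < 1e-12 are pruned. Clusters are read from
attractor rows (diagonal mass > 1e-6), overlapping attractor systems
merged, and unassigned nodes become singletons, so the output is always
a partition and disconnected components can never merge (the iteration
preserves block structure). Dense matrices bound practical graphs to
~10⁴ nodes, ample for unigene-set use with pre-filtered hits.

Hit filtering keeps alignments covering ≥ 60% of the shorter sequence
with identity strictly above 80% (the boundary itself is removed), drops
self-hits, and is idempotent. Category assignment uses the precedence
E (duplication/alternative-splice signature) → A (PLAZA protein hit) →
B (NCBI-nr hit only) → C (only in the maritime pine unigene set) → D
(conifer TGI unigenes only); a COS with no evidence flag at all is
rejected as contradictory since every COS originates in the TGI sets.
Linkage-group alignment excludes orthologs under 75% hit coverage,
declares homologous group pairs at ≥ 3 shared anchors, and reports
orthologs contradicting a declared homology as putative paralogs.

## The simulator: what it does and does not emulate

`simdata` generates a 12-linkage-group genome (default 2,500 cM total —
the genus-typical haploid chromosome number and the genome length the
formulas above assume), places markers uniformly or at caller-supplied
positions, assigns CP segregation types at 40/40/20
(`lmxll`/`nnxnp`/`hkxhk`) and random phases, and optionally co-locates
several markers per contig (exactly 0 cM apart, as for SNPs a few
hundred bp apart). Meioses follow a Poisson (no-interference) crossover
process: recombination between adjacent markers at d cM occurs with the
Haldane probability (1−e^(−2d/100))/2. Genotyping errors replace a call
with a uniformly chosen different legal call at the configured rate
(default 0.4%, the rate the error estimator is built to detect);
missingness is uniform (default 2%). Defaults of 90 offspring match the
size of the mapping populations this pipeline targets.

Not emulated: crossover interference (so Kosambi is *mis*-specified for
the simulator — a deliberate, documented mismatch that matters only at
distances ≳15 cM), segregation distortion with a biological cause,
clustered or allele-biased genotyping failures, intensity-level signals
(the simulator starts at called genotypes), and sequence-level homology
(the COS universe plants ortholog/paralog structure directly in hit
tables). Passing tests therefore demonstrate correctness of the
estimators under clean Mendelian sampling with uniform error — not
robustness to the correlated artefacts of real intensity data.

## Problem sizes in the test suite

The suite's simulation scales are package choices balancing statistical
resolution against determinism: grouping/ordering recovery uses 12
chromosomes × 5-marker clusters at 15 cM spacing, 200 offspring, 1%
error (a design in which every within-group order is identifiable);
genome-length recovery uses 300 testcross markers × 90 offspring × 20
seeded replicates; heterogeneity calibration uses 500 independent
homogeneous pairs; the two-point oracle check uses 200 random
9-class tables against a 1e-4 grid. All stochastic tests are seeded.

## Known limitations

* Single-linkage grouping at LOD 3 over large tables will occasionally
  merge chromosomes (null rate ≈ 2×10⁻⁴ per pair); no automatic repair
  is attempted.
* Ordering is a greedy heuristic with local ripple; like the procedure
  it reimplements, it can lock in a suboptimal order for weakly linked
  or near-coincident markers, and provides no global optimality
  guarantee.
* The consensus pooled table is computed per pair with the generic
  engine (no vectorized path), so merging very large marker sets is
  quadratic with a noticeable constant.
* `estimate_two_point` assumes the declared segregation codes are
  correct; systematically mistyped markers surface as phase or
  distance anomalies rather than explicit errors.
* The error-rate estimator's "adjacent pair" decomposition follows the
  printed data-point arithmetic of the assay it models; other contig
  pairings (all-pairs) would change the denominator.
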