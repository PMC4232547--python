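# Methods

This note records the models, estimators, numerical choices and known
limitations behind each stage of the package.

## Genotype model and conventions

Genotypes are diploid alternate-allele dosages in {0, 1, 2} with a distinct
missing code. Physical coordinates are 1-based inclusive (VCF convention);
all windows are half-open `[start, end)` in bp, tiled from 0 at a default
width of 100 kb (non-overlapping; a step parameter allows overlap). A
diploid call contributes two alleles; every per-site statistic uses the
realized non-missing allele count at that site.

## Marker filtering

Markers pass when MAF ≥ 0.01 (non-strict), call rate > 0.85 (strict) and the
1-df chi-square Hardy–Weinberg goodness-of-fit p > 0.01; the inequalities'
strictness follows the usual reporting convention for these thresholds. The
chi-square approximation is used rather than the exact test, matching
common SNP-panel practice at n ≈ 86; monomorphic markers get p = 1 by
convention. LD pruning slides a window of 50 markers (step 5) along each
chromosome and repeatedly removes the lower-MAF member of the worst pair
with r² above the threshold (default 0.05; ties remove the later position).
The default threshold is deliberately exposed: "pruning at 0.05" is
ambiguous between an r² cutoff and other readings, so the parameter is a
config knob rather than a constant.

## Recombination-fraction estimation

For a codominant F2 the 3×3 genotype table has class probabilities
(coupling, recombination fraction r): corners (1−r)²/4 and r²/4, edges
r(1−r)/2, centre ((1−r)² + r²)/2. The MLE is found by EM on the
double-heterozygote class — the only class with a latent recombinant/
non-recombinant split — using the closed-form update
r' = (R₁ + 2R₂ + 2n₁₁·r²/((1−r)²+r²)) / 2N, iterated to |Δr| ≤ 1e-12 from
r₀ = 0.25 (the update is monotone in likelihood; convergence is certified in
tests against a 1e-4 likelihood grid). Both phase codings (original and
dosage-mirrored second marker) are fit; the higher-likelihood phase wins.
LOD is the base-10 likelihood ratio against r = 0.5. Pairs with fewer than
two pairwise-complete samples are undefined and reported as such. All
pairwise estimation is vectorized over marker pairs via 9 indicator-matrix
products.

## Skeleton map construction

Twin groups are the transitive closure of "zero opposing non-missing calls"
(a `max_mismatch` tolerance is exposed, default 0 — zero distance means
identical segregation). A minimum pairwise overlap of 10 samples guards
against vacuous matches under heavy missingness. The delegate is the member
with fewest missing calls. Only delegates of groups with ≥ 2 members enter
the skeleton: a marker with a perfectly co-segregating partner is very
unlikely to carry a genotyping error, and with per-call error rates around
1% this selection is what keeps skeletal interval distances (and hence map
length) near truth — singleton markers would each inflate their adjacent
intervals by roughly the error rate's worth of false recombinants.

Linkage groups: single-linkage with edges where LOD ≥ 6 and r ≤ 0.4. The
LOD default is the field's stringent grouping convention; at n = 113 a
chance cross-chromosome pair occasionally reaches LOD ≈ 4.5 (phase selection
doubles the tail), so 3 would be unsafe. Groups below 2 members dissolve to
the heap.

Ordering: minimize the summed adjacent Haldane distance over an open path —
greedy nearest-neighbour construction from up to 12 deterministic starts,
refined by best-improvement 2-opt. Undefined/unlinked r values are capped at
0.4999 before the distance transform. Orientation places the smallest
physical position in the first half of the order (lexicographic endpoint
tie-break without positions). The heuristic equals the exhaustive optimum on
groups ≤ 8 in tests.

Jackknife stability: each of 100 replicates drops ⌈10% of individuals⌉ and
reorders; a marker is stable when its immediate neighbour set (orientation-
free) is preserved in ≥ 70% of replicates. Unstable markers are removed
together, then the monotony check runs on the full data: along the order,
r from an anchor to successive markers must not *decrease* by more than
eps = 0.03 + 1.64·SE(difference), with var(r̂) ≈ r(1−r)/(2N); the scan stops
once r saturates past 0.4, where pairs are effectively unlinked and carry
noise only. A violating triple blames the marker whose r to the anchor is
too large (error inflation manifests exactly there); the worst offender is
removed per pass (later position on ties) and the whole cycle repeats until
stable. On clean simulations this removes nothing; a marker with 20%
injected error is reliably removed.

Add-on attachment: a heap marker attaches to the interval whose flanks give
the smallest map distance, iff that distance ≤ the interval's length. When
the nearest flank is shared by both adjacent intervals the triangle excess
d_left + d_right − interval_length breaks the tie (the consistent side has
excess ≈ 0). Twins attach at their delegate's position with distance 0.

Recombination events are genotype-state transitions along the skeletal
order (|Δdosage| summed over adjacent non-missing pairs) after masking
singleton states — a marker disagreeing with two identical neighbours is
more plausibly an error than a double crossover. On error-free simulations
counts equal an independent reconstruction from the logged crossover
positions (interval-parity per gamete, same masking).

## Recombination landscape

GWRR per consecutive skeletal interval is ΔcM/(Δbp/10⁶), oriented so bp
increases; zero-bp-span intervals merge into their neighbour. The interval
cM spans are stored explicitly, so the conservation identity
Σ gwrr·Mb = mapped chromosome length holds exactly (same summands, same
order) rather than to rounding. A length-weighted resampling onto fixed
windows (default 1 Mb) supports plotting and the diversity association
(Spearman). Hotspots are maximal runs of intervals with GWRR ≥ 2; the 2–4
band is a label, not a filter. Estimated maps at fine marker spacing have
noisy per-interval GWRR (r̂ granularity ≈ 1/(2N) cM over sub-Mb spans), so
hotspot calls on real-size data are most meaningful on the windowed track.

Collinearity per group: orientation maximizes Spearman ρ between map rank
and bp; markers with rank residual > max(1, 5% of group size) are flagged,
and breakpoint segments are maximal runs of adjacent markers whose physical
position moves backwards along the oriented order. The run definition (not
flagged-marker runs) is what makes a single reversed segment — an inversion
relative to the assembly — report as exactly one segment; rank residuals
vanish at an inversion's centre and would split it in two.

## Diversity, Tajima's D and sweep calling

Per-site π is the unbiased heterozygosity 2p(1−p)·m/(m−1) (equal to the mean
pairwise difference at the site, verified by enumeration). Window summaries
average per-site values over polymorphic sites (the convention of the
SNP-panel software this mirrors; window means then sit in the 0.15–0.35
range for diverse panels), and also report absolute per-window sums. The
sweep diversity ratio uses the sums: averaging over polymorphic sites only
conditions on polymorphism and would not scale with a planted
diversity-reduction factor. Tajima's D uses the standard constants and
variance; with missing data one n per window is needed, taken as the modal
non-missing allele count over the window's polymorphic sites (exact when
missingness is zero), while π inside D stays fully missing-aware per site.
S = 0 or a non-positive variance term leaves D undefined (never 0).

The sweep rule flags windows with D(cultivated) < 0 and D(semi-wild) > 0 and
merges adjacent flags into runs of ≥ 2 windows. Under the panel simulator's
common-variant ascertainment, out-of-sweep windows have positive D in both
subpopulations, and frequencies pushed toward fixation inside the sweep
drive cultivated D negative, so the sign rule recovers planted sweeps with
median Jaccard ≈ 1 at the study scale (60 accessions, ~20 SNPs/window).

PCA mean-imputes missing dosages per marker, centers columns (optional
1/√(p(1−p)) scaling) and uses a full SVD, so duplicated samples get
identical coordinates and scores are exactly centered.

## LD

r² is the squared Pearson correlation of dosage vectors over
pairwise-complete samples — the phase-free composite statistic standard for
unphased panels (an EM haplotype-frequency r² is out of scope). Monomorphic-
on-overlap pairs are undefined. Decay curves are mean r² per distance bin,
empty bins undefined. Blocks chain consecutive markers whose adjacent-pair
r² ≥ 0.5 (default), tolerating up to `max_gap_markers` interrupting markers
(g markers span g+1 below-threshold adjacencies); the block criterion is a
package definition — the literature rarely states one — with all parameters
exposed. Block summaries report the length-weighted mean GWRR inside the
block and its ratio to the chromosome mean, the quantitative form of "LD
blocks are recombination cold spots".

## Simulators: what they emulate and what they do not

**F2 intercross.** Crossovers are a Poisson process on the genetic map
(Haldane, no interference — consistent with the default mapping function and
invertible for testing), two independent gametes per selfed F1 meiosis,
113 progeny by default, chromosomes defaulting to the genetic lengths of a
dense cucurbit map with physical lengths giving ≈ 1.2 cM/Mb. Twin clusters
(default 20% of markers) duplicate an existing marker at identical cM but a
distinct bp within 1 kb, mirroring co-segregating GBS tags from one
restriction fragment. Genotyping errors flip a call to a uniformly chosen
different state (symmetric — the simplest model that stresses the twin and
jackknife filters); missingness is uniform. An optional per-chromosome
intensity map (piecewise-constant multipliers on cM/Mb) plants hotspots and
cold spots. Not modelled: crossover interference, segregation distortion,
locus-specific error/missingness (real GBS missingness is depth-dependent),
read-level artefacts.

**Diversity panel.** Balding–Nichols: per marker an ancestral frequency
(minor allele uniform on (0.05, 0.5], randomly oriented — the panel has no
published frequency spectrum, and GBS panels are ascertained toward common
variants), then per-subpopulation Beta(p(1−F)/F, (1−p)(1−F)/F) frequencies
with drift F defaulting to 0.20/0.25/0.35 for wild/semi-wild/cultivated
(cultivated narrowest, as domestication bottlenecks imply), and binomial
diploid genotypes for 22/13/51 accessions. The sweep is planted by shrinking
cultivated frequencies toward the nearest absorbing state so that expected
heterozygosity is reduced by exactly the configured factor (default 0.3 over
a 2-Mb region) — direct control of the diversity ratio the scan must
recover, rather than simulating hitchhiking dynamics. Markers are unlinked,
so this panel exercises the window scan and sweep caller but not LD decay
(the F2 simulator provides distance-structured LD). Passing tests therefore
demonstrate correct statistics and calling under the stated frequency
model, not robustness to real LD structure, admixture or ascertainment
quirks.

**Neutral coalescent.** Epoch-based: with k lineages, an Exp(k(k−1)/2)
waiting time; mutations Poisson with rate θ/2 per lineage per unit time,
placed on a uniformly chosen lineage of an epoch drawn proportional to
branch length; a site's derived count is the lineage's descendant-leaf
count. Verified against E[S] = θ·a₁, the closed-form SFS E[ξ_k] = θ/k, and
an external coalescent simulator. Note the finite-sample mean of Tajima's D
under neutrality is slightly negative (≈ −0.07 at n = 20, θ = 5), not
exactly 0; the calibration band of ±0.1 covers it.

## Numerical choices and degenerate inputs

EM tolerance 1e-12, ≤ 500 iterations; r̂ clipped to [0, 0.5]; distances for
ordering capped at r = 0.4999 (≈ 345 cM) to keep unlinked pairs finite.
Undefined statistics are `nan` and documented as such (never silently 0):
all-missing MAF, monomorphic r², S = 0 Tajima's D, empty windows/bins,
zero-π diversity ratios. Determinism: every stochastic component takes a
seed; the pipeline derives per-stage seeds from one master seed via
`SeedSequence`, and fixed-seed runs are byte-identical.

## Problem sizes

Test and demo sizes are chosen to exercise each method at the study's
stated conditions while staying desk-scale: the map-recovery experiment
uses 3 chromosomes × 200 markers × 113 progeny; sweep recovery uses 20
replicates of 2000 SNPs × 60 accessions; the neutral calibration uses 2000
coalescent replicates; LD/collinearity replicates use 50–60 markers ×
20 seeds. The full suite runs in well under two minutes on one CPU.

## Known limitations

- Outcross/backcross designs, dominant markers and multi-locus likelihood
  ordering are out of scope; the RF model is strictly codominant F2.
- Recombination counting is transition-based with singleton masking, a
  declared simplification of multi-locus EM/Gibbs approaches; it undercounts
  double crossovers within one skeletal interval by construction.
- Window Tajima's D with heterogeneous per-site missingness uses one modal
  n; heavily uneven missingness would warrant a per-site-weighted variant.
- The LD block criterion and the collinearity flag threshold are package
  definitions, exposed as parameters, not community standards.
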