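# Methods

`mpqtl` implements the genetic-dissection pipeline used for large multiparent
inter-cross (MAGIC-style) populations: a panel of F inbred founders is
inter-crossed for several generations and then selfed, so that each derived
line's genome is a mosaic of founder identity-by-descent (IBD) segments. The
package covers the simulation of such populations, reconstruction of the
founder mosaics from SNP data, and the downstream association machinery
(single-variant and bin-haplotype mixed models, epistasis, QTL refinement).
This note records the models, their assumptions, the tunable parameters, and
the design decisions taken where the methodology left genuine freedom.

## Population and genome model

**Genetic map.** Marker coordinates live on a per-chromosome bp/cM table;
bp→cM queries interpolate piecewise-linearly and clamp at the map ends.
Coordinates are 1-based inclusive throughout; BED export converts to 0-based
half-open.

**Founder panels.** Founders are fully homozygous, represented haploid. Each
simulated site carries the minor allele in `k` of the `F` founders; mixing
singleton (`k = 1`) and balanced (`k = F//2`) sites tunes the expected
pairwise difference rate at segregating sites to a target `divergence`. With
F founders this rate is bounded by `[2/F, ~F/(2(F-1))]`, so a 24-founder
panel tops out near 0.52; requests outside the range are capped. The default
0.6 used with small panels (and 0.5 with 24 founders) makes most segments
identifiable by a handful of SNPs, emulating a diverse elite-inbred panel.

**Meiosis.** Crossovers are placed without interference: the per-chromosome
crossover count is Poisson with mean equal to the map length in Morgans and
positions are uniform on the cM scale, i.e. breakpoint density follows the
local recombination rate. This Markovian process is chosen deliberately — it
is the generative counterpart of the HMM's exponential segment-length
assumption. Selection steps present in real breeding designs (selection of
the best F1s, biased seed mixing, diversity retention) are not simulated:
the downstream analyses only require the mosaic and phenotype structure.

**Pedigree simulator.** Generation 1 forms F1s from distinct founder pairs
(complete-diallel style); later inter-cross generations mate random distinct
parents (open pollination); final generations self by single seed descent,
which halves heterozygosity each round (~1.6% residual after six selfings —
kept, and later absorbed by the IBD SNP filters, as in the real pipeline).
The truth mosaic records the first transmitted haplotype; after selfing the
two haplotypes differ only over the residual-heterozygous fraction.
Under G_ic inter-cross generations plus selfing, the expected segment count
per line is roughly `G_eff * L + C` for genome length `L` Morgans and `C`
chromosomes, with `G_eff ≈ G_ic + 1` because selfing accumulates about half
a generation's recombination per round.

**Pseudoprogeny.** For HMM power evaluation, lines are built directly by
reshuffling founder genomes: a fixed number of segments (default 180) is
allocated to chromosomes proportionally to map length (largest-remainder,
at least one each), breakpoints are drawn uniformly on the cM scale, and
founders are assigned uniformly with adjacent labels forced distinct.

**Phenotypes.** Additive QTN effects follow the geometric series `a**n`
(default a = 0.95); raw genetic values are rescaled so the realized genetic
variance is exactly `h2 * Vp` (defaults 0.8 and 1), residuals are i.i.d.
normal with the remaining variance (0.2 in the default case), and optional
epistatic product terms are each rescaled to a requested variance share.
Multi-environment tables add a random environment main effect and
independent replicate noise of variance `env_var`.

## Founder-mosaic HMM

Hidden states are the F founders; the chain starts uniform. Between adjacent
markers at distance `d` Morgans a switch occurs with probability
`1 - exp(-G d)`, with `G` the effective number of accumulated generations
(default 9 = eight inter-cross rounds plus ~one from six selfings). On a
switch the new founder is re-drawn uniformly over all F (self-switch
allowed), which makes marginal segment lengths exponential with mean
`rho/G * F/(F-1)` — negligibly above the nominal `rho/G` for F = 24, and
the simpler parameterization; a distinct-founder re-draw is available via
`HmmParams(redraw="distinct")`. Emissions compare the progeny's homozygous
allele to each founder's allele with symmetric error `epsilon` (default
0.02 — low-coverage sequencing plus imputation justify a small nonzero
value; there is no EM re-estimation). Heterozygous progeny calls are
treated as missing: under a haploid state space they are uninformative, and
high-heterozygosity markers (>10%) and high-missingness markers (>25%) are
filtered out beforehand. Posteriors come from the scaled (not log)
forward-backward recursion with per-site normalization; a founder is called
at a SNP when its posterior reaches `call_factor / F` (default twice the
1/F chance level; ties break to the lowest founder index), else the site is
UNKNOWN. Runs of identical calls merge into segments with boundaries at
inter-marker midpoints. Tracing power is the fraction of SNPs whose called
founder equals the simulated truth, UNKNOWN counting as incorrect.

The tracing-power study uses a 10-chromosome, 180 cM/chromosome fixture
genome (1500 markers each). The total map length (~18 Morgans) was chosen
so that 180 segments per line match the segment density the G = 9 prior
expects, as in a real maize consensus map; on a much shorter genome the
same segment count would contradict the prior and the study would measure
the wrong thing.

## Bins and bin kinship

A bin is a maximal span with no recombination breakpoint in any line: bin
edges are the union of all segment boundaries, each line inherits its
segment's state per bin, and UNKNOWN propagates. Kinship reformats bin
states as founder-state dummy variables: `K = Z Z' / n_bins`, i.e.
`K[i,j]` is the fraction of bins where lines i and j share a founder state.
UNKNOWN matches nothing (conservative), so the diagonal is each line's
traceable fraction; K is PSD by construction. Bins are unweighted by
default (a length-weighted variant exists behind a flag) because bin counts,
not lengths, define the downstream tests.

## Single-variant scan (sGWAS)

`y = X b + g beta + u + e` with `u ~ N(0, sigma_g^2 K)`, K the centered
dosage cross-product kinship, X an intercept plus the top 10 genotype PCs
(signs fixed by the largest-magnitude loading). Variance components are
estimated once under the null by REML on the eigenbasis of K and held fixed
for all markers (the P3D/EMMAX approximation; exact per-marker REML behind
`exact=True` agrees to within an order of magnitude on null markers).
Markers below MAF 0.02 are skipped. Significant SNPs group into sQTL by:
gap chaining (<20 kb), a two-SNP minimum, LD merging of adjacent loci when
any cross-locus pair has r² ≥ 0.2 (all significant pairs, not only peaks),
and a 25-kb two-sided extension for loci under 50 kb whose peak beats the
threshold by 100×. The genome-wide threshold is `alpha / n_eff` with the
effective test count supplied by the user (its estimation is out of scope).

## Bin-haplotype scan (hGWAS)

Per bin, the full model adds a random haplotype effect over the bin's
founder-state dummies, `a ~ N(0, sigma_b^2 I)`, to the polygenic term with
the bin kinship; the null omits it. Fixed effects are identical in both
models, so the restricted likelihoods are comparable and
`LRT = 2 (logL_full - logL_null)`, floored at 0. The solver profiles out
the residual variance on the eigenbasis of K; the polygenic ratio is fitted
under the null and, by default, held there while the per-bin haplotype
ratio is maximized by a grid-plus-Brent 1-D search (Woodbury identities
keep each evaluation at O(m²) for m founder states). This nests the null
exactly at sigma_b² = 0, so the LRT is non-negative by construction; a
`mode="full"` re-optimizes both ratios per bin and is cross-checked against
a dense-matrix REML evaluation in the tests. Because sigma_b² sits on the
boundary under the null, significance is calibrated by permutation (500
phenotype shuffles by default; genome-wide max-LRT 95th percentile), never
by an asymptotic chi-square. Founder states carried by fewer than 3 lines
are pooled into an "other" dummy column; UNKNOWN lines get a zero row
rather than being dropped. Significant bins merge into hQTL when separated
by ≤1 Mb or ≤5 intervening bins.

## Epistasis

Markers are MAF-filtered (≥0.02) and LD-pruned (greedy, r² < 0.5 in 50-kb
windows, 5-SNP step). The scan statistic is the 1-df interaction t-test of
`y ~ gA + gB + gA·gB` on dosages — the quantitative-trait analogue of the
case-control fast-epistasis test, substituted deliberately because the
traits here are continuous. Pairs above the permissive first-pass cut
(default 6e-16 ≈ 0.01/Ne²) are discarded; surviving pairs whose endpoints
both fall within 100 kb of another pair's endpoints form clusters (the
cluster reading of the ambiguous uniqueness rule) keeping the minimum-P
representative. Retained pairs are re-fit with PCs and additive terms; the
adjusted interaction P must beat 1e-12 and the pair PVE is the interaction
term's incremental R². The joint epistatic variance is the incremental R²
of all interaction terms over the [PCs + all involved additive dosages]
model, relative to total trait variance — the Frisch–Waugh form of
"regress out structure and additive effects, then regress residuals on the
interaction terms", which (unlike the literal two-stage version with raw
product regressors) cannot fall below any single pair's PVE. Pairs are
categorized SS-1/SS-2/SN/NN by whether each side lies within 50 kb of an
sQTL interval and whether the linked sQTL share a trait.

## QTL refinement

Major QTL are loci detected by both scans with ≥10% PVE each; the region is
the union of the two intervals. At the peak bin, founder IBD groups (with
at least 2 lines) collapse into *functional alleles*: all pairwise Welch
t-tests between founder groups are computed once, the between-cluster
p-value is the largest cross-pair p (single linkage), and clusters merge
largest-p-first until every between-cluster comparison has p < 0.05. Welch
rather than Student is used for the unequal group sizes, and testing only
original founder groups avoids the selection bias of re-testing pooled
clusters, which otherwise splits exchangeable groups spuriously. No
multiple-testing correction is applied inside the collapse (the raw-p
criterion is part of the procedure). The allele labels are projected onto
every bin of the region (founders unobserved at the peak stay UNKNOWN),
lines with complete projections group into major haplotypes (n > 8), and
each bin is scored: it supports the QTL iff every phenotypically distinct
haplotype pair (Welch p < 0.01) differs in allele there while every
equivalent pair agrees. The refined interval is the longest run of
supporting bins; with fewer than two major haplotypes or no distinct pair
the region is returned unchanged and flagged. The per-bin consistency rule
is one faithful reading of the published verbal procedure and is isolated
in a single function for replaceability.

## Simulation studies and the scales used

**Tracing power.** 100 pseudoprogeny, 180 segments, 24 founders at
divergence 0.5, G = 9, default epsilon: genome-wide power ≈ 99%,
comfortably above the 93% floor the method is expected to clear.

**Mapping power.** The desk-scale study uses a pedigree population of 200
lines (24 founders, one 60 cM / 6 Mb chromosome, 1500 markers,
8 inter-cross + 6 selfing generations, ~700 bins). Each replicate simulates
one trait carrying three causal bins of every architecture simultaneously
(1, 2 or 3 incompletely linked QTN per bin, within-bin pairwise r² in
(0.1, 0.9) best-effort), h² = 0.8, Vp = 1 — nine loci per trait rather than
the thirty used at full scale, because at n = 200 a thirty-locus budget
leaves each locus too weak to measure power differences. Both scans run at
matched genome-wide thresholds: Bonferroni 0.05/n_markers for sGWAS and a
null-trait permutation LRT cutoff for hGWAS (~6.8 at this scale). Detection
windows are 200 kb (~2 cM); the 1-Mb convention of a 2.3-Gb genome would
cover most of a 6-Mb fixture chromosome.

The geometric effect series `a**n` can be read two ways for multi-QTN loci,
and the two readings correspond to the two matched-effect comparisons the
architecture figure makes. With the series over *loci* ("locus" model: a
k-QTN locus splits its effect across its QTN), architectures are compared
at matched per-locus variance — the comparison under which the
single-variant scan is most powerful for biallelic QTL, since splitting
dilutes every single-SNP signal. With the series over *QTN* ("qtn" model:
every QTN draws its own effect), architectures are compared at matched
per-QTN effect — the comparison under which the bin-haplotype scan's power
rises with allele count, since a k-QTN bin accumulates about k variance
shares that no single SNP tags but the founder-state term captures jointly.
The study runs both models per replicate with shared causal bins and
residual noise (common random numbers), and the ordering assertions test
each claim under its matched comparison with one-sided 99% tests on the
extreme differences. At a fixed total h² these orderings are zero-sum
trade-offs, which is why neither single model reproduces both patterns at
once at this scale.

**What passing tests do and do not show.** The synthetic populations have
no genotyping error beyond the injected emission noise, no population
stratification beyond what the pedigree creates, no missing phenotypes, and
founder panels with exchangeable (LD-free) site patterns. Calibration and
recovery results therefore validate the estimators and the pipeline
plumbing, not robustness to real-data artifacts such as assembly errors,
segregation distortion, or selection during population development.

## Numerical choices and degenerate inputs

- Forward-backward uses per-site scaling; zero inter-marker distance gives
  an identity transition; an observation impossible under every founder
  (possible only at epsilon = 0) raises rather than returning NaN.
- The founder-call threshold comparison is `>=`, so the degenerate F = 2
  case (threshold exactly 1) still calls perfect posteriors.
- REML optimizers work on log-variance scales with grid initialization;
  boundary fits (a variance → 0) are admissible; the LRT is floored at 0.
- Single-environment phenotype tables cannot separate variance components:
  line means are returned with a warning and NaN components.
- Monomorphic markers: skipped in scans (P = 1), excluded as epistasis pair
  members; bins with one observed state get LRT 0.
- Collinear predictors in PVE regressions are dropped via least-squares
  rank handling with a logged warning.

## Known limitations

- The HMM has no diplotype (founder-pair) states, so residually
  heterozygous regions can only be called UNKNOWN or mis-assigned; this is
  bounded by the ~1–2% residual heterozygosity after six selfings.
- P3D-style fixing of the polygenic ratio slightly deflates per-marker and
  per-bin statistics for very large effects; exact modes exist but are
  O(markers) slower.
- The effective-test count for thresholds is an input, not estimated.
- Bin construction at exact bp resolution makes the bin count grow with
  population size (every breakpoint is a boundary); real pipelines observe
  breakpoints at marker resolution, which collapses coincident boundaries.
- The epistasis scan is O(pairs) in pruned markers and is meant for pruned
  sets of at most a few thousand markers.
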