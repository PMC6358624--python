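# Methods

This note documents the models, the numerical choices, and what the
synthetic validation does and does not show. Symbols: N recipients, M
donors, G donor groups, g an admixture age in generations, alpha an
admixture proportion, d genetic distance.

## Copying model and coancestry

Each recipient haplotype is an imperfect mosaic of donor haplotypes. The
hidden copying state switches donor between adjacent SNPs with probability
1 − exp(−rho·d), d the inter-SNP gap in cM, the new donor drawn uniformly
from the allowed set; alleles are emitted with miscopy probability theta.
Defaults: rho = 1 per cM, theta = 0.01 (the pipeline configuration uses
rho = 2 per cM, which shortens chunks and sharpens the curve analyses
below). Both are configuration, not estimated — estimation of copying
parameters is outside this package's scope.

Expected copied length per donor is accumulated by attributing each
inter-SNP interval's cM to the painting posterior at its left SNP. This
rule is exact against brute-force path enumeration (the posterior
marginals are exact, and expected lengths are linear in them; verified to
1e-8 on ≤4-donor × ≤6-SNP instances) and conserves: each haplotype's row
sums exactly to its painted span (first to last SNP per chromosome).
Expected chunk *counts* — the alternative coancestry measure — come from
posterior transition expectations; count and length rankings agree
(Spearman > 0.9) on structured panels. Diploids: recipients are painted
per haplotype with their own two haplotypes excluded from the donor set;
donor haplotypes are pooled per individual; the four haplotype-pair values
are summed, so square-matrix rows sum to 2 × span.

## Partition model and MCMC

Coancestry rows are converted to effective counts by rescaling with a
c-factor and rounding half-to-even, the row total preserved by adjusting
the largest entry. The default c is the mean chunk size (total painted
length / total expected chunks), so scaled rows approximate independent
chunk counts; any externally computed c can be supplied.

The likelihood is a two-level Dirichlet-multinomial. Under partition z
(shared by rows and columns of a square matrix), a copy from row-cluster a
lands in column-cluster b with probability theta_ab and is allocated
uniformly within b — over |b| members, or |b|−1 for the row's own cluster,
since an individual cannot copy itself. The cluster-level compositions are
integrated against a Dirichlet whose base measure is proportional to
column-cluster size (the aggregation of a flat measure over individuals),
so the total concentration is independent of K and adding a cluster does
not re-price other clusters' marginals. The category space is always the
full set of columns, making marginals of different partitions comparable;
the uniform-within-cluster term is what penalizes merging heterogeneous
columns. The self-exclusion correction matters: without it, small clusters
are systematically punished for the structural zero diagonal. The
partition prior is uniform over K and uniform over set partitions with K
blocks (log-Stirling numbers by dynamic programming).

MCMC: random-order Gibbs single-individual reassignment (existing clusters
plus a fresh singleton) interleaved with a Metropolis–Hastings
split-or-merge proposal (random bipartition, exact proposal correction).
Chains start from all singletons — coalescing by single moves mixes far
better than splitting out of one cluster. The reported MAP is the
best-posterior visited state refined by a deterministic single-move hill
climb. Convergence is checked as in practice: pairwise coincidence
matrices of two independent runs correlate > 0.9 on separated data.

Assignment certainty for individual i and final cluster k is the mean over
MCMC samples of |c_t(i) ∩ k| / |c_t(i)|, where c_t(i) is i's sampled
cluster; rows sum to 1 and aggregate up the tree by summation. The merge
tree greedily applies the pairwise merge with the smallest posterior
decrease (ties: smallest cluster-id pair; scores clamped at 0). Tree-level
rules: "all-greater-than s" returns the finest level where every cluster
exceeds s; "first-large-merge t" returns the level at which two clusters
each larger than t first merge.

## External-sharing clustering

The rectangular matrix X (recipients × external donors) is embedded in
C = [[0, X], [0, Y]] of size (N+M)². Y is zero outside within-donor-group
blocks; every entry of group k's block — self-pairs included — equals
g_k = mean of the group-k entries of X, which makes the group-k means of X
and Y equal by construction (machine precision). The zeros ensure
recipient-recipient copying contributes nothing to the likelihood; donor
groups are frozen during the MCMC (recipients may neither join them nor
split them), so splits and merges happen among recipients alone. Two
behaviours follow and are tested: demes differing only by private recent
drift merge (their donor-sharing is identical), and demes differing in
external admixture fraction (0 vs 0.2) separate exactly.

## Drift/admixture bootstrap test

Every cluster with ≥ s members (s = 13 by default) is sub-sampled to s
without replacement — coancestry is undefined between an individual and
itself, so sampling must be without replacement — the coancestry matrix is
re-painted on the sub-sampled panel (a fast matrix-slicing mode exists but
is approximate, because painting is relative to the sample), and mean
within-cluster coancestry (diagonal excluded) is compared with mean
cross-cluster coancestry. S counts null-consistent resamples (within ≥
cross) and p = (S+1)/(R+1), so consistent excess-cross pairs get small p;
pairs below 0.02 (uncorrected) are flagged. Equal subsample sizes remove
cluster-size bias.

The generator's demographic cartoons make the test's logic concrete. The
excess-cross signature is only realizable when the admixed cluster's
*background* copying is diluted across other clusters while its
source-derived copying concentrates on the drifted source group; with only
two equal-size clusters the background term always dominates (an
expectation computation over the leave-one-out painting shows within-pair
background share (1−a)/(s−1) exceeds cross share 2a/(n_source + a·n_self)
for any a ≤ 0.5). The cartoon panels therefore include two unadmixed
background demes sharing the recipient's ancestral pool — the analogue of
the many other clusters in a real panel.

## Ancestry profiles

The donor basis B has one row per donor group: each donor individual is
painted against all donor haplotypes except its own two (optionally
excluding its whole group), results aggregated by group, averaged within
group, and normalized to proportions. Targets (cluster means, donor
groups with their own entry removed and renormalized, or grid cells) are
fit as y ≈ Bᵀβ with β ≥ 0, Σβ = 1: non-negative least squares with the
sum-to-one constraint imposed by a heavily weighted augmentation row
(weight 1e4), then exact renormalization; coefficients below 1e-4 are
zeroed and the rest renormalized (reporting convention). The fit matches
an exhaustive simplex grid search at step 0.01 to within 0.02.
Uncertainty: 1000 pseudo-individual re-estimations (each pseudo individual
takes a random member's painting per chromosome, preserving
within-chromosome correlation), inner 95% reported; a group is displayed
when its range excludes zero and the point estimate exceeds 0.001.

## Spatial smoothing

Placement: centroid of the four grandparental coordinates; retention
requires all four within 80 km of the centroid (a pairwise ≤ 80 km reading
is available behind a flag); co-located display points are jittered
uniformly within 24 km. Cluster-density maps and copying-vector fields
live on a 3-km grid (planar km throughout — at a national scale the
smoothing only needs a metric). The kernel bandwidth at a cell is
max(base, distance to the k-th nearest retained individual), defaults
k = 10, base = 3 km — a simple adaptive rule honouring density-dependent
bandwidth. A designated no-fine-geography region (ids + bounding box)
receives one constant vector, the plain average over its individuals.
Grid-cell ancestry profiles reuse the profile fit with y set to the cell's
smoothed vector.

## Coancestry curves and dating

Restricted painting yields per-site posterior copying probabilities per
donor group. These are centred per site (subtracting the across-haplotype
mean field — this cancels site-level structure such as chromosome-edge
effects in the HMM posterior), and for each group pair (a, b) the products
at within-chromosome site pairs are averaged in 1-cM distance bins
(symmetrized in a, b, so curve(a,b) = curve(b,a) identically). After a
two-way pulse, cov_ab(d) ≈ alpha(1−alpha)·delta_a·delta_b·exp(−g·d) with
delta the difference of the two sources' copying profiles.

Fitting: exponential-plus-intercept by weighted least squares, rates
scanned on a fixed grid (1..60 per Morgan) with amplitudes solved
linearly, then an analytic-jacobian least-squares polish; the joint
estimate shares one rate across all pair curves. Default bins run from 2
to 50 cM: the painting posterior's own chunk-scale autocorrelation decays
at roughly the switch rate and measurably contaminates the 1–2 cM bins at
the SNP densities simulated here, so the short-range cutoff sits at 2 cM
rather than 1 cM (configurable).

Evidence: the observed statistic is the leading eigenvalue magnitude of
the fitted amplitude matrix, with amplitudes evaluated at the first bin
(near-flat fits make raw amplitude and intercept jointly unbounded; the
short-range excess is stable). Its null distribution comes from a
site-permutation repaint: target alleles are shuffled across haplotypes
independently at every site (site frequencies kept, all within-haplotype
LD destroyed), the pseudo-panel painted identically, and its curves
bootstrapped over haplotypes; p = (1 + #null ≥ observed)/(n_null + 1),
detection at p < 0.01. A cross-haplotype product null alone is
anti-conservative because it lacks the painting's chunk autocorrelation.

Proportion and sources: the amplitude matrix's leading eigenpair gives the
direction of delta; for each candidate alpha (grid 0.01..0.50) and sign,
the implied sources f1 = mu + alpha·delta and f2 = mu − (1−alpha)·delta
are fit onto the donor basis under simplex constraints. The residual is
one-sided in alpha — below the true proportion the implied minor source
leaves the basis simplex, above it everything fits — so alpha is the
smallest value whose residual is within 10% of the minimum (the elbow),
not the argmin of noise on the flat side. Minor side = smaller weight;
ties report 0.5. Dates convert to calendar years as
year = reference − generation_time·g (defaults 1940 and 28; non-integer
years are kept, rounding only at display).

One- vs two-date comparison: per curve, the RSS reduction of a
two-exponential over a one-exponential fit is ranked against a parametric
bootstrap from the one-exponential fit (Gaussian bin noise at the
residual scale); curves without significant decay at all are labelled
no-decay. The overall verdict is two-date only if some curve — optionally
restricted to pairs involving designated groups — prefers two dates, and
"no admixture" when nothing decays. Bootstrap intervals for g resample
pseudo-individuals (random member per chromosome), capturing both the
individual and chromosome axes of variation; haplotype-only resampling
under-covers.

## Synthetic data: what it emulates, and what it does not

Demes draw allele frequencies from a Balding–Nichols model around shared
base frequencies (divergence parameter F), with haplotypes sampled
site-independently; recent strong local drift is modelled separately as a
Markov mosaic over a small pool of founder haplotypes, which produces the
long shared segments behind extreme within-cluster coancestry (and, under
the all-vs-all analysis, realistic sub-splitting of such a deme). A
frequency pool may be shared between populations (the first population
naming it fixes its drift); founders are always private. Admixture pulses
rewrite recipient haplotypes as renewal segments (boundaries Poisson at
rate g per Morgan; each segment independently carries source ancestry
with probability alpha; adjacent same-source segments are kept distinct in
the truth record, so complete segment lengths are exactly Exp(100/g) cM
and ancestry autocorrelation decays as exp(−g·d)); source-segment content
is drawn fresh from the source pool's generating distribution. Genetic
maps are uniform per chromosome; geography is planar km with Gaussian
grandparent dispersion around deme centroids.

Not emulated: background linkage disequilibrium within pools (sites are
exchangeable given the pool), mutation, genotyping error, phasing error,
variable recombination maps, continuous migration, or sex chromosomes.
Passing tests therefore demonstrate correctness of the estimators under
the stated generative model at desk scale — painting-resolution effects,
resampling calibration, identifiability — not robustness to the artefact
spectrum of real array data.

## Problem sizes and scenario conventions

Validation runs are scaled to minutes on one CPU: demes of 14–20 diploids,
donor pools of 10–12, genomes of 2–8 chromosomes × 80–100 cM with 1.5–6
SNPs/cM. Donor-pool divergences (0.5–0.7) are chosen larger than
continental-scale F_ST to compensate for the reduced SNP density — what
matters for the methods is the per-cM discrimination of the painting,
which at cohort scale comes from marker density instead. Dating scenarios
pair one "near" donor group sharing the target's background pool (the
anchor, analogous to a neighbouring population) with one diverged source
group; with no anchor the copying posterior loses per-tract resolution and
dates bias upward. Where a criterion fixes a quantity (alpha = 0 vs 0.2;
pulse at g = 30 with alpha = 0.1; subsample 13 × 200 resamples), those
values are used as stated; remaining scenario parameters are the package's
documented study conditions, chosen for well-posed truth recovery.

## Known limitations

* The painting rate estimate retains a small finite-information bias
  (generally within ~10% at the validated densities); bootstrap intervals
  are the honest uncertainty statement, and absolute parity with
  production painting/clustering/dating software is explicitly not
  claimed.
* The drift test's resamples share the one observed panel; its p-values
  calibrate sub-sampling noise, not evolutionary replication.
* The event decomposition assumes a single two-way pulse; multi-way or
  continuous admixture is out of scope, and with two donor groups the
  proportion is identified only through the simplex-boundary elbow.
* The c-factor heuristic treats chunks as independent; strong LD would
  require the external calibration the real software derives.
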