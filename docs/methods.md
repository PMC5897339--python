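# Methods

`netexpr` re-implements, as a tested pipeline, an analysis that links spatial
gene expression in post-mortem brain tissue to cortico-striatal functional
networks. This note documents the models, the choices made where the
procedure was genuinely open, and what the synthetic benchmark does and does
not establish.

## Sample-to-network assignment

Tissue samples carry MNI coordinates (mm); functional atlases are volumetric
integer label images (nominally 1 mm isotropic) whose labels group into
networks. Assignment uses an expanding region of interest: cubes of side 1, 2
and 3 voxels are evaluated in order, stopping at the first cube containing at
least one labeled voxel; the network with the most overlapping voxels in that
cube wins, and a sample whose side-3 cube is all background is omitted.

Cube placement is under-determined by a side length alone, so we fix it as
follows: the side-1 ROI is the voxel containing the continuous coordinate
(voxel centers at integer indices); the side-2 cube is the 2×2×2 block of
voxels nearest the continuous coordinate, extending toward the coordinate's
octant with ties resolved toward negative indices; the side-3 cube is
centered on the side-1 voxel. Inter-network ties in voxel counts go to the
network holding the lowest tied label and are logged, since no tie rule is
standard. Coordinates outside the volume yield an omitted sample with a
warning rather than an error. The expansion is applied identically to cortex
and striatum by default; a strict cortical mode (side-1 only, `strict_cortex`)
is available because cortical assignment is sometimes defined as strict
containment. For non-1 mm atlases, coordinates pass through the affine and
cube sides are counted in voxels.

## Expression preprocessing

Matrices carry an explicit scale state machine (`linear → log2 →
log2_mean_normalized`) so that operations cannot be applied out of order.

**Probe collapsing.** For genes with ≥ 3 probes, the probe with the maximum
*summed adjacency* is kept, defined here as the sum of its pairwise Pearson
correlations (across samples, pairwise-complete) with the gene's other
probes; zero-variance probes contribute adjacency 0. For 1–2 probes the
max-mean rule applies. Ties break toward the lexicographically smallest probe
id, which also makes selection invariant to row order.

**Mean normalization.** Because global transcription differs markedly between
cortex and striatum, each gene is centered separately within each
compartment, on the log2 scale; output per-gene per-compartment means are
exactly 0 and the operation is idempotent. A division-by-mean variant on the
linear scale is provided (`method="divide_linear"`) but off by default, since
centering on log2 is the standard reading of "mean-normalized log2".
Missing values propagate and are excluded pairwise; there is no imputation.

**Homolog mapping** requires a strictly one-to-one table; unmapped genes are
dropped with a logged count, and an empty intersection is an error.

## Network-biased differential expression

Expression is aggregated hierarchically per donor: samples averaged within
parcels, then parcel means averaged *unweighted* within networks, so heavily
sampled parcels do not dominate. A donor-network cell with no samples is
absent, never zero.

Per gene, a linear model of the donor × network means on an intercept plus a
target-network indicator (plus optional donor-level covariates such as age
and sex) gives the one-vs-rest log2 fold change. Residual variances are
moderated empirically: under a scaled-inverse-chi-square prior, the
hyperparameters (d0, s0²) are estimated by method of moments on log s_g²
using digamma/trigamma identities (with a Newton inversion of the trigamma
function); the moderated variance is the posterior mean
s̃² = (d0·s0² + d·s²)/(d0 + d) and the moderated t carries d0 + d degrees of
freedom. When the moment estimate leaves no excess spread, d0 = +inf and all
genes share the pooled variance. For RNA-seq style inputs, `trend=True`
replaces the constant s0² with a LOWESS fit of log s_g² on average
expression; precision-weighting of individual observations is deliberately
not implemented (inputs are assumed pre-normalized).

**Donor blocking.** Observations from the same donor co-vary. Three modes are
exposed: `none`; `donor_fixed` (donor indicator columns); and the default
`consensus_correlation`, which estimates a single intra-donor correlation
pooled across genes — per-gene one-way ANOVA intraclass correlations of
residuals, capped at ±0.99, Fisher-z transformed, 10%-trimmed mean, back
transformed — and uses it as a compound-symmetric block correlation in
generalized least squares (whitening per donor block). Residuals for the ICC
are taken about the saturated network-means design so the estimate reflects
donor structure rather than network structure. The exact design of the
original analysis (donor as blocking factor vs covariate) is not recoverable,
which is why both `consensus_correlation` and `donor_fixed` are exposed.

Significance uses two-sided p-values from the moderated t and
Benjamini–Hochberg step-up adjustment (hand-rolled to the stated formula,
cross-checked against statsmodels in the tests). "Network-biased" genes are
those with q ≤ 0.01 *and* positive log2FC — a post-hoc sign filter, not a
one-sided test. The boundary q = 0.01 is included.

The within/between contrast summarizes a gene set per donor as its mean
expression in the target network versus the average of its per-network means
elsewhere; the test is the paired t across donors reported as F = t² with df
(1, D−1), matching the set-mean-per-donor convention (gene-level observations
would inflate the df).

## Co-expression and correspondence with functional connectivity

Per donor, expression is averaged within regions (regions sampled by fewer
than `min_donors_per_region` donors are dropped globally, not per donor) and
region pairs are Spearman-correlated across the chosen gene subset. Donor
matrices are averaged on the Fisher-z scale: |r| is capped at 0.999999 before
atanh, means are taken over the donors in which a pair was measured, and
entries whose available values are all equal bypass the cap so averaging
identical matrices is an exact identity. Pairs observed in no donor stay
absent. Functional-connectivity matrices are consumed precomputed and keep
Pearson correlations; gene expression keeps Spearman.

Matrix correspondence vectorizes the unique off-diagonal pairs (upper
triangle) of two matrices aligned on their common region set and reports
Pearson r; rectangular striatum × cortex profiles are compared cell-by-cell.
The rectangular profiles use the same per-donor Spearman + Fisher-average
recipe as square matrices ("Fisher transform, then average", rather than
correlating per donor and averaging the correspondence).

## Replication and enrichment

Set overlaps use the exact upper-tail hypergeometric probability P(X ≥ k),
including the observed k (the standard enrichment convention). Universe
convention: within one dataset, that dataset's measured universe; across
datasets, the intersection of measured universes — the universe is echoed in
every report because results are sensitive to it. Fold-change concordance is
Pearson r over shared genes (fold-change scatter comparisons conventionally
use Pearson), with ≥ 3 shared genes required.

Cell-type enrichment compares the top-expressing cell type with the
second-highest: log2((top + c)/(second + c)) with pseudocount c = 0.01
guarding zero denominators (the rule is otherwise undefined at zero);
a gene is called iff the ratio strictly exceeds the threshold (default 1.5
log2 units), so exact ties give no call. Calls are invariant to rescaling a
gene's profile up to pseudocount effects, which vanish for large values.
Laminar contrasts group layers 2/3 (superficial) vs 5/6 (deep) and reuse the
moderated one-vs-rest machinery with donor blocking, flagging deep-biased
genes at q ≤ 0.05.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
known ground truth:

- **Atlas**: 3-voxel cubic parcels on a 6-voxel grid in a 40³ volume with
  identity affine, labels 1..P grouped into networks.
- **Expression** (log2 scale): value = baseline (8.0) + δ·planted indicator
  + donor effect + compartment shift (striatum) + residual noise. Defaults:
  2000 genes, 6 donors (matching the donor count of the motivating atlas),
  δ = 1.0 log2 units, residual SD 0.5, donor SD 0.25, compartment shift 5.0,
  10% of genes planted per network (disjoint within a compartment). Donor
  effects are gene-specific draws shared across a donor's samples — exactly
  the structure the consensus-correlation estimator must recover. Cortical
  and striatal planted sets are independent by default;
  `shared_planted_fraction` forces overlap to emulate genes biased in both
  compartments of one network. Optional probe expansion replicates each gene
  into 1–4 probes with a per-probe bias (SD 0.2) and per-sample noise.
- **Functional connectivity**: sample correlation of MVN signals over 1000
  pseudo-subjects with population correlation 0.6 within and 0.1 between
  networks (PSD by construction).

All draws come from one seeded generator; a fixed seed reproduces every
output bit for bit.

What the generator does *not* emulate: spatial autocorrelation of expression
along the cortical sheet, graded (rather than block) network effects,
count-level measurement noise, probe-specific cross-hybridization, or
realistic fcMRI noise structure. Passing the synthetic benchmark therefore
shows that the estimators recover the planted architecture under the model's
own assumptions — not that real tissue data satisfy those assumptions.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at 2000 genes
× 6 donors (the study-condition scale for differential expression, 10
planted-effect seeds and 20 null seeds) and at 600 genes for the
co-expression block-structure checks (10 seeds), sizes at which the Monte
Carlo error of the reported summaries is well below the margins being
checked. Degenerate cases are handled explicitly: numerically-zero contrasts
give t = 0 and p = 1 rather than 0/0; single-donor data fall back from
consensus blocking to no blocking with a warning; correlations at ±1 are
capped at 0.999999 before atanh except where an equal-value fast path makes
averaging exact; trigamma inversion uses Newton iteration with closed-form
endpoints for extreme arguments.

## Known limitations

- The moderated-model formulas are fixed as stated above; alternative
  empirical-Bayes variants (robust estimation, winsorized variances) are not
  implemented.
- Full mixed-model REML, spline age trajectories, and interaction contrasts
  are out of scope; covariates enter only as linear fixed effects.
- fcMRI matrices are always consumed, never computed from time series.
- Surface-based assignment and probabilistic atlases are not supported.
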