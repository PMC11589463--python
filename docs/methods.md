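# Methods

## Structural covariance networks

A structural covariance network is a group-level graph: each node is a brain
region, and the edge between two regions is the Pearson correlation of their
grey-matter volumes **across subjects**, after removing nuisance covariates.
Unlike tractography or functional connectivity, it is defined only at the
group level — one matrix per group, not per subject — which dictates the
inferential machinery below (label-permutation rather than subject-level
models).

Volumes are residualised on age, sex and total intracranial volume (TIV) by
ordinary least squares with an intercept.  The default residualisation scope
is **pooled**: one group-blind design over all subjects entering a
comparison, so that genuine group differences in covariance are not absorbed
by group-specific covariate fits; per-group residualisation is available via
`RunConfig.residual_scope`.  A covariate that is constant within scope (for
example sex in a single-sex subgroup) is dropped with a logged warning
rather than failing the fit.

Correlations are Fisher-transformed, z = atanh(r), for variance
stabilisation; r is clipped to ±(1 − 1e−12) beforehand so that exactly
collinear node pairs produce a finite (large) z with a warning rather than
an infinity.  The diagonal of the z-matrix is set to 0 by convention.

## The motor atlas

Twenty nodes: ten homotopic left/right pairs — precentral gyrus (PrG),
supplementary motor area (SMA), postcentral gyrus (PoG), superior parietal
lobule (SPL), paracentral lobule (PaL), caudate (Cau), putamen (Put),
pallidum (Pal), thalamus (Tha) and cerebellar hemisphere (Cer).  Each node
carries a region class — cortex, central grey nuclei
(`basal_ganglia_thalamus`), or cerebellum — used as the anatomical 3-module
partition for the participation coefficient and for summarising edge-level
results.  Each cerebellar hemisphere is treated as a single node; lobular
subdivisions are outside the atlas's resolution.  Node order is fixed by the
atlas and shared by every downstream matrix.

## Density thresholding

The z-matrix is binarised by **density**: at density d over N nodes, the top
round(d · N(N−1)/2) edges are kept (half-away-from-zero rounding, for
bit-exact reproducibility).  Edges are ranked by **signed z** descending by
default — negative covariances enter only after all positive ones — with
|z| ranking available via `RunConfig.edge_ranking`; ties are broken by
(smaller first node index, then smaller second).  The default grid is
0.10–0.50 in steps of 0.01 (41 levels, 19–95 edges on 20 nodes); because all
densities share one ranking, the graph family is nested.  Metrics computed
along the sweep are aggregated by the trapezoidal integral divided by the
grid span (a density-averaged value, "AUC"); non-finite points on a curve
are excluded pairwise with a logged count.

## Graph measures

All measures are for binary undirected graphs, computed directly on numpy
adjacency matrices (all-pairs BFS via boolean matrix products; Brandes'
algorithm for node and edge betweenness).  The vectorised implementation
exists because permutation inference re-evaluates a 41-density sweep
thousands of times; the test-suite verifies every measure against networkx
and against brute-force enumeration oracles on small graphs.

Conventions for degenerate cases: global efficiency averages 1/d over all
ordered pairs, counting disconnected pairs as 0; characteristic path length
L averages over **connected** pairs only and is NaN (flagged) on an empty
graph; clustering and local efficiency are 0 for nodes of degree < 2;
participation is 0 for isolated nodes; assortativity is NaN when degrees at
edge ends have zero variance.  Degree centrality is reported as raw degree
(the hub rule is scale-invariant) and betweenness unnormalised.

Small-world indices are normalised against a null ensemble of 100
degree-preserving Maslov–Sneppen rewirings (10·|E| double-edge swaps per
null, via networkx); nulls that disconnect a connected original are rejected
and redrawn (≤ 50 retries).  γ = C/C_rand, λ = L/L_rand, σ = γ/λ.

## Permutation inference

**Network-based statistic.**  Edges are compared by the Fisher-z difference
statistic t = (zᴀ − z_B)/√(1/(nᴀ−3−k) + 1/(n_B−3−k)), k the number of
residualised covariates — the standard large-sample statistic for comparing
correlations between independent groups.  Suprathreshold edges (t > 3.1 for
A > B; t < −3.1 for A < B; each direction its own family, as the two
directions answer different questions) are grouped into connected
components.  The null distribution of the maximum component size (edge
count) is obtained by shuffling group labels and re-running
residualisation → correlation → statistic → components; with pooled
residualisation the residuals are label-invariant, so only the row-to-group
assignment needs redrawing, which is also what makes 5000 permutations
cheap.  All permutation p-values use the +1 correction,
p = (1 + #{null ≥ obs})/(1 + n_perm), so p ≥ 1/(1 + n_perm) always.
Because component size is heavily discrete, the test is conservative: the
measured family-wise rejection rate per direction on null cohorts is
~0.01–0.05 at nominal α = 0.05.

**Metric comparisons.**  Group differences of AUC-averaged metrics are
tested two-sided against the same label-permutation null (default 1000
permutations).  Nodal p-values are Benjamini–Hochberg corrected across the
20 nodes within each metric family.  A degenerate permutation distribution
(all values identical) yields p = 1 with a warning.

**Specificity.**  The mean off-diagonal z among the 20 motor nodes is
compared with the same statistic over 5000 random 20-node subsets drawn
from a whole-brain ROI pool; the pool excludes the motor nodes by default
(`RunConfig.specificity_pool`), since the question is a contrast against
*other* regions; one-sided p both ways.

**Hubs.**  A hub is a node whose density-averaged degree centrality exceeds
the network mean by `hub_sd_multiplier` (default 1) population standard
deviations.  A participation-coefficient variant of the rule is available
(`RunConfig.hub_rule`), since both statistics are in circulation for hub
definitions; the degree rule is the default.  Patient vs reference hub sets
are classified preserved (both), lost (reference only) and reconfigured
(patient only) — three disjoint sets by construction.

## Clinical statistics

2×2 contingency tables use the Pearson chi-square without continuity
correction by default (a Yates flag exists).  Global volume comparisons are
ANCOVA fits (group + centred covariates) with adjusted means at the
covariate mean and model-based pairwise contrasts.  Brain–behaviour analysis
is the residual-on-residual partial Pearson correlation given age, sex and
TIV, with a t-based two-sided p on n − 2 − k df and Benjamini–Hochberg
correction across the ROI × score grid.  The a-priori sample size for a
one-way ANOVA uses Cohen's f with noncentrality λ = f²·N and returns the
smallest **balanced** total (a multiple of k, n ≥ 2 per group) whose
noncentral-F power reaches the target; for k = 3, f = 0.40, α = 0.05,
power 0.80 this gives N = 66 (unrestricted integer N would give 64 — the
balanced convention matches standard a-priori calculators).

## The synthetic cohort generator

The generator emulates the features the analysis relies on, with defaults
fixed at the study conditions:

| parameter | default | rationale |
|---|---|---|
| group sizes | pPVL 27, fPVL 15, HC 38 | study cohort |
| age | Uniform(1, 8) y | study age range |
| sex | Bernoulli(0.5), male = 1 | balanced cohort |
| TIV | Normal; HC 1348 ml, pPVL 1156 ml, fPVL 1300 ml (SD 150) | group means match the reported global volumes |
| node means | per-region plausible ml (e.g. Tha 7, Cer 50) | order-of-magnitude realism only |
| base correlation | 0.6 within region class, 0.3 between | a synthetic convention, not an empirical estimate |
| covariance deltas | nuclei–other −0.25/+cortex–cerebellum +0.25 (pPVL), ∓0.15 (fPVL) | direction of the disease contrast; magnitudes chosen for testability, no published effect sizes exist |
| atrophy | LTha −15%, RTha −12% (pPVL); LTha −8% (fPVL) | thalamic atrophy pattern, preterm > full-term, left > right |
| score model | GMFM ≈ 60 + 8·(thalamic latent SD) + N(0, 10²) | positive thalamus–gross-motor association |
| extra ROIs | 70, correlation 0.25 within / 0.20 with motor | whole-brain pool for the specificity test |

Volumes are built as (atrophy-scaled mean) × (1 + covariate effects) +
noise × latent MVN draw.  Covariance deltas are applied on the **latent**
(covariate-free) scale, so residualisation recovers the implanted structure
exactly in expectation and recovery tests are sharp.  When deltas push a
correlation matrix off the positive-definite cone it is repaired by
eigenvalue clipping at 1e−6 and re-normalisation to unit diagonal (logged).
`make_null_cohort` removes every group difference (no deltas, no atrophy,
no TIV shift) and is the exact null used to calibrate NBS and the metric
permutation tests.

What the generator does **not** emulate: spatial structure (no images beyond
tiny test fixtures), non-Gaussian volume distributions, missing data,
scanner or site effects, floor/ceiling effects in motor scores, and
lesion-extent heterogeneity.  Passing recovery tests therefore demonstrates
that the estimators recover the structures they target under the stated
model, not that the clinical effect sizes are realistic.

## Verification strategy and problem sizes

Every graph measure is checked against brute-force enumeration
(Floyd–Warshall, triple counting, simple-path betweenness) on 200 random
graphs of ≤ 7 nodes and against networkx; NBS component extraction against
a union-find oracle on random 20-node matrices.  Calibration uses 200 null
replicates at 500 permutations for the NBS family-wise rate (accepted band
0.01–0.10 around the nominal 0.05, reflecting the discrete conservatism
noted above) and 60 replicates for uniformity (Kolmogorov–Smirnov at
α = 0.01) of the metric-comparison and specificity p-values.  Recovery uses
an implanted +0.3 correlation increase on a 4-edge cortex–cerebellum star
(all four edges incident to the left cerebellar node, so that detected
edges always form one component) at n = 200/group: 50 replicates, NBS
power > 0.8, and Jaccard overlap between the significant component and the
implanted edges summarised by the median replicate (≥ 0.75).  At these
conditions the per-edge detection probability is ≈ 0.75 (expected edge
statistic ≈ 3.8 against threshold 3.1), which caps the *mean* Jaccard near
0.75 by construction; the median is the stable summary of the typical
replicate.  Thalamus–score sign recovery uses 60 replicates at n = 100.
These sizes keep the full suite within a few minutes on one CPU while
leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* The group-level design means no subject-level network estimates and no
  longitudinal modelling.
* Metric comparisons on σ/λ/γ require a null ensemble per permutation and
  are correspondingly expensive; they are supported but not in the default
  comparison set.
* The 3.1 edge-statistic threshold is a tuning constant of NBS, not a
  calibrated quantity; conclusions at other thresholds can differ (this is
  inherent to NBS).
* With 20 nodes, data-driven module detection is unstable; the participation
  coefficient therefore uses the fixed anatomical partition.
* The balanced-allocation convention in the sample-size routine is a
  modelling choice; unbalanced designs need a direct power scan.
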