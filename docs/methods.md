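# Methods

This note records the models implemented by `clonal_circuits`, the
parameter choices that matter, what the synthetic generator does and does
not emulate, and the numerical decisions made where the design was open.

## Cortical-cylinder input-fraction model

The model treats the presynaptic neighbourhood of a cell as a cylinder of
cortex: density 100,000 neurons/mm², excitatory fraction 0.8, tangential
radius r = 0.087 mm (half the 99% quantile of recorded pairwise distances).
π·r²·80,000 evaluates to ≈ 1902 excitatory cells; because the radius is
itself a rounded quantity, `CylinderModel(total_override=1908)` is provided
to fix the total at the conventionally quoted 1908, and the headline
reproductions use that mode. The clone of k = 60 cells (the median labeled
clone size) gives q_r = k/N ≈ 3.1% related cells in the cylinder; layer
composition is 35/15/25/25% for L2/3, L4, L5, L6.

Inputs per layer and lineage relation are Binomial(n_i·q_l, p_il). The
expected related fraction e = p_r·q_r/(p_r·q_r + p_u·(1−q_r)) is independent
of the layer pool sizes (they cancel), which the tests assert numerically
against the pool-size formulation.

The standard error of e is a first-order Taylor propagation from the two
binomial rate estimates, taken as independent (the two lineages are measured
on disjoint pair sets):

SE[e] = sqrt{ q²(1−q)² [p_u²·p_r(1−p_r)/m_r + p_r²·p_u(1−p_u)/m_u] /
(p_u(1−q) + p_r·q)⁴ }.

*Limitation:* the linearization is only trustworthy when both counts are
moderately large. At counts like 2/89 the parametric bootstrap distribution
of e has an atom at p̂_u = 0 (probability ≈ 13%), where e jumps to 1, so
its SD is several-fold larger than the delta-method SE. The bootstrap
agreement test therefore runs at ten-fold counts; the reported SEs at small
counts should be read as local curvature, not as spanning the heavy tail.

Percentages are rounded half-away-from-zero to one decimal, matching the
convention of the printed estimates.

## Lineage-pooling power analysis

A labeled clone of S = 60 neurons spread over L = 4 layers pools N
radial-glial lineages. Under the hypothesis that only shared-RGC kinship
changes connectivity (by fold change FC over the unrelated rate), the
pooled rates are the mixtures given in the README. The lateral equation
excludes the indexed cell from its own same-layer, same-lineage pool of
S/(NL) cells (the "−1" terms); it assumes RGC lineages distribute evenly
over layers.

Defaults are the observed rates: P_ul = 51/626, P_uv = 19/711,
P_rv = 28/464, group sizes n1 = 626 and n2 = 248, α = 0.05. Power uses the
arcsine (Cohen's h) two-proportion normal approximation with effective size
ñ = n1·n2/(n1+n2); two tails are summed (so power → α as h → 0). A
one-sided option exists.

Grids run N = 1..20 (integer) and FC = 0..0.1..30; the resolution is a
package choice, results are insensitive to it. For N ≥ 16 with S = 60,
L = 4 the same-lineage pool S/(NL) drops below one cell and the lateral
equation's pool term goes negative; predicted rates are clipped into [0,1]
(with a warning at the top) so grids stay total. The `PowerConfig`
invariant S/(NL) ≥ 1 applies only to a single configured analysis.

Two printed byproducts of the original power discussion (a 16% probability
of detecting a 50% decrease, and a sample size of 233 for the cell-type
matching comparison) do not follow from the standard two-proportion
formulas with the stated inputs; the package provides the generic
`two_proportion_power` and `two_proportion_sample_size` operations and does
not special-case those numbers.

## Pair-table statistics

- **Clopper-Pearson** intervals via beta quantiles; lower bound 0 at k = 0,
  upper bound 1 at k = n.
- **Fisher's exact test** follows the minimum-likelihood two-sided
  convention (tables with point probability ≤ observed are summed), which
  is what scipy and the common stats toolboxes implement. Degenerate
  tables with an all-zero margin return p = 1 with a warning.
- **Distance-matched bootstrap.** Control pool = pairs with at least one
  unlabeled cell; a control matches a related pair when it shares both
  layers and is within 20 μm (inclusive) on the tangential *and* vertical
  axes. Related pairs with no match are dropped and reported. Each of the
  B = 1000 iterations resamples related pairs with replacement and picks
  one matched control per selected pair, uniformly at random among its
  eligible controls (the matching rule within an iteration is otherwise
  unspecified in the field; uniform selection is the neutral choice).
  The two-tailed p inverts the bootstrap interval: the mean of the
  bootstrap differences is subtracted from each difference and p is the
  fraction of shifted differences at least as large in magnitude as that
  mean. With B finite the smallest attainable p is 1/B.
- **Log-ratios.** Laplace smoothing (+1 on numerator and denominator
  counts) removes zero divisions; bootstrap replicates redraw the related
  count as Binomial(B, (A+1)/(B+1)) and the unrelated count as
  Binomial(D, (C+1)/(D+1)), and the CI is the 2.5–97.5% coverage interval
  of the re-smoothed log-ratios.
- **Connectivity GLM.** Bernoulli response per tested directed pair, logit
  link, design = constant + L (related), C (vertical), D (Euclidean μm),
  R (rostrocaudal 1..5) + all pairwise interactions (11 parameters, so
  residual df = n − 11 on full-rank designs; statsmodels reduces the df on
  rank-deficient degenerate designs). Non-convergence or separation raises
  with diagnostics instead of returning silently. Each directed test is
  treated as an independent observation (clone-level clustering is out of
  scope).
- **Rostrocaudal stratification** re-runs the related-vs-unrelated
  comparison per stratum; the default split is at the median position into
  rostral/caudal, and any mapping from positions 1..5 to strata can be
  supplied. Strata missing a lineage group are skipped with a warning.

## Synthetic-data generator

The generator defines the conditions under which everything is tested.
Each clone is one recording "site": S = 60 labeled cells split
multinomially over N = 2 lineages, plus unlabeled background cells filling
the cylinder to the configured density (≈ 1842 per site at defaults;
reducible for speed). Layers are multinomial on the 35/15/25/25 fractions;
positions are uniform in the cylinder disc (matching the model's
homogeneity assumption — no spatial structure is claimed for unrelated
cells) and uniform within nominal layer depth bands; each site draws a
rostrocaudal position 1..5. Distances are tangential (in-plane Euclidean),
vertical (depth difference) and Euclidean (root of sum of squares), all μm.

Pair tests are Bernoulli draws at per-(relation, pre-layer, post-layer)
probabilities whose defaults are the empirical rates of the published count
table. Pairs flagged as tested in both directions contribute two
independent directed draws linked by a pair id, so the reciprocal
connection rate is p² by construction. No generative model links
connection outcome to distance; matched-control analyses are exercised with
explicitly constructed offsets.

Expression is cluster-structured negative-binomial: a lognormal baseline
mean per gene, disjoint 20-gene marker blocks per cluster (fold 10),
a single dispersion θ = 2 (variance μ + μ²/θ; a Poisson flag takes the
θ → ∞ limit), and per-cell library-size factors uniform in [0.5, 2].
The reference atlas draws from the same means and fixes a 2-D embedding
with cluster centroids on a circle (radius 20, jitter SD 1). The embedding
is always an *input* — the package never computes t-SNE. What passing
tests show is that the operators behave correctly on data satisfying their
assumptions; real Patch-seq data add contamination, dropout structure,
batch effects and continuous variation that this generator deliberately
omits.

One global seed expands into per-operation substreams (population, pairs,
expression) so modules reproduce independently; fixed seeds give
byte-identical table output.

## Transcriptome mapping

- **Cell QC** removes cells more than 3 MADs below the median on library
  size or genes detected. The MAD carries the 1.4826 normal-consistency
  scaling, as in the R outlier helpers this rule emulates (the unscaled
  variant cuts at ≈ 2σ and discards healthy cells).
- **Gene filter** keeps genes with mean count ≥ 1 per cell (strictly-below
  removed).
- **Normalization** uses library-size/geometric-mean size factors and
  log₂(x+1); precomputed factors (e.g. from pool-based methods) are
  accepted for exact replication. Pool-based normalization itself is out
  of scope — size factors track library size closely in practice.
- **Variable genes:** genes need counts ≥ 32 in ≥ 10 cells to be eligible;
  μ is the mean log₂ count over counts > 32 and τ the fraction < 32
  (counts exactly 32 enter neither statistic, as the asymmetric wording of
  the rule implies). The offset b is binary-searched — the selected count
  is non-increasing in b — until the count hits n_target or the bracket is
  below 1e-9, returning the closest achievable set (±1 in general
  position; exact ties on the curve can widen this).
- **kNN mapping:** Pearson correlation of each query against every
  reference cell over the shared genes (both log₂(x+1)); position =
  coordinate-wise median of the k = 10 best references' embedding
  coordinates. Zero-variance queries are flagged and skipped. Precision =
  80th percentile of displacement across 100 gene-bootstrap re-mappings;
  dot-size classes at ≤ 5 / (5,10] / > 10 embedding units.
- **Cluster assignment** is nearest-centroid by correlation against mean
  log₂ profiles; ties break to the lowest cluster index (logged). Broad
  classes come from a user-supplied cluster→class table.
- **Region classifier:** L2-penalized multinomial logistic over a C grid
  (10⁻²..10²) with stratified k-fold CV (default 20 folds, reduced to the
  smallest class count when necessary); performance is the best mean
  accuracy along the path, mirroring glmnet's `lambda.min` usage. An L1
  option exists; the permutation-null framing makes the conclusion robust
  to the penalty type. Permutation p-values use the add-one convention
  (1 + #null ≥ obs)/(1 + P), which is valid at any permutation count;
  plain-fraction p-values can reach 0 and anti-conservative calibration.

## Problem sizes used in the test suite

Simulation-backed checks run at sizes chosen to keep Monte-Carlo error
comfortably inside the asserted tolerances: binomial-CI frequency checks at
6,200 draws, Clopper-Pearson coverage at 10,000 replicates, the power
Monte-Carlo oracle at 100,000 replicates, GLM recovery at 25 replicates of
20,000 pairs, bootstrap calibration at 30 replicates of 200 iterations, and
the expression checks at a few hundred cells × a few hundred genes. The
full suite completes in well under a minute on a single CPU.
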