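# Methods

This note documents the models, conventions and numerical choices behind
`phyloscape`, and what the synthetic-data validation does and does not
establish about real atlas data.

## Diversity metrics

PD is **rooted** Faith diversity: the total length of the union of
root-to-tip paths of the species present in a cell. The rooted form
means a single-species cell has nonzero PD (its path to the root); an
unrooted convention would subtract the deepest shared stem. A root edge
length, when present in the input Newick (e.g. a single-tip tree
`A:1;`), is counted.

PE follows the range-weighted branch formulation: each branch's
geographic range is the set of cells holding at least one of its
descendant tips, and the branch contributes `length / |range|` to every
cell in its range. Branch ranges are computed once per (tree,
occurrence) pairing into a branch × cell presence table and reused by
the null-model stage; with that table, per-cell PD and PE are boolean
matrix products, which is what makes 10³–10⁴-replicate randomizations
cheap. Two conservation identities follow from the definition and are
enforced in tests: map-wide PE sums to the length of the tree pruned to
occurring species, and WE sums to the species count.

Cells with zero species are retained in tables (zeros) but excluded from
regression; species occupying fewer than `min_range_cells` (default 3)
can be removed before modelling, because an extreme micro-endemic
concentrates near-maximal PE in one or two cells and destabilizes a
Gaussian regression on log PE.

Ultrametricity is validated (relative tip-depth spread ≤ 1e-6) but only
warned about: PD/PE are defined for arbitrary branch lengths.

## Null models

Tip shuffle permutes the species → tip assignment uniformly; topology,
branch lengths and the community matrix are fixed. Implementation
detail: a label permutation is equivalent to composing a uniform
permutation of tip positions with the species→tip index map, so each
replicate is one matrix product, and one shuffled tree serves the whole
map per replicate (whole-map randomization, not per-cell resampling).
Under this null a cell's PD distribution depends only on its richness.

The independent swap (fixed-fixed) draws random 2 × 2 submatrices and
flips checkerboards; both margins are preserved exactly by construction.
The default chain length is 10 × the number of presences, a standard
burn-in heuristic; the method's originators give no parameter values.

The rank p-value is `p = (#{null < obs} + 0.5·#{null = obs} + 1)/(R+1)`
with ties counted half. The half-tie rule makes a degenerate cell (e.g.
one holding every species under tip shuffle, where every replicate
equals the observation) land at ~0.5 rather than 1.0. With this
convention p can reach 1.0 when the observation exceeds every replicate;
significance is declared one-tailed at strictly p > .95. Cells with null
sd 0 get SES = 0 plus an explicit `degenerate` flag, never NaN, so the
null mean stays usable as a regression covariate.

## Climatic instability

The statistic standardizes the **current** climate variables over cells,
fits a PCA on them, and projects every historical period into that fixed
PC1–PC2 plane, standardizing the past layers with the *current*
means/sds. Fitting the PCA once (rather than per period) keeps the
geometry comparable across periods, so per-cell step distances measure
climate change rather than re-normalization; a side effect is exact
invariance to affine rescaling of any input variable (tested). Periods
are ordered oldest → present and distances taken between consecutive
periods; since each step distance is symmetric, only the pairing
matters. The long-window variant (since the last interglacial) uses 4
periods and the mean of its 3 steps on the full variable panel; the
high-frequency variant (since the last glacial maximum, e.g. 500-year
steps) reports mean, sum and sd over its steps on a restricted panel.
All three windows include the current period as the final step.
Constant variables are rejected by name. Only PC1–PC2 are used;
variance explained is available from the fitted object but not
thresholded.

## Terrain

TPI(c) = z_c − mean(8 neighbors); TRI(c) = mean |z_n − z_c|; both
restrict to neighbors that exist at grid edges. Slope uses Horn's 3 × 3
finite differences in degrees, with edge replication for the pad. (TRI
is sometimes defined as the root-sum-of-squares of neighbor differences;
the mean-absolute form used here preserves the ranking on smooth
terrain and has the convenient flat-DEM = 0 / symmetric-window
properties the tests exercise.)

## Collinearity screening

The correlation report clusters predictors by complete linkage on
distance 1 − |r| (grouped at |r| > 0.7 by default) and is advisory only;
selection is by stepwise VIF: repeatedly drop the predictor with the
largest VIF_j = 1/(1 − R²_j) until max VIF ≤ 2.5, ties broken
alphabetically for determinism. A duplicated column yields an infinite
VIF and is removed first. Retained predictors are scaled to mean 0 / sd
1 over modelled (complete-case) cells; a cell missing any selected
predictor is excluded from the model stage, with a logged count.

## Spatial regression

The SAR is the **error** specification — y = Xβ + u with u = λWu + ε —
chosen because the diagnostic being addressed is residual spatial
autocorrelation ("SAR" is ambiguous in the literature; the lag model
answers a different question). W is a distance-band neighbor matrix
(all cells within d_max, self excluded), row-standardized; d_max is the
upper bound of the first Moran-correlogram distance class with p ≥ .05,
scanning outward from zero, recomputed per response. Correlogram
p-values use the normal approximation, two-sided, without
multiple-class correction (a Bonferroni variant would widen d_max; the
uncorrected rule is the package default and the correction is easy to
apply by passing a smaller α). Cells left with zero neighbors are a
hard error listing the offenders, with a `drop_islands` escape hatch.

Estimation maximizes the concentrated likelihood: for trial λ the data
are filtered by (I − λW), β̂ and σ̂² follow by least squares, and
logL = ln|I − λW| − (n/2)ln(2πσ̂²) − n/2, with the log-determinant from
the eigenvalues of W. W = D⁻¹A with A symmetric, so its spectrum equals
that of the symmetric D^(−1/2)AD^(−1/2) and is real; the
eigendecomposition is done densely once per weights object and cached,
adequate through a few thousand cells (sparse/Chebyshev log-determinant
approximations would be the next step beyond that). λ is found by
bounded scalar search inside (1/ω_min, 1/ω_max) with tolerance 1e-8.
Coefficient standard errors are the GLS errors at λ̂ (the β block of the
information matrix); the λ standard error comes from the numerical
curvature of the profile likelihood. AIC = −2 logL + 2k with
k = |β| + 2, counting λ and σ²; since the +2 is common to all subsets
it never affects rankings.

Nagelkerke pseudo-R² divides the Cox–Snell likelihood-ratio R² by its
maximum attainable value; the null likelihood is the **non-spatial**
intercept-only OLS fit (using the spatial intercept-only fit instead
would fold the spatial signal into the baseline and shrink every R²; the
non-spatial baseline matches how the statistic is usually reported).

All-subsets selection fits every subset of ≤ 15 candidates (2¹⁵ ceiling)
plus the intercept-only model; an optional always-included covariate
carries the null-model expected diversity (the PD ~ PD_null + predictors
design), standardized like other predictors. PE is log-transformed
(natural log) before modelling to stabilize its right-skewed
distribution; zero cells are not modelled.

## Synthetic data

One master seed spawns named PCG64 sub-streams (tree / env / paleo /
ranges) via `numpy.random.SeedSequence`, so every output is bit-identical
per seed and each component can be regenerated independently.

- **Tree**: Yule pure-birth (exponential waits, uniform splitting
  lineage, tips extended to a common final time) — exactly ultrametric
  by construction. Tree *shape* is not a tested quantity, so the simplest
  ultrametric generator suffices.
- **Environment**: Gaussian random fields (white noise smoothed by a
  Gaussian kernel of configurable correlation length), standardized per
  layer.
- **Paleo series**: per-cell Gaussian random walk whose step sd is a
  supplied volatility layer — the ground truth the instability statistic
  must recover.
- **Ranges**: each species occupies the top-q cells of a suitability
  field mixing a designated driver layer (weight 0.8 by default) with a
  private random field; q realizes a log-normal target range size, giving
  the strongly skewed range-size distribution that drives PE. Designated
  micro-endemics are clamped to ≤ 2 contiguous cells to exercise the
  restricted-range filter. Default study conditions: 27 species, one
  micro-endemic, 30 × 30 grid of 10-unit cells.

What this emulates — and what it does not: the generator produces
spatially coherent environments, skewed ranges and label-permutable
communities, so it validates the *computations* (conservation laws,
null exactness, parameter recovery). It has no niche evolution,
dispersal limitation, phylogenetic signal in ranges, or observation
error, so passing tests say nothing about whether those processes shape
a real fauna — only that the statistics measure what they claim.

## Problem sizes used in validation

The test and acceptance runs use deliberately small systems chosen so
the whole suite runs in well under a minute while keeping each check
statistically sharp: conservation laws on 100 random 6 × 6-grid
datasets; exhaustive 720-permutation enumeration on a 6-tip tree against
9,999 replicates; SAR parameter recovery on a 30 × 30 grid (n = 900,
λ = 0.6, β = (1, 0.5, −0.5), ±3 SE coverage over 100 seeds); driver
recovery with 6 candidates (64 subsets × 100 seeds) on a 16 × 16 grid;
and a 12-species / 20 × 20 / 99-replicate demo pipeline for end-to-end
determinism.

## Known limitations

- Raster I/O covers ESRI ASCII grids; there is no GeoTIFF reader and no
  reprojection — inputs must share a coordinate system, and coordinates
  are treated as abstract Euclidean map units (the unit is carried as
  metadata only). Coastal/partial cells are treated like any other cell.
- The dense eigendecomposition bounds practical weights matrices to
  ~5 × 10³ cells.
- The independent-swap chain length heuristic is not a mixing proof;
  very dense or very sparse matrices may need longer chains.
- p-value conventions for permutation nulls vary across packages; the
  half-tie rule here is documented, not claimed identical to any
  particular reference implementation.
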