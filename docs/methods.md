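# Methods

## Observation model

Spot counts are modelled as a Poisson-Gamma mixture: conditional on a
multiplicative random effect `V_ig ~ Gamma(alpha_i, alpha_i)` (mean 1,
variance `1/alpha_i`), `y_ig` is Poisson with mean
`Phi_i * lambda_ig * V_ig`, where `Phi_i` is the spot's total UMI count
and `lambda_ig = beta_i0 + sum_t beta_it * s_tg` a non-negative linear
mixture of the cell-type signatures. Marginally `y_ig` is negative
binomial with mean `mu = Phi_i * lambda_ig` and variance
`mu + mu^2/alpha_i`; as `alpha_i -> inf` (or with `V` fixed at 1 via
`overdispersion=False`) the model reduces to Poisson. We use the standard
closed form of the Gamma-Poisson marginal,

```
log P(y) = lgamma(y+a) - lgamma(a) - lgamma(y+1)
           + a*log(a/(a+mu)) + y*log(mu/(a+mu)),
```

and verify it in the test suite against numerical quadrature of the
mixture integral rather than trusting the algebra. `mu = 0` is treated as
a point mass at zero; for `y > 0` a finite sentinel (-1e10) stands in for
`-inf` so optimizer line searches remain finite.

`Phi_i` is computed over the full input gene panel before marker-gene
subsetting: it is the spot's sequencing depth, and restricting the
analysis to a marker panel must not change it. One dispersion `alpha_i`
is shared by all genes of a spot.

## Geographically weighted fitting

Each spot maximises the weighted sum of its neighbours' full-profile
log-likelihoods, all evaluated at the focal spot's parameters. The
neighbour set contains the spot itself plus all spots within the
bandwidth; the self-weight is exactly 1.

The fit is a bound-constrained quasi-Newton maximisation (L-BFGS-B with
analytic gradients) over `beta >= 0` and `alpha >= 1e-4`, initialised from
non-negative least squares of the depth-normalised focal profile on the
signatures (intercept 0) and `alpha = 10`. Convergence uses a relative
log-likelihood tolerance of 1e-6 with at most 500 iterations; the returned
likelihood never falls below its value at initialisation. At depths of a
few thousand UMIs the likelihood is very flat in `alpha` near its optimum,
so the reported dispersion often stays near its initialisation; this has
no measurable effect on the likelihood (differences < 1e-3 relative) or on
the proportions, which are the quantity of interest.

Proportions are `beta_it / sum_t' beta_it'` with the intercept excluded —
the intercept captures a spot-specific baseline, not a cell type. Spots
whose loadings are all zero (e.g. empty spots) receive uniform proportions
and a degenerate flag; failed fits are recorded and the run aborts only if
more than 10% of spots fail.

## Spatial weights

- **Kernel.** Bi-square, `w(d) = [1-(d/b)^2]^2` for `d <= b`, else 0.
  The default bandwidth is 1.2x the median nearest-neighbour distance:
  first-order neighbours get positive weight, second-order neighbours
  (>= sqrt(2) x pitch on a square lattice, sqrt(3) x on a hex lattice) get
  zero. Coordinates are arbitrary Euclidean units; nothing is
  platform-specific.
- **Pre-clustering mask.** Spots are clustered on expression (library-size
  normalise, log1p, top-2000 variable genes, PCA, Leiden at resolution
  0.5 by default; k-means on the PCs for datasets too small for a
  neighbour graph). Neighbour weights across cluster boundaries are set
  to zero. The clustering backend is pluggable and the method is robust
  to the choice.
- **Elastic adjustment.** Surviving non-self weights become
  `w^(rho * (1 - Sim))` with `Sim` the cosine similarity of the two
  spots' library-normalised log1p expression over the deconvolution gene
  panel (raw-count vectors are switchable). `0^0` is defined as 0 so a
  masked or out-of-bandwidth neighbour can never be resurrected.

**Choice of `rho`.** Cosine similarities of neighbouring spots' expression
profiles are compressed near 1 (typically 0.97-0.999), so any fixed
`rho` of order 1 gives exponents `rho*(1-Sim) << 1`, which *promotes every
surviving weight towards 1* — a one-sided adjustment that over-pools
homogeneous regions and cannot shrink a dissimilar neighbour below its
kernel weight. The default is therefore adaptive:
`rho = 1 / median(1 - Sim)` over the neighbour pairs the adjustment
applies to. A neighbour of median similarity keeps its kernel weight,
more similar neighbours are promoted, less similar ones shrunk — the
intended two-sided behaviour on the similarity scale the data actually
has. A fixed numeric `rho` remains available in the configuration; note
the literal `rho = 0` limit sets every surviving weight to 1 and is
distinct from disabling the elastic stage (which keeps kernel weights).

SONAR-0, the ablation without mask and elastic stage, is available via
`precluster=False, elastic=False` (CLI `--sonar0`).

## Reference signatures and platform correction

Cell types with fewer than 5 cells are dropped. Cells are scaled to a
common library size (the median cell depth) and averaged within type.
Marker genes are kept when some type expresses them above 0.02% of the
per-cell library and at least 0.75 natural-log fold change over the mean
across all types (focal type included; pseudocount 1e-9). With only two
cell types that inclusive denominator caps the achievable fold change at
ln 2 ~= 0.69, so two-type references need a lower threshold.

Platform effects between the scRNA-seq reference and the spatial assay are
corrected gene-wise: the spatial data is collapsed to one pseudo-bulk
composition, its type proportions estimated by least squares on the
signature profiles (clipped at zero and renormalised), and each gene
rescaled by the ratio of observed to predicted bulk expression,
`s_tg = s_raw_tg * e^{gamma_g}`.

**Identifiability limit.** `gamma` is identified only up to components of
the log-factor field orthogonal to the span of the signature profiles: a
platform shift concentrated on one cell type's markers is absorbed into
that type's estimated bulk proportion and re-emerges as a coherent error
on those markers. In practice this means (a) recovery of isolated strong
effects (e.g. a doubled gene) is accurate at realistic pseudo-bulk depth,
but (b) correction is only guaranteed to help downstream when the platform
field is large relative to this projection error — with mild, sparse
effects the Poisson-Gamma fit (whose free dispersion absorbs gene-level
multiplicative noise shared across types) can be more accurate uncorrected.
Correction is on by default and switchable off.

## Synthetic data

The generator emulates a multi-type scRNA-seq reference and the two
pseudo-spot simulation schemes.

- **Reference.** Types share a lognormal baseline rate profile; each type's
  disjoint marker block (15 of 200 genes by default) is elevated 5-10x.
  Cells draw NB counts (dispersion 2) with lognormal depth variation
  around 500 UMIs/cell — so a typical dominant-type spot (~6 cells plus
  sparse types) carries ~3000+ UMIs. Defaults: 4 types, 30 cells/type.
- **Spots.** A spot's designed composition maps types to expected cell
  numbers (dominant 6, sparse 0.1, at most four types positive).
  Realised numbers are Poisson draws; that many cells are sampled with
  replacement from the reference pool and summed. Realised cell counts
  are the ground truth.
- **Homo-Area.** 20x20 grid, one composition, four scenario families:
  dominant abundance (8 to 2), number of dominant types (4 to 1),
  relative proportion of two dominants (even to uneven), sparse abundance
  (0.3 to 0) — 16 configurations; with 5 replicates each, 80 datasets.
- **Compo-Area.** 20x40 grid of homogeneous subregions (one dominant +
  three shared sparse types each): layer patterns (2-5 vertical bands),
  hierarchically halved blocks (2/4/8, alternating axes), circular
  background patches (radius 4), and two-region abundance contrasts — 19
  configurations, 95 datasets with 5 replicates. Transitions between
  layers: jump (hard boundary), gradient (linear interpolation across a
  4-column buffer at positions (k+1)/(w+1)), mix (buffer spots get the
  arithmetic mean of the flanking compositions). Buffer compositions are
  trimmed to their four largest expectations to respect the four-type cap.
- **Gridding.** Single-cell-resolution data are binned into half-open
  square bins from the minimum coordinate; bin sums become pseudo-spot
  counts, bin centres the coordinates, label tallies the truth. Counts
  and cells are conserved; empty bins are dropped.

What the generator does *not* emulate: gene-gene correlation beyond the
shared baseline, segmentation errors, spatial covariates of depth, and
real platform chemistry; passing tests demonstrate correctness of the
machinery and the qualitative behaviour of the weighting stages, not
performance on real tissue.

## Metrics

RMSE per cell type (root mean square proportion error over spots, plus a
pooled version), Jensen-Shannon divergence per spot (natural log, maximum
ln 2; base-2 switchable), and mean rank (MR): per dataset, methods are
ranked per cell type by RMSE and per spot by JSD, the two average ranks
averaged; across a collection, per-dataset mean-JSD ranks and per-type
RMSE mean-ranks are averaged over datasets. Ties share average ranks.
Spots with empty ground truth are excluded from JSD averages and counted.
The LoCo score of a cell-type pair at a spot is the Spearman correlation
of the two types' proportions over the spot's bandwidth neighbourhood
(no cluster masking); neighbourhoods smaller than 3 spots or with constant
proportions give NaN.

## Numerical and design choices

- NB log-pmf vs the Poisson limit: the exact gap is
  `((y-mu)^2 - y)/(2*alpha)`, so pointwise agreement at `alpha = 1e8` holds
  to 1e-5 only for moderate `y`; tail disagreement is mathematics, not
  error. Tests assert the pointwise limit for `y <= 30` and the
  total-variation limit over the full range.
- Zero expression vectors get cosine similarity 0 (maximally dissimilar
  for weighting purposes) with a warning when both are zero.
- Duplicate coordinates are allowed (mutual neighbours at distance 0,
  warned); a fully coincident dataset cannot auto-select a bandwidth.
- Determinism: every stochastic step (simulation, clustering, fitting
  order) is driven by explicit seeds; rerunning a configuration
  byte-reproduces its outputs. Replicates use `base_seed + replicate`.
- Problem sizes in the test suite and acceptance script (20x20 and 20x40
  grids, 200-gene panels, 3 replicates) are the simulation schemes' native
  sizes; they run end-to-end in a few minutes on one CPU.

## Known limitations

- The dispersion `alpha_i` is weakly identified at typical spot depths;
  treat it as a nuisance parameter, not an estimate of biological
  overdispersion.
- Platform correction inherits the pseudo-bulk identifiability limit
  described above; with an external reference whose types are missing
  from the tissue, the corresponding factors are untrustworthy.
- Per-spot estimates in homogeneous tissue track the locally pooled
  composition by design; spot-level fluctuations (realised cell sampling
  noise) are deliberately smoothed, which bounds per-spot truth-estimate
  correlation below what an unpooled fit achieves there, in exchange for
  lower divergence at region boundaries.
- Bandwidth selection by cross-validation/AIC, anisotropic kernels,
  absolute cell abundance estimation, and GPU execution are out of scope.
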