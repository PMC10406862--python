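# sonar

Cell-type deconvolution for sequencing-based spatial transcriptomics with a
spatially weighted Poisson-Gamma (negative binomial) regression.

Each capture spot in platforms like Visium or Spatial Transcriptomics mixes
transcripts from several cells. Given an annotated scRNA-seq reference,
`sonar` estimates the per-spot cell-type proportions while borrowing
strength from spatial neighbours — useful for anyone mapping cell types
onto tissue sections from spot-level counts.

## Model

Counts are modelled per spot *i* and gene *g* as

```
y_ig | V_ig ~ Poisson(Phi_i * lambda_ig * V_ig),   V_ig ~ Gamma(alpha_i, alpha_i)
lambda_ig = beta_i0 + sum_t beta_it * s_tg
```

where `Phi_i` is the spot's total UMI count, `s_tg` the reference signature
of cell type *t* (platform-corrected against the spatial data), `beta_it >= 0`
the type loadings (normalised to proportions), and `alpha_i` a per-spot
dispersion; marginalising `V` gives a negative binomial with variance
`mu + mu^2/alpha`. Each spot's parameters maximise a geographically
weighted local likelihood over its neighbour set `N_i`:

```
T(beta_i, alpha_i) = sum_{n in N_i} L_n(beta_i, alpha_i) * w~_ni
```

The weights `w~_ni` start from a bi-square kernel
`w(d) = [1 - (d/b)^2]^2` (bandwidth `b` = 1.2x the median nearest-neighbour
distance, so only first-order neighbours count), are zeroed between spots
assigned to different expression pre-clusters, and are elastically tuned by
expression similarity, `w~ = w^(rho * (1 - cos_sim))`, so similar
neighbours gain weight and dissimilar ones lose it. Disabling the mask and
the elastic stage gives the pure-kernel ablation ("SONAR-0").

## Worked example

```python
import numpy as np
from sonar import simulate as sim
from sonar import SONARModel, build_reference
from sonar.metrics import jsd

ref_counts, ref_labels = sim.make_synthetic_reference(n_types=3, seed=1)
types = sorted(ref_labels.unique())
design = sim.design_homo_area("n_dominant", 3, types, seed=1)
dataset, truth = sim.realize_design(design, ref_counts, ref_labels, seed=1)

signature = build_reference(ref_counts, ref_labels.reset_index(drop=True), dataset)
model = SONARModel(dataset.subset_genes(signature.gene_ids), signature, seed=1)
result = model.fit()
print(result.summary())

tp = truth.aligned_proportions(result.cell_type_ids)
print("mean JSD vs truth:", np.mean(jsd(result.proportions, tp)).round(4))
```

prints

```
SONAR deconvolution results
============================================
spots: 400    cell types: 3
converged: 400/400    degenerate: 0    failed: 0
total local log-likelihood: -84893.37
median dispersion alpha: 10
--------------------------------------------
cell type                 mean prop.
type_0                        0.3187
type_1                        0.3189
type_2                        0.3625
mean JSD vs truth: 0.0035
```

The three types were simulated at equal expected abundance (6 cells each
per spot); the estimated mean proportions sit near one third each, and the
per-spot Jensen-Shannon divergence from the realised ground truth is
~0.0035 (0 is perfect, ln 2 is maximal).

The same pipeline is scriptable from the shell:

```
sonar simulate --scheme compo --pattern layer --transition jump --seed 3 --out sim/
sonar fit --counts sim/counts.csv --coords sim/coords.tsv \
          --ref-counts sim/ref_counts.csv --ref-labels sim/ref_labels.tsv --out run/
sonar eval --truth sim/truth.csv --pred sonar run/proportions.csv --out eval/
```

## Layout

- `sonar.model` — likelihood, per-spot ML fit, `SONARModel`/`SONARResults`
- `sonar.weights` — kernel, pre-clustering mask, elastic weighting
- `sonar.reference` — signature building and platform-effect correction
- `sonar.simulate` — synthetic reference and ground-truthed pseudo-spots
- `sonar.metrics` — RMSE, JSD, mean-rank aggregation, LoCo score
- `sonar.io` / `sonar.cli` — file formats, run configuration, CLI

See `docs/methods.md` for the modelling details and known limitations.
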