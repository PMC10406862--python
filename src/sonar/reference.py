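"""Cell-type signature construction from annotated scRNA-seq counts.

The signature matrix ``S`` (cell types x genes) provides the regression
covariates for deconvolution.  It is built in four steps:

1. drop cell types with fewer than 5 cells;
2. library-size normalise every cell to a common depth (the median cell
   depth) and average within each type -> raw signatures ``S_raw``;
3. keep marker genes: for some type, mean normalised expression above
   0.02% of the per-cell library AND at least 0.75 natural-log fold
   change over the across-type average;
4. correct gene-level platform effects between the scRNA-seq reference
   and the spatial measurement: regress the spatial pseudo-bulk
   composition on the type profiles, and rescale each gene by the ratio
   of observed to predicted bulk expression,
   ``s_{t,g} = s_raw_{t,g} * e^{gamma_g}``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SpatialDataset

__all__ = [
    "ReferenceSignature",
    "build_raw_signature",
    "select_marker_genes",
    "estimate_platform_effect",
    "apply_platform_correction",
    "build_reference",
]

MIN_CELLS_PER_TYPE = 5
_LFC_PSEUDOCOUNT = 1e-9


@dataclass
class ReferenceSignature:
    """Signature matrices on the selected marker-gene panel.

    ``gamma`` stores the gene-level platform effect as the multiplicative
    factor ``e^{gamma_g}``, so ``S_corrected = S_raw * gamma`` exactly.
    """

    S_raw: np.ndarray  # types x genes
    S_corrected: np.ndarray
    gamma: np.ndarray  # length genes, multiplicative
    cell_type_ids: list[str]
    gene_ids: list[str]
    n_cells_per_type: dict[str, int]

    @property
    def n_types(self) -> int:
        return len(self.cell_type_ids)

    def to_dataframe(self, corrected: bool = True) -> pd.DataFrame:
        S = self.S_corrected if corrected else self.S_raw
        return pd.DataFrame(S, index=self.cell_type_ids, columns=self.gene_ids)


def build_raw_signature(
    ref_counts: pd.DataFrame, labels: pd.Series, min_cells: int = MIN_CELLS_PER_TYPE
) -> tuple[pd.DataFrame, dict[str, int], float]:
    """Per-type mean of library-size-normalised cells.

    Parameters
    ----------
    ref_counts : DataFrame, cells x genes
    labels : Series of cell-type labels aligned to ``ref_counts`` rows

    Returns
    -------
    profiles : DataFrame, types x genes — mean normalised expression
    n_cells : dict type -> cell count (retained types only)
    library_size : the common depth cells were scaled to (median cell depth)
    """
    labels = pd.Series(labels).reset_index(drop=True)
    counts = np.asarray(ref_counts, dtype=np.float64)
    if len(labels) != counts.shape[0]:
        raise ValueError("labels must cover all cells")
    sizes = labels.value_counts()
    keep_types = sizes[sizes >= min_cells].index.tolist()
    dropped = sizes[sizes < min_cells].index.tolist()
    if dropped:
        warnings.warn(f"dropping cell types with <{min_cells} cells: {dropped}",
                      stacklevel=2)
    if not keep_types:
        raise ValueError(f"no cell type has >= {min_cells} cells")
    depth = counts.sum(axis=1)
    positive = depth > 0
    library_size = float(np.median(depth[positive])) if positive.any() else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        normed = np.where(depth[:, None] > 0, counts / depth[:, None] * library_size, 0.0)
    rows, n_cells = [], {}
    for t in sorted(map(str, keep_types)):
        mask = (labels.astype(str) == t).to_numpy()
        rows.append(normed[mask].mean(axis=0))
        n_cells[t] = int(mask.sum())
    genes = list(ref_counts.columns) if isinstance(ref_counts, pd.DataFrame) \
        else [f"gene_{g}" for g in range(counts.shape[1])]
    profiles = pd.DataFrame(rows, index=list(n_cells), columns=genes)
    return profiles, n_cells, library_size


def select_marker_genes(
    mean_profiles: pd.DataFrame,
    library_size: float,
    min_frac: float = 0.0002,
    min_lfc: float = 0.75,
) -> list[str]:
    """Union over types of genes that are both abundant and type-enriched.

    A gene is kept if some type expresses it above ``min_frac`` of the
    per-cell library AND at least ``min_lfc`` natural-log fold change over
    the mean expression across all types (focal type included).
    """
    if mean_profiles.shape[0] < 2:
        raise ValueError("marker selection needs >= 2 cell types")
    P = mean_profiles.to_numpy(dtype=np.float64)
    abundant = P > min_frac * library_size
    across = P.mean(axis=0, keepdims=True)
    lfc = np.log((P + _LFC_PSEUDOCOUNT) / (across + _LFC_PSEUDOCOUNT))
    keep = np.any(abundant & (lfc >= min_lfc), axis=0)
    if not keep.any():
        raise ValueError(
            "no gene passed marker selection; relax min_frac/min_lfc thresholds"
        )
    return [g for g, k in zip(mean_profiles.columns, keep) if k]


def estimate_platform_effect(
    S_raw: np.ndarray, spatial: SpatialDataset | np.ndarray
) -> np.ndarray:
    """Gene-level platform factors ``e^{gamma_g}`` between reference and spatial.

    The spatial data is collapsed to one pseudo-bulk composition; its type
    proportions are estimated by OLS on the reference profiles (clipped at
    zero and renormalised); the ratio of observed to predicted bulk
    composition per gene is the multiplicative platform effect.  Genes the
    reference predicts at zero keep factor 1 (nothing to rescale against).
    """
    S_raw = np.asarray(S_raw, dtype=np.float64)
    bulk = spatial.counts.sum(axis=0) if isinstance(spatial, SpatialDataset) \
        else np.asarray(spatial, dtype=np.float64)
    if bulk.shape[0] != S_raw.shape[1]:
        raise ValueError("spatial and reference gene sets must be aligned")
    if bulk.sum() == 0:
        raise ValueError("spatial pseudo-bulk is all zero")
    if np.linalg.matrix_rank(S_raw) < S_raw.shape[0]:
        raise ValueError("signature matrix is rank-deficient; "
                         "remove collinear cell types")
    bulk_comp = bulk / bulk.sum()
    pi, *_ = np.linalg.lstsq(S_raw.T, bulk_comp, rcond=None)
    pi = np.clip(pi, 0.0, None)
    if pi.sum() == 0:
        raise ValueError("pseudo-bulk regression gave all-zero proportions")
    pi = pi / pi.sum()
    predicted = pi @ S_raw
    predicted = predicted / predicted.sum()
    factors = np.ones_like(predicted)
    zero_pred = predicted == 0
    if zero_pred.any():
        warnings.warn(
            f"{int(zero_pred.sum())} gene(s) predicted at zero from the "
            "reference; platform factor left at 1", stacklevel=2,
        )
    ok = ~zero_pred
    factors[ok] = bulk_comp[ok] / predicted[ok]
    return factors


def apply_platform_correction(S_raw: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """``S_corrected[t, g] = S_raw[t, g] * gamma_g`` (gamma multiplicative)."""
    S_raw = np.asarray(S_raw, dtype=np.float64)
    gamma = np.asarray(gamma, dtype=np.float64)
    if gamma.shape[0] != S_raw.shape[1]:
        raise ValueError("gamma must have one factor per gene")
    return S_raw * gamma[None, :]


def build_reference(
    ref_counts: pd.DataFrame,
    labels: pd.Series,
    spatial: SpatialDataset,
    min_frac: float = 0.0002,
    min_lfc: float = 0.75,
    correct_platform: bool = True,
) -> ReferenceSignature:
    """Full reference pipeline: filter, normalise, select markers, correct.

    Markers are selected on the reference first, intersected with the
    spatial gene universe, then the platform effect is estimated on that
    shared panel.  With ``correct_platform=False`` the factors are all 1.
    """
    profiles, n_cells, library_size = build_raw_signature(ref_counts, labels)
    markers = select_marker_genes(profiles, library_size, min_frac, min_lfc)
    spatial_genes = set(spatial.gene_ids)
    markers = [g for g in markers if g in spatial_genes]
    if not markers:
        raise ValueError("no marker gene is present in the spatial data")
    S_raw = profiles[markers].to_numpy()
    spatial_sub = spatial.subset_genes(markers)
    if correct_platform:
        gamma = estimate_platform_effect(S_raw, spatial_sub)
    else:
        gamma = np.ones(len(markers))
    return ReferenceSignature(
        S_raw=S_raw,
        S_corrected=apply_platform_correction(S_raw, gamma),
        gamma=gamma,
        cell_type_ids=list(profiles.index),
        gene_ids=markers,
        n_cells_per_type=n_cells,
    )
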