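"""Core data containers for spatial deconvolution.

A :class:`SpatialDataset` holds the raw spot-by-gene count matrix together
with spot coordinates and per-spot sequencing depths.  Depths are computed
once, on the full input gene set, *before* any marker-gene subsetting: the
depth of a spot is defined as its total UMI count, and restricting to a
marker panel must not change it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpatialDataset", "GroundTruth"]


@dataclass
class SpatialDataset:
    """Spot-level expression counts with spatial coordinates.

    Parameters
    ----------
    counts : ndarray of shape (n_spots, n_genes)
        Non-negative integer UMI counts.
    coords : ndarray of shape (n_spots, 2)
        Euclidean spot coordinates (arbitrary units: pixels or microns).
    spot_ids, gene_ids : sequences of str
        Unique spot barcodes and gene names.
    depth : ndarray of shape (n_spots,), optional
        Total UMIs per spot.  Computed from ``counts`` row sums when not
        given; pass explicitly after gene subsetting so the full-panel
        depth is preserved.
    """

    counts: np.ndarray
    coords: np.ndarray
    spot_ids: list[str] = field(default=None)
    gene_ids: list[str] = field(default=None)
    depth: np.ndarray = field(default=None)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D spots x genes matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if np.any(self.counts != np.floor(self.counts)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.float64)
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (self.n_spots, 2):
            raise ValueError(
                f"coords must have shape ({self.n_spots}, 2), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")
        if self.spot_ids is None:
            self.spot_ids = [f"spot_{i}" for i in range(self.n_spots)]
        else:
            self.spot_ids = [str(s) for s in self.spot_ids]
        if len(set(self.spot_ids)) != self.n_spots:
            raise ValueError("spot_ids must be unique")
        if self.gene_ids is None:
            self.gene_ids = [f"gene_{g}" for g in range(self.n_genes)]
        else:
            self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length must match counts columns")
        if self.depth is None:
            self.depth = self.counts.sum(axis=1)
        else:
            self.depth = np.asarray(self.depth, dtype=np.float64)
            if self.depth.shape != (self.n_spots,):
                raise ValueError("depth must be one value per spot")
        if np.any(self.depth == 0):
            warnings.warn(
                f"{int(np.sum(self.depth == 0))} spot(s) have zero total counts",
                stacklevel=2,
            )

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes: list[str]) -> "SpatialDataset":
        """Restrict to a gene panel, keeping the full-panel per-spot depth."""
        index = {g: j for j, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in dataset: {missing[:5]}")
        cols = [index[g] for g in genes]
        return SpatialDataset(
            counts=self.counts[:, cols],
            coords=self.coords,
            spot_ids=list(self.spot_ids),
            gene_ids=list(genes),
            depth=self.depth.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.spot_ids, columns=self.gene_ids)


@dataclass
class GroundTruth:
    """True per-spot cell counts and proportions (simulation only).

    Rows with zero total cells carry no defined proportion; they are kept
    (flagged via :attr:`empty_spots`) so spot indexing stays aligned, and
    excluded from divergence averages by the metrics layer.
    """

    cell_counts: np.ndarray  # spots x types, integers
    cell_type_ids: list[str]
    region_label: np.ndarray = None  # integer region per spot
    spot_ids: list[str] = None

    def __post_init__(self):
        self.cell_counts = np.asarray(self.cell_counts, dtype=np.float64)
        n = self.cell_counts.shape[0]
        if self.spot_ids is None:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        if self.region_label is None:
            self.region_label = np.zeros(n, dtype=int)
        self.region_label = np.asarray(self.region_label)

    @property
    def empty_spots(self) -> np.ndarray:
        """Boolean mask of spots with zero cells (undefined proportions)."""
        return self.cell_counts.sum(axis=1) == 0

    @property
    def proportions(self) -> np.ndarray:
        """Simplex rows; empty spots get uniform rows (see empty_spots)."""
        totals = self.cell_counts.sum(axis=1, keepdims=True)
        T = self.cell_counts.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = self.cell_counts / totals
        p[totals[:, 0] == 0] = 1.0 / T
        return p

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.proportions, index=self.spot_ids, columns=self.cell_type_ids
        )

    def aligned_proportions(self, cell_type_ids: list[str]) -> np.ndarray:
        """True proportions reindexed to a type universe (absent types = 0)."""
        return (
            self.to_dataframe()
            .reindex(columns=list(cell_type_ids), fill_value=0.0)
            .to_numpy()
        )
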