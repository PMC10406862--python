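"""Readers, writers, run configuration, and the end-to-end fit pipeline.

Counts are accepted either as MatrixMarket coordinate triplets (1-based,
rows = spots) with companion ``barcodes.tsv`` / ``genes.tsv`` name files,
or as a dense CSV whose header row holds gene names and whose first column
holds spot ids.  Coordinates are a TSV with columns (spot_id, x, y).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .data import SpatialDataset
from .model import FitConfig, SONARModel
from .reference import (
    ReferenceSignature,
    apply_platform_correction,
    build_reference,
    estimate_platform_effect,
)

__all__ = [
    "FormatError",
    "RunConfig",
    "read_counts",
    "write_counts_csv",
    "write_counts_mtx",
    "read_coords",
    "read_labels",
    "read_signature",
    "run_fit",
]

log = logging.getLogger("sonar")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class RunConfig:
    """Resolved settings of a deconvolution run; serialisable to YAML."""

    counts: str = ""
    coords: str = ""
    ref_counts: str = ""
    ref_labels: str = ""
    signature: str = ""
    outdir: str = "sonar_out"
    bandwidth: float | None = None  # None = auto (1.2 x median NN distance)
    rho: float | str = "auto"
    precluster: bool = True
    precluster_method: str = "leiden"
    precluster_resolution: float = 0.5
    elastic: bool = True
    sonar0: bool = False
    no_overdispersion: bool = False
    platform_correction: bool = True
    min_frac: float = 0.0002
    min_lfc: float = 0.75
    tol: float = 1e-6
    max_iter: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _validate_integer_matrix(M: np.ndarray, spot_ids, gene_ids) -> np.ndarray:
    bad = np.argwhere((M < 0) | (M != np.floor(M)))
    if len(bad):
        i, j = bad[0]
        raise FormatError(
            f"counts must be non-negative integers; offending entry at "
            f"spot {spot_ids[i]!r}, gene {gene_ids[j]!r}: {M[i, j]}"
        )
    return M


def read_counts(path, fmt: str = "auto"):
    """Read a spot x gene count matrix.

    Returns ``(counts, spot_ids, gene_ids)``.  ``fmt='mtx'`` expects
    ``barcodes.tsv`` (row names) and ``genes.tsv`` (column names) next to
    the matrix file; ``fmt='csv'`` a dense table with gene header and spot
    id first column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = "mtx" if path.suffix == ".mtx" else "csv"
    if fmt == "mtx":
        try:
            M = scipy.io.mmread(path)
        except Exception as err:
            raise FormatError(f"cannot parse MatrixMarket file {path}: {err}") from err
        M = np.asarray(M.todense() if scipy.sparse.issparse(M) else M, dtype=np.float64)
        barcodes = path.parent / "barcodes.tsv"
        genes = path.parent / "genes.tsv"
        for companion in (barcodes, genes):
            if not companion.exists():
                raise FormatError(f"missing companion name file {companion}")
        spot_ids = barcodes.read_text().split()
        gene_ids = genes.read_text().split()
        if len(spot_ids) != M.shape[0] or len(gene_ids) != M.shape[1]:
            raise FormatError(
                f"matrix is {M.shape} but names give "
                f"{len(spot_ids)} spots x {len(gene_ids)} genes"
            )
    else:
        df = pd.read_csv(path, index_col=0)
        spot_ids = [str(s) for s in df.index]
        gene_ids = [str(g) for g in df.columns]
        try:
            M = df.to_numpy(dtype=np.float64)
        except ValueError as err:
            raise FormatError(f"non-numeric entry in {path}: {err}") from err
    if len(set(spot_ids)) != len(spot_ids):
        dup = pd.Series(spot_ids).value_counts()
        raise FormatError(f"duplicate spot id(s): {dup[dup > 1].index.tolist()[:5]}")
    _validate_integer_matrix(M, spot_ids, gene_ids)
    return M, spot_ids, gene_ids


def write_counts_csv(path, counts, spot_ids, gene_ids) -> None:
    pd.DataFrame(np.asarray(counts, dtype=np.int64), index=spot_ids,
                 columns=gene_ids).to_csv(path)


def write_counts_mtx(path, counts, spot_ids, gene_ids) -> None:
    """Write counts as 1-based coordinate MTX + barcodes.tsv / genes.tsv."""
    path = Path(path)
    sparse = scipy.sparse.coo_matrix(np.asarray(counts))
    scipy.io.mmwrite(path, sparse, field="integer")
    (path.parent / "barcodes.tsv").write_text("\n".join(map(str, spot_ids)) + "\n")
    (path.parent / "genes.tsv").write_text("\n".join(map(str, gene_ids)) + "\n")


def read_coords(path) -> pd.DataFrame:
    """Coordinates TSV with columns (spot_id, x, y); spot_id as index."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError("coordinates file needs columns (spot_id, x, y)")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return df.iloc[:, :2].astype(float)


def read_labels(path) -> pd.Series:
    """Cell labels TSV with columns (cell_id, cell_type)."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError("labels file needs columns (cell_id, cell_type)")
    return pd.Series(df.iloc[:, 1].astype(str).to_numpy(),
                     index=df.iloc[:, 0].astype(str), name="cell_type")


def read_signature(path) -> pd.DataFrame:
    """Precomputed signature CSV: rows = cell types, columns = genes."""
    df = pd.read_csv(path, index_col=0)
    if (df.to_numpy(dtype=np.float64) < 0).any():
        raise FormatError("signature entries must be non-negative")
    return df


def _build_dataset(config: RunConfig):
    counts, spot_ids, gene_ids = read_counts(config.counts)
    coords = read_coords(config.coords)
    missing = [s for s in spot_ids if s not in coords.index]
    if missing:
        raise FormatError(f"spots missing coordinates: {missing[:5]}")
    xy = coords.loc[spot_ids].to_numpy()
    return SpatialDataset(counts=counts, coords=xy, spot_ids=spot_ids,
                          gene_ids=gene_ids)


def _build_signature(config: RunConfig, dataset: SpatialDataset):
    if config.signature:
        sig = read_signature(config.signature)
        genes = [g for g in sig.columns if g in set(dataset.gene_ids)]
        if not genes:
            raise FormatError("signature and spatial data share no genes")
        S_raw = sig[genes].to_numpy(dtype=np.float64)
        sub = dataset.subset_genes(genes)
        if config.platform_correction:
            gamma = estimate_platform_effect(S_raw, sub)
        else:
            gamma = np.ones(len(genes))
        return ReferenceSignature(
            S_raw=S_raw,
            S_corrected=apply_platform_correction(S_raw, gamma),
            gamma=gamma,
            cell_type_ids=[str(t) for t in sig.index],
            gene_ids=genes,
            n_cells_per_type={},
        )
    ref_counts, _, ref_gene_ids = read_counts(config.ref_counts)
    ref_df = pd.DataFrame(ref_counts, columns=ref_gene_ids)
    labels = read_labels(config.ref_labels)
    return build_reference(
        ref_df, labels.reset_index(drop=True), dataset,
        min_frac=config.min_frac, min_lfc=config.min_lfc,
        correct_platform=config.platform_correction,
    )


def run_fit(config: RunConfig):
    """Full pipeline: read, build signature, weight, fit, write artifacts.

    Writes ``proportions.csv``, ``params.csv``, ``signature.csv``,
    ``gamma.csv``, ``weights.tsv``, ``clusters.tsv``, ``config.yaml`` and
    a per-stage timing log into ``config.outdir``.  Partial outputs are
    removed if any stage fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    try:
        stage("read")
        dataset = _build_dataset(config)
        done("read")

        stage("signature")
        signature = _build_signature(config, dataset)
        aligned = dataset.subset_genes(signature.gene_ids)
        if len(signature.gene_ids) < 50:
            log.warning(
                "only %d shared genes after selection", len(signature.gene_ids)
            )
        done("signature")

        stage("fit")
        fit_cfg = FitConfig(
            tol=config.tol, max_iter=config.max_iter,
            overdispersion=not config.no_overdispersion,
        )
        model = SONARModel(
            aligned, signature,
            bandwidth=config.bandwidth, rho=config.rho,
            precluster=config.precluster and not config.sonar0,
            elastic=config.elastic and not config.sonar0,
            precluster_method=config.precluster_method,
            precluster_resolution=config.precluster_resolution,
            seed=config.seed, config=fit_cfg,
        )
        result = model.fit()
        done("fit")

        stage("write")
        p = outdir / "proportions.csv"
        result.proportions_df.round(10).to_csv(p, index_label="spot_id")
        written.append(p)
        p = outdir / "params.csv"
        result.params_df().to_csv(p, index_label="spot_id")
        written.append(p)
        signature.to_dataframe().to_csv(outdir / "signature.csv")
        pd.DataFrame({"gene": signature.gene_ids, "factor": signature.gamma}
                     ).to_csv(outdir / "gamma.csv", index=False)
        scheme = model.weight_scheme_
        rows = []
        for i, idx in scheme.neighbor_sets.items():
            for j, n in enumerate(idx):
                rows.append((aligned.spot_ids[i], aligned.spot_ids[n],
                             scheme.kernel_weights[i][j],
                             scheme.final_weights[i][j]))
        pd.DataFrame(rows, columns=["focal_spot", "neighbor_spot", "kernel_w",
                                    "final_w"]).to_csv(
            outdir / "weights.tsv", sep="\t", index=False)
        pd.DataFrame({"spot_id": aligned.spot_ids,
                      "cluster": scheme.cluster_labels}).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False)
        config.to_yaml(outdir / "config.yaml")
        with open(outdir / "run_log.json", "w") as fh:
            json.dump({"seed": config.seed, "timings_sec": timings,
                       "n_spots": aligned.n_spots,
                       "n_genes": aligned.n_genes,
                       "bandwidth": scheme.bandwidth}, fh, indent=2)
        done("write")
    except Exception as err:
        for f in written:
            f.unlink(missing_ok=True)
        raise RuntimeError(f"run failed at stage "
                           f"{list(timings)[-1] if timings else 'setup'}: {err}"
                           ) from err
    return result
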