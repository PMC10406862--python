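"""Benchmark metrics for deconvolution accuracy and local co-localization.

RMSE and JSD compare predicted against true proportions; MR (mean rank)
aggregates both into a single cross-method ranking, within one dataset or
across a collection; the LoCo score measures local co-localization of a
cell-type pair as the Spearman correlation of their proportions over each
spot's spatial neighbourhood.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

__all__ = [
    "rmse",
    "jsd",
    "mean_rank_dataset",
    "mean_rank_collection",
    "loco_score",
]


def _check_simplex(P, tol=1e-8, name="P"):
    P = np.asarray(P, dtype=np.float64)
    if np.any(P < 0):
        raise ValueError(f"{name} has negative entries")
    if np.any(np.abs(P.sum(axis=-1) - 1.0) > tol):
        raise ValueError(f"{name} rows must sum to 1 (tolerance {tol})")
    return P


def rmse(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """Root mean square error of proportions.

    Returns ``(per_type, pooled)``: per cell type, the RMS over spots of
    the proportion error; pooled, the RMS over all spot-type entries.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    sq = (pred - truth) ** 2
    return np.sqrt(sq.mean(axis=0)), float(np.sqrt(sq.mean()))


def jsd(P, Q, base: str = "e"):
    """Jensen-Shannon divergence between proportion rows.

    ``JSD(P, Q) = KL(P || M)/2 + KL(Q || M)/2`` with ``M = (P+Q)/2`` and
    the convention ``0 log(0/q) = 0``.  Natural log by default (maximum
    ``ln 2``); ``base="2"`` rescales to bits (maximum 1).  Accepts single
    distributions or matrices of rows; returns a scalar or a per-row array.
    """
    P = _check_simplex(np.atleast_2d(P), name="P")
    Q = _check_simplex(np.atleast_2d(Q), name="Q")
    if P.shape != Q.shape:
        raise ValueError("P and Q must have the same shape")
    M = 0.5 * (P + Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        kl_pm = np.where(P > 0, P * np.log(P / M), 0.0).sum(axis=-1)
        kl_qm = np.where(Q > 0, Q * np.log(Q / M), 0.0).sum(axis=-1)
    out = 0.5 * kl_pm + 0.5 * kl_qm
    if base == "2":
        out = out / np.log(2.0)
    elif base != "e":
        raise ValueError("base must be 'e' or '2'")
    out = np.maximum(out, 0.0)  # guard tiny negative rounding
    return float(out[0]) if out.shape == (1,) else out


def _rank_low_is_best(values: np.ndarray) -> np.ndarray:
    """Competition rank with tie-averaging; smallest value gets rank 1."""
    return rankdata(values, method="average")


def mean_rank_dataset(results: dict[str, np.ndarray], truth: np.ndarray) -> pd.DataFrame:
    """Mean rank (MR) of each method on a single dataset.

    Per cell type, methods are ranked by RMSE; per spot, by JSD; the two
    average ranks are themselves averaged:
    ``MR = (mean_t rank_RMSE(t) + mean_s rank_JSD(s)) / 2``.
    Ties share the average rank.  Lower MR is better.
    """
    if len(results) < 2:
        raise ValueError("MR needs >= 2 methods to rank")
    methods = list(results)
    truth = np.asarray(truth, dtype=np.float64)
    rmse_mat = np.vstack([rmse(results[m], truth)[0] for m in methods])
    jsd_mat = np.vstack([jsd(results[m], truth) for m in methods])
    rank_rmse = np.apply_along_axis(_rank_low_is_best, 0, rmse_mat).mean(axis=1)
    rank_jsd = np.apply_along_axis(_rank_low_is_best, 0, jsd_mat).mean(axis=1)
    return pd.DataFrame(
        {
            "rank_rmse": rank_rmse,
            "rank_jsd": rank_jsd,
            "MR": 0.5 * (rank_rmse + rank_jsd),
        },
        index=methods,
    )


def mean_rank_collection(per_dataset: dict[str, dict[str, dict]]) -> pd.DataFrame:
    """Mean rank of each method across a collection of datasets.

    ``per_dataset[dataset][method]`` holds ``{"rmse_per_type": array,
    "mean_jsd": float}``.  Within each dataset, the RMSE rank is the mean
    over cell types of the method's per-type RMSE rank, and the JSD rank
    ranks the methods' mean JSD; both are averaged over datasets and the
    two halves summed.
    """
    datasets = list(per_dataset)
    if not datasets:
        raise ValueError("empty collection")
    methods = list(per_dataset[datasets[0]])
    if len(methods) < 2:
        raise ValueError("MR needs >= 2 methods to rank")
    for d in datasets:
        if set(per_dataset[d]) != set(methods):
            raise ValueError(f"dataset {d!r} is missing some methods")
    rank_rmse = np.zeros(len(methods))
    rank_jsd = np.zeros(len(methods))
    for d in datasets:
        rmse_mat = np.vstack(
            [np.atleast_1d(per_dataset[d][m]["rmse_per_type"]) for m in methods]
        )
        per_type_ranks = np.apply_along_axis(_rank_low_is_best, 0, rmse_mat)
        rank_rmse += per_type_ranks.mean(axis=1)
        mean_jsds = np.array([per_dataset[d][m]["mean_jsd"] for m in methods])
        rank_jsd += _rank_low_is_best(mean_jsds)
    rank_rmse /= len(datasets)
    rank_jsd /= len(datasets)
    return pd.DataFrame(
        {
            "rank_rmse": rank_rmse,
            "rank_jsd": rank_jsd,
            "MR": 0.5 * (rank_rmse + rank_jsd),
        },
        index=methods,
    )


def loco_score(
    proportions: np.ndarray,
    neighbor_sets: dict[int, np.ndarray],
    type_a: int,
    type_b: int,
) -> np.ndarray:
    """Local co-localization of two cell types, per spot.

    The score at spot ``i`` is the Spearman correlation of the two types'
    proportions over the spots in ``i``'s neighbourhood (the kernel
    bandwidth neighbour set, no cluster masking).  Neighbourhoods smaller
    than 3 spots, or with a constant proportion vector, give NaN.
    """
    P = np.asarray(proportions, dtype=np.float64)
    scores = np.full(P.shape[0], np.nan)
    for i, idx in neighbor_sets.items():
        a, b = P[idx, type_a], P[idx, type_b]
        if len(idx) < 3 or np.all(a == a[0]) or np.all(b == b[0]):
            continue
        rho = spearmanr(a, b).statistic
        scores[i] = rho
    return scores
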