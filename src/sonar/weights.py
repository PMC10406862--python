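"""Spatial neighbour weights: bi-square kernel, cluster mask, elastic tuning.

The local likelihood of a focal spot pools its neighbours through weights
built in three stages:

1. **Kernel** — the bi-square kernel ``w(d) = [1 - (d/b)^2]^2`` for
   ``d <= b``, else 0, over Euclidean distances, with bandwidth ``b``
   defaulting to just beyond the first-order neighbour distance.
2. **Cluster mask** — a coarse expression pre-clustering of the spots;
   neighbours assigned to a different cluster than the focal spot get
   weight zero, which blocks pooling across sharp tissue boundaries.
3. **Elastic adjustment** — surviving non-self weights are raised to the
   power ``rho * (1 - Sim(E_n, E_i))`` where ``Sim`` is the cosine
   similarity of the two spots' expression vectors: similar neighbours are
   promoted towards full weight, dissimilar ones shrunk.

Disabling stages 2 and 3 leaves the pure kernel weighting (the SONAR-0
ablation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .data import SpatialDataset

__all__ = [
    "WeightScheme",
    "bisquare_weight",
    "build_neighbor_sets",
    "default_bandwidth",
    "precluster",
    "cosine_similarity",
    "elastic_adjust",
    "resolve_rho",
    "build_weight_scheme",
]


def bisquare_weight(d, b: float):
    """Bi-square kernel: ``[1 - (d/b)^2]^2`` for ``d <= b``, else 0."""
    if b <= 0:
        raise ValueError("bandwidth b must be > 0")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    w = np.where(d <= b, (1.0 - (d / b) ** 2) ** 2, 0.0)
    return w if w.ndim else float(w)


def build_neighbor_sets(coords: np.ndarray, bandwidth: float) -> dict[int, np.ndarray]:
    """Neighbour set of each spot: itself plus all spots within the bandwidth."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    coords = np.asarray(coords, dtype=np.float64)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(bandwidth, output_type="ndarray")
    if len(pairs) and np.any(
        np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1) == 0
    ):
        warnings.warn("duplicate coordinates: coincident spots are mutual "
                      "neighbours at distance 0", stacklevel=2)
    sets: dict[int, list[int]] = {i: [i] for i in range(len(coords))}
    for a, b in pairs:
        sets[int(a)].append(int(b))
        sets[int(b)].append(int(a))
    return {i: np.array(sorted(v), dtype=int) for i, v in sets.items()}


def default_bandwidth(coords: np.ndarray) -> float:
    """1.2x the median nearest-neighbour distance.

    On a regular lattice this gives positive weight to first-order
    neighbours only: second-order neighbours sit at >= sqrt(2) (square) or
    sqrt(3) (hex) times the pitch, beyond 1.2x.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if len(coords) < 2:
        raise ValueError("need at least 2 spots to set a bandwidth")
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    nn = np.median(dist[:, 1])
    if nn == 0:
        raise ValueError("all nearest-neighbour distances are zero "
                         "(coincident spots); supply a bandwidth explicitly")
    return 1.2 * nn


def _normalized_log_expression(counts: np.ndarray) -> np.ndarray:
    """Library-size normalise rows to the median depth, then log1p."""
    depth = counts.sum(axis=1, keepdims=True)
    target = np.median(depth[depth > 0]) if np.any(depth > 0) else 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(depth > 0, counts / depth * target, 0.0)
    return np.log1p(scaled)


def precluster(
    dataset: SpatialDataset,
    method: str = "leiden",
    resolution: float = 0.5,
    seed: int = 0,
    n_pcs: int = 30,
) -> np.ndarray:
    """Coarse expression clustering of spots for the weight mask.

    The pipeline is the standard one: library-size normalise, log1p, top
    2000 variable genes, PCA, then graph clustering ("leiden") or k-means
    on the PCs ("kmeans", also the automatic fallback for very small
    datasets, where a k-nearest-neighbour graph is not meaningful).
    Deterministic for a given seed.
    """
    counts = dataset.counts
    n, G = counts.shape
    if n == 0 or G == 0:
        raise ValueError("counts must be non-empty")
    if np.all(counts == counts[0]):
        return np.zeros(n, dtype=int)
    if method not in ("leiden", "kmeans"):
        raise ValueError(f"unknown precluster method {method!r}; "
                         "valid: 'leiden', 'kmeans'")
    if method == "leiden" and n < 30:
        warnings.warn(f"only {n} spots; falling back to k-means pre-clustering",
                      stacklevel=2)
        method = "kmeans"

    n_comps = min(n_pcs, n - 1, G - 1)
    if n_comps < n_pcs:
        warnings.warn(f"reducing PCA components to {n_comps}", stacklevel=2)

    if method == "kmeans":
        from sklearn.cluster import KMeans
        from sklearn.decomposition import PCA
        from sklearn.metrics import silhouette_score

        X = PCA(n_components=n_comps, random_state=seed).fit_transform(
            _normalized_log_expression(counts)
        )
        best_labels, best_score = np.zeros(n, dtype=int), -np.inf
        for k in range(2, min(9, n)):
            labels = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(X)
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(X, labels)
            if score > best_score:
                best_labels, best_score = labels, score
        return best_labels.astype(int)

    import scanpy as sc
    from anndata import AnnData

    adata = AnnData(counts.copy())
    sc.pp.normalize_total(adata, target_sum=1e4)
    sc.pp.log1p(adata)
    if G > 2000:
        sc.pp.highly_variable_genes(adata, n_top_genes=2000, subset=True)
    sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=min(15, n - 1), random_state=seed)
    sc.tl.leiden(
        adata, resolution=resolution, random_state=seed,
        flavor="igraph", n_iterations=2, directed=False,
    )
    return adata.obs["leiden"].astype(int).to_numpy()


def cosine_similarity(E_n: np.ndarray, E_i: np.ndarray) -> float:
    """Cosine similarity of two expression vectors; zero vectors map to 0."""
    E_n = np.asarray(E_n, dtype=np.float64)
    E_i = np.asarray(E_i, dtype=np.float64)
    if E_n.shape != E_i.shape:
        raise ValueError("expression vectors must have the same length")
    nn, ni = np.linalg.norm(E_n), np.linalg.norm(E_i)
    if nn == 0 or ni == 0:
        if nn == 0 and ni == 0:
            warnings.warn("cosine similarity of two zero vectors defined as 0",
                          stacklevel=2)
        return 0.0
    return float(E_n @ E_i / (nn * ni))


def elastic_adjust(w: float, rho: float, sim: float) -> float:
    """Similarity-adaptive weight shrinkage: ``w_tilde = w ** (rho*(1-sim))``.

    ``0 ** 0`` is defined as 0: a weight already zeroed by the bandwidth or
    the cluster mask can never be resurrected by perfect similarity.  Note
    the literal ``rho = 0`` limit promotes every positive weight to 1; to
    keep plain kernel weights, disable the elastic stage instead.
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    if not 0.0 <= w <= 1.0:
        raise ValueError("kernel weight must be in [0, 1]")
    if w == 0.0:
        return 0.0
    return float(w ** (rho * (1.0 - sim)))


@dataclass
class WeightScheme:
    """Per-spot neighbour sets with kernel and final weights.

    ``final_weights`` are the kernel weights after the cluster mask and
    elastic adjustment; the self-weight is always exactly 1.
    """

    neighbor_sets: dict[int, np.ndarray]
    kernel_weights: dict[int, np.ndarray]
    final_weights: dict[int, np.ndarray]
    cluster_labels: np.ndarray
    bandwidth: float
    rho: float

    def weight_map(self, i: int) -> dict[int, float]:
        """Map neighbour index -> final weight for focal spot ``i``."""
        return dict(zip(self.neighbor_sets[i].tolist(),
                        self.final_weights[i].tolist()))

    def __getitem__(self, i: int) -> dict[int, float]:
        return self.weight_map(i)


def resolve_rho(similarity_deficits: np.ndarray) -> float:
    """Median-heuristic elastic strength: ``rho = 1 / median(1 - sim)``.

    Cosine similarities of neighbouring spots' expression profiles are
    compressed near 1, so a fixed O(1) exponent scale would leave the
    elastic stage inert (every exponent ``rho*(1-sim)`` far below 1, every
    surviving weight promoted towards 1).  Scaling ``rho`` to the typical
    similarity deficit centres the adjustment: a neighbour of median
    similarity keeps its kernel weight, more similar neighbours are
    promoted, less similar ones shrunk.
    """
    deficits = np.asarray(similarity_deficits, dtype=np.float64)
    deficits = deficits[np.isfinite(deficits)]
    if len(deficits) == 0:
        return 1.0
    med = float(np.median(deficits))
    if med < 1e-9:  # all neighbours (near-)identical: elastic has no scale
        return 1.0
    return min(1.0 / med, 1e6)


def build_weight_scheme(
    dataset: SpatialDataset,
    bandwidth: float,
    rho: float | str,
    precluster_labels: np.ndarray,
    elastic: bool = True,
) -> WeightScheme:
    """Compose kernel, cluster mask, and elastic stages into final weights.

    With all spots in one cluster and ``elastic=False`` this reduces to the
    pure bi-square kernel weighting (SONAR-0).  The self-weight is exempt
    from the elastic exponent (its similarity is 1 anyway) and stays 1.
    ``rho="auto"`` resolves the elastic strength by :func:`resolve_rho`
    over the neighbour pairs the elastic stage applies to.
    """
    labels = np.asarray(precluster_labels)
    if labels.shape[0] != dataset.n_spots:
        raise ValueError("cluster labels must cover every spot")
    nbr = build_neighbor_sets(dataset.coords, bandwidth)
    E = _normalized_log_expression(dataset.counts) if elastic else None

    kernel_weights: dict[int, np.ndarray] = {}
    sims: dict[int, np.ndarray] = {}
    deficits: list[float] = []
    for i, idx in nbr.items():
        d = np.linalg.norm(dataset.coords[idx] - dataset.coords[i], axis=1)
        kw = bisquare_weight(d, bandwidth)
        kw[idx == i] = 1.0  # d = 0
        kernel_weights[i] = kw
        if elastic:
            s = np.ones(len(idx))
            for j, n in enumerate(idx):
                if n == i or kw[j] == 0.0 or labels[n] != labels[i]:
                    continue
                s[j] = cosine_similarity(E[n], E[i])
                deficits.append(1.0 - s[j])
            sims[i] = s
    if rho == "auto":
        rho = resolve_rho(np.array(deficits)) if elastic else 1.0
    rho = float(rho)

    final_weights: dict[int, np.ndarray] = {}
    for i, idx in nbr.items():
        kw = kernel_weights[i]
        fw = np.where(labels[idx] == labels[i], kw, 0.0)
        if elastic:
            for j, n in enumerate(idx):
                if n == i or fw[j] == 0.0:
                    continue
                fw[j] = elastic_adjust(fw[j], rho, sims[i][j])
        final_weights[i] = fw
    return WeightScheme(
        neighbor_sets=nbr,
        kernel_weights=kernel_weights,
        final_weights=final_weights,
        cluster_labels=labels,
        bandwidth=float(bandwidth),
        rho=float(rho),
    )
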