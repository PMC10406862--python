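"""Ground-truthed synthetic data for spatial deconvolution.

Two layers are generated: a synthetic annotated scRNA-seq reference with
per-type marker blocks, and pseudo-spot spatial datasets assembled by
sampling whole cells from that reference under designed regional
compositions.

Designs come in two schemes.  **Homo-Area** is a 20x20 grid with one
homogeneous composition, varying four local factors (dominant-cell
abundance, number of dominant types, relative proportion of two dominant
types, sparse-cell abundance).  **Compo-Area** is a 20x40 grid split into
homogeneous subregions under layer / block / background spatial patterns,
with jump (hard), gradient (linear buffer) or mix (uniform-mixture buffer)
transitions between adjacent subregions.  Dominant types default to an
expected 6 cells per spot, sparse types to 0.1, and each spot's designed
composition holds at most four cell types.

Realised per-type cell numbers at each spot are Poisson draws around the
designed expectations; the sampled cells' counts are summed to give the
spot's expression profile, and the realised cell counts are the ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import GroundTruth, SpatialDataset

__all__ = [
    "RegionDesign",
    "make_synthetic_reference",
    "sample_spot",
    "design_homo_area",
    "design_compo_area",
    "realize_design",
    "grid_single_cell_data",
    "homo_area_configs",
    "compo_area_configs",
    "HOMO_SCENARIOS",
    "COMPO_SCENARIOS",
]

DOMINANT_EXPECTATION = 6.0
SPARSE_EXPECTATION = 0.1
MAX_TYPES_PER_SPOT = 4

# Scenario grids for the two simulation schemes; with 5 replicates each
# these enumerate the full 80 Homo-Area and 95 Compo-Area configurations.
HOMO_SCENARIOS: dict[str, list] = {
    "dominant_abundance": [8, 6, 4, 2],
    "n_dominant": [4, 3, 2, 1],
    "dominant_proportion": [(3, 3), (4, 2), (5, 1), (5.5, 0.5)],
    "sparse_abundance": [0.3, 0.2, 0.1, 0.0],
}
COMPO_SCENARIOS: dict[str, list] = {
    "transition": ["jump", "gradient", "mix"],  # 2-layer
    "layer": [2, 3, 4, 5],
    "block": [2, 4, 8],
    "background": [1, 2, 3],  # number of floating patches
    "abundance_change": [(6, 1), (6, 2), (6, 3), (6, 4), (6, 5), (6, 8)],
}


@dataclass
class RegionDesign:
    """Spatial layout of regions and their designed compositions.

    ``expectations`` gives every spot's expected cell count per type after
    resolving the transition mode (buffer spots differ from their region's
    base composition under gradient/mix transitions).
    """

    grid_shape: tuple[int, int]  # (rows, cols)
    region_label: np.ndarray  # per spot, row-major
    pattern: str  # homo | layer | block | background
    transition: str  # jump | gradient | mix
    expectations: pd.DataFrame  # spots x cell types
    region_compositions: list[dict] = field(default_factory=list)
    buffer_width: int = 0

    @property
    def n_spots(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def coords(self) -> np.ndarray:
        """Unit-spaced (x, y) = (col, row) coordinates, row-major order."""
        rows, cols = self.grid_shape
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        return np.column_stack([cc.ravel(), rr.ravel()]).astype(float)


def make_synthetic_reference(
    n_types: int = 4,
    n_genes: int = 200,
    n_cells_per_type: int = 30,
    n_markers_per_type: int = 15,
    depth_mean: float = 500.0,
    marker_fold: tuple[float, float] = (5.0, 10.0),
    dispersion: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Annotated scRNA-seq-like reference with disjoint marker blocks.

    Every type shares a lognormal baseline rate profile; its own marker
    block is elevated by a uniform 5-10x fold.  Cells draw NB counts (mean
    = rate x depth, Gamma-shape ``dispersion``) with lognormal per-cell
    depth variation around ``depth_mean``.

    Returns the cell x gene count table and the per-cell type labels.
    """
    if n_cells_per_type <= 0:
        raise ValueError("n_cells_per_type must be positive")
    if n_markers_per_type * n_types > n_genes:
        raise ValueError("marker blocks exceed the gene panel: need "
                         f"{n_markers_per_type * n_types} <= {n_genes} genes")
    rng = np.random.default_rng(seed)
    base = rng.lognormal(mean=0.0, sigma=0.6, size=n_genes)
    rates = np.tile(base, (n_types, 1))
    for t in range(n_types):
        block = slice(t * n_markers_per_type, (t + 1) * n_markers_per_type)
        rates[t, block] *= rng.uniform(*marker_fold, size=n_markers_per_type)
    rates /= rates.sum(axis=1, keepdims=True)

    counts, labels = [], []
    type_names = [f"type_{t}" for t in range(n_types)]
    for t, name in enumerate(type_names):
        depths = rng.lognormal(np.log(depth_mean), 0.3, size=n_cells_per_type)
        mu = depths[:, None] * rates[t][None, :]
        lam = rng.gamma(shape=dispersion, scale=mu / dispersion)
        counts.append(rng.poisson(lam))
        labels.extend([name] * n_cells_per_type)
    cells = pd.DataFrame(
        np.vstack(counts),
        index=[f"cell_{i}" for i in range(n_types * n_cells_per_type)],
        columns=[f"gene_{g}" for g in range(n_genes)],
    )
    return cells, pd.Series(labels, index=cells.index, name="cell_type")


class _ReferencePool:
    """Per-type row indices into a reference count matrix, for fast sampling."""

    def __init__(self, ref_counts: pd.DataFrame, labels: pd.Series):
        self.counts = np.asarray(ref_counts, dtype=np.float64)
        self.gene_ids = list(ref_counts.columns)
        lab = np.asarray(labels).astype(str)
        self.by_type = {t: np.flatnonzero(lab == t) for t in np.unique(lab)}


def sample_spot(
    composition: dict[str, float], pool: _ReferencePool, rng: np.random.Generator
) -> tuple[np.ndarray, dict[str, int]]:
    """Assemble one pseudo-spot from a designed composition.

    Per-type realised cell numbers are Poisson draws at the designed
    expectations; that many cells are sampled with replacement from the
    type's pool and their counts summed.
    """
    positive = {t: e for t, e in composition.items() if e > 0}
    if any(e < 0 for e in composition.values()):
        raise ValueError("expectations must be >= 0")
    if len(positive) > MAX_TYPES_PER_SPOT:
        raise ValueError(
            f"at most {MAX_TYPES_PER_SPOT} cell types per spot; got {len(positive)}"
        )
    missing = [t for t in positive if t not in pool.by_type]
    if missing:
        raise KeyError(f"cell types absent from the reference: {missing}")
    counts = np.zeros(pool.counts.shape[1])
    realized: dict[str, int] = {}
    for t, expectation in positive.items():
        k = int(rng.poisson(expectation))
        realized[t] = k
        if k:
            chosen = rng.choice(pool.by_type[t], size=k, replace=True)
            counts += pool.counts[chosen].sum(axis=0)
    return counts, realized


def _cap_types(expect: dict[str, float]) -> dict[str, float]:
    """Keep the MAX_TYPES_PER_SPOT largest expectations, zeroing the rest."""
    positive = [(t, e) for t, e in expect.items() if e > 0]
    if len(positive) <= MAX_TYPES_PER_SPOT:
        return expect
    keep = set(
        t for t, _ in sorted(positive, key=lambda te: (-te[1], te[0]))[
            :MAX_TYPES_PER_SPOT
        ]
    )
    return {t: (e if t in keep else 0.0) for t, e in expect.items()}


def _pick_types(cell_types, n_dominant, n_sparse, rng):
    if n_dominant > len(cell_types):
        raise ValueError(f"need {n_dominant} dominant types but only "
                         f"{len(cell_types)} available")
    n_sparse = min(n_sparse, len(cell_types) - n_dominant)
    chosen = list(rng.choice(cell_types, size=n_dominant + n_sparse, replace=False))
    return chosen[:n_dominant], chosen[n_dominant:]


def design_homo_area(
    scenario: str,
    level,
    cell_types: list[str],
    seed: int = 0,
    grid_shape: tuple[int, int] = (20, 20),
) -> RegionDesign:
    """One homogeneous region whose composition follows the named scenario.

    Scenarios and their levels (see ``HOMO_SCENARIOS``):

    - ``dominant_abundance``: one dominant type at ``level`` expected
      cells (8 down to 2) plus three sparse types.
    - ``n_dominant``: ``level`` dominant types (4 down to 1) at the
      default abundance, padded with sparse types to four total.
    - ``dominant_proportion``: two dominant types at expectations
      ``level = (e1, e2)`` from even to uneven, plus two sparse types.
    - ``sparse_abundance``: one dominant type plus three sparse types at
      ``level`` (0.3 down to 0) expected cells.

    Which concrete cell types play each role is sampled per seed.
    """
    if scenario not in HOMO_SCENARIOS:
        raise ValueError(
            f"unknown Homo-Area scenario {scenario!r}; "
            f"valid: {sorted(HOMO_SCENARIOS)}"
        )
    rng = np.random.default_rng(seed)
    if scenario == "dominant_abundance":
        dom, sparse = _pick_types(cell_types, 1, 3, rng)
        comp = {dom[0]: float(level)} | {s: SPARSE_EXPECTATION for s in sparse}
    elif scenario == "n_dominant":
        k = int(level)
        dom, sparse = _pick_types(cell_types, k, MAX_TYPES_PER_SPOT - k, rng)
        comp = {d: DOMINANT_EXPECTATION for d in dom} | {
            s: SPARSE_EXPECTATION for s in sparse
        }
    elif scenario == "dominant_proportion":
        e1, e2 = level
        dom, sparse = _pick_types(cell_types, 2, 2, rng)
        comp = {dom[0]: float(e1), dom[1]: float(e2)} | {
            s: SPARSE_EXPECTATION for s in sparse
        }
    else:  # sparse_abundance
        dom, sparse = _pick_types(cell_types, 1, 3, rng)
        comp = {dom[0]: DOMINANT_EXPECTATION} | {s: float(level) for s in sparse}

    n_spots = grid_shape[0] * grid_shape[1]
    types = sorted(comp)
    expectations = pd.DataFrame(
        np.tile([comp[t] for t in types], (n_spots, 1)), columns=types
    )
    return RegionDesign(
        grid_shape=grid_shape,
        region_label=np.zeros(n_spots, dtype=int),
        pattern="homo",
        transition="jump",
        expectations=expectations,
        region_compositions=[comp],
    )


def _layer_labels(grid_shape, n_layers):
    rows, cols = grid_shape
    col_bands = np.array_split(np.arange(cols), n_layers)
    label_of_col = np.empty(cols, dtype=int)
    for r, band in enumerate(col_bands):
        label_of_col[band] = r
    return np.tile(label_of_col, (rows, 1)).ravel()


def _block_labels(grid_shape, n_blocks):
    if n_blocks not in (2, 4, 8):
        raise ValueError("block pattern supports 2, 4 or 8 subregions")
    rows, cols = grid_shape
    labels = np.zeros((rows, cols), dtype=int)
    # recursive halving, alternating the split axis
    def split(r0, r1, c0, c1, depth, base):
        if depth == 0:
            labels[r0:r1, c0:c1] = base
            return 1
        if (c1 - c0) >= (r1 - r0):
            mid = (c0 + c1) // 2
            n = split(r0, r1, c0, mid, depth - 1, base)
            split(r0, r1, mid, c1, depth - 1, base + n)
        else:
            mid = (r0 + r1) // 2
            n = split(r0, mid, c0, c1, depth - 1, base)
            split(mid, r1, c0, c1, depth - 1, base + n)
        return 2 ** depth

    split(0, rows, 0, cols, int(np.log2(n_blocks)), 0)
    return labels.ravel()


def _background_labels(grid_shape, n_patches, radius, rng):
    rows, cols = grid_shape
    labels = np.zeros((rows, cols), dtype=int)
    centers_c = np.linspace(cols / (n_patches + 1), cols * n_patches / (n_patches + 1),
                            n_patches)
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    for p, c_center in enumerate(centers_c, start=1):
        r_center = rng.uniform(radius, rows - radius)
        inside = (rr - r_center) ** 2 + (cc - c_center) ** 2 <= radius**2
        labels[inside] = p
    return labels.ravel()


def design_compo_area(
    pattern: str,
    transition: str = "jump",
    n_subregions: int = 2,
    cell_types: list[str] | None = None,
    seed: int = 0,
    grid_shape: tuple[int, int] = (20, 40),
    buffer_width: int = 4,
    dominant_expectations: list[float] | None = None,
    patch_radius: int = 4,
) -> RegionDesign:
    """Composite region of homogeneous subregions on a 20x40 grid.

    Each subregion is one dominant type (distinct per subregion) plus
    three sparse types shared across subregions.  ``layer`` splits the
    grid into contiguous vertical bands; ``block`` halves it recursively,
    alternating axes; ``background`` floats circular patches on a
    homogeneous background.  Soft transitions (layer pattern) replace the
    ``buffer_width`` columns straddling each boundary: ``gradient``
    interpolates the two flanking compositions linearly across the buffer,
    ``mix`` gives every buffer spot their arithmetic mean.  Buffer
    compositions are trimmed to the four largest expectations.
    """
    if pattern not in ("layer", "block", "background"):
        raise ValueError(f"unknown pattern {pattern!r}; "
                         "valid: 'layer', 'block', 'background'")
    if transition not in ("jump", "gradient", "mix"):
        raise ValueError(f"unknown transition {transition!r}; "
                         "valid: 'jump', 'gradient', 'mix'")
    if transition != "jump" and pattern != "layer":
        raise ValueError("soft transitions are defined for the layer pattern")
    rng = np.random.default_rng(seed)
    rows, cols = grid_shape

    if pattern == "layer":
        if not 2 <= n_subregions <= 5:
            raise ValueError("layer pattern supports 2-5 subregions")
        region = _layer_labels(grid_shape, n_subregions)
    elif pattern == "block":
        region = _block_labels(grid_shape, n_subregions)
        n_subregions = int(region.max()) + 1
    else:
        n_patches = n_subregions - 1
        if n_patches < 1:
            raise ValueError("background pattern needs >= 1 patch subregion")
        if n_patches * 2 * patch_radius > cols:
            raise ValueError(f"{n_patches} patches of radius {patch_radius} "
                             "do not fit the grid")
        region = _background_labels(grid_shape, n_patches, patch_radius, rng)
        n_subregions = int(region.max()) + 1

    if cell_types is None:
        cell_types = [f"type_{t}" for t in range(n_subregions + 3)]
    if len(cell_types) < n_subregions + 3:
        raise ValueError(
            f"need >= {n_subregions + 3} cell types for {n_subregions} "
            "subregions plus 3 shared sparse types"
        )
    if dominant_expectations is None:
        dominant_expectations = [DOMINANT_EXPECTATION] * n_subregions
    chosen = list(rng.choice(cell_types, size=n_subregions + 3, replace=False))
    dominants, sparse = chosen[:n_subregions], chosen[n_subregions:]
    compositions = []
    for r in range(n_subregions):
        comp = {dominants[r]: float(dominant_expectations[r])}
        comp |= {s: SPARSE_EXPECTATION for s in sparse}
        compositions.append(comp)

    types = sorted({t for c in compositions for t in c})
    base = np.zeros((rows * cols, len(types)))
    for r, comp in enumerate(compositions):
        mask = region == r
        base[mask] = [comp.get(t, 0.0) for t in types]

    buffer_used = 0
    if transition != "jump" and pattern == "layer":
        buffer_used = buffer_width
        col_bands = np.array_split(np.arange(cols), n_subregions)
        boundaries = [band[-1] + 1 for band in col_bands[:-1]]
        col_of = np.tile(np.arange(cols), (rows, 1)).ravel()
        for b_idx, boundary in enumerate(boundaries):
            left = np.array([compositions[b_idx].get(t, 0.0) for t in types])
            right = np.array([compositions[b_idx + 1].get(t, 0.0) for t in types])
            start = boundary - buffer_width // 2
            for k in range(buffer_width):
                c = start + k
                if not 0 <= c < cols:
                    continue
                if transition == "gradient":
                    f = (k + 1) / (buffer_width + 1)
                    comp_vec = (1 - f) * left + f * right
                else:  # mix
                    comp_vec = 0.5 * (left + right)
                capped = _cap_types(dict(zip(types, comp_vec)))
                base[col_of == c] = [capped[t] for t in types]

    expectations = pd.DataFrame(base, columns=types)
    return RegionDesign(
        grid_shape=grid_shape,
        region_label=region,
        pattern=pattern,
        transition=transition,
        expectations=expectations,
        region_compositions=compositions,
        buffer_width=buffer_used,
    )


def realize_design(
    design: RegionDesign,
    ref_counts: pd.DataFrame,
    ref_labels: pd.Series,
    seed: int = 0,
) -> tuple[SpatialDataset, GroundTruth]:
    """Draw a pseudo-spot dataset and its ground truth from a design."""
    pool = _ReferencePool(ref_counts, ref_labels)
    rng = np.random.default_rng(seed)
    types = list(design.expectations.columns)
    n = design.n_spots
    counts = np.zeros((n, len(pool.gene_ids)))
    cells = np.zeros((n, len(types)))
    for i in range(n):
        comp = design.expectations.iloc[i].to_dict()
        row, realized = sample_spot(comp, pool, rng)
        counts[i] = row
        cells[i] = [realized.get(t, 0) for t in types]
    spot_ids = [f"spot_{i}" for i in range(n)]
    dataset = SpatialDataset(
        counts=counts,
        coords=design.coords,
        spot_ids=spot_ids,
        gene_ids=pool.gene_ids,
    )
    truth = GroundTruth(
        cell_counts=cells,
        cell_type_ids=types,
        region_label=design.region_label,
        spot_ids=spot_ids,
    )
    return dataset, truth


def grid_single_cell_data(
    cell_coords: np.ndarray,
    cell_counts: pd.DataFrame,
    cell_labels,
    grid_size: float,
) -> tuple[SpatialDataset, GroundTruth]:
    """Aggregate single-cell-resolution spatial data into square pseudo-spots.

    The coordinate plane is tiled with half-open ``grid_size`` bins from
    the minimum coordinate; cells in a bin are summed, the bin centre
    becomes the new coordinate, and the bin's label counts are the ground
    truth.  Empty bins are dropped, so counts and cells are conserved.
    """
    if grid_size <= 0:
        raise ValueError("grid_size must be positive")
    coords = np.asarray(cell_coords, dtype=np.float64)
    counts = np.asarray(cell_counts, dtype=np.float64)
    labels = np.asarray(cell_labels).astype(str)
    origin = coords.min(axis=0)
    bins = np.floor((coords - origin) / grid_size).astype(int)
    types = sorted(np.unique(labels))
    keys, inverse = np.unique(bins, axis=0, return_inverse=True)
    n = len(keys)
    spot_counts = np.zeros((n, counts.shape[1]))
    cell_tallies = np.zeros((n, len(types)))
    t_index = {t: j for j, t in enumerate(types)}
    np.add.at(spot_counts, inverse, counts)
    for i, lab in zip(inverse, labels):
        cell_tallies[i, t_index[lab]] += 1
    centers = origin + (keys + 0.5) * grid_size
    gene_ids = list(cell_counts.columns) if isinstance(cell_counts, pd.DataFrame) \
        else None
    dataset = SpatialDataset(
        counts=spot_counts, coords=centers, gene_ids=gene_ids,
    )
    truth = GroundTruth(
        cell_counts=cell_tallies, cell_type_ids=types,
        spot_ids=list(dataset.spot_ids),
    )
    return dataset, truth


def homo_area_configs() -> list[dict]:
    """All (scenario, level) Homo-Area configurations (x5 replicates = 80)."""
    return [
        {"scenario": s, "level": lv}
        for s, levels in HOMO_SCENARIOS.items()
        for lv in levels
    ]


def compo_area_configs() -> list[dict]:
    """All Compo-Area configurations (x5 replicates = 95)."""
    configs: list[dict] = []
    for mode in COMPO_SCENARIOS["transition"]:
        configs.append({"pattern": "layer", "transition": mode, "n_subregions": 2})
    for n in COMPO_SCENARIOS["layer"]:
        configs.append({"pattern": "layer", "transition": "jump", "n_subregions": n})
    for n in COMPO_SCENARIOS["block"]:
        configs.append({"pattern": "block", "transition": "jump", "n_subregions": n})
    for p in COMPO_SCENARIOS["background"]:
        configs.append({"pattern": "background", "transition": "jump",
                        "n_subregions": p + 1})
    for e1, e2 in COMPO_SCENARIOS["abundance_change"]:
        configs.append({"pattern": "layer", "transition": "jump",
                        "n_subregions": 2, "dominant_expectations": [e1, e2]})
    return configs
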