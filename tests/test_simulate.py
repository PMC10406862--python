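"""Synthetic reference, pseudo-spot designs, sampling, and gridding."""

import numpy as np
import pandas as pd
import pytest

from sonar.simulate import (
    COMPO_SCENARIOS,
    HOMO_SCENARIOS,
    _ReferencePool,
    compo_area_configs,
    design_compo_area,
    design_homo_area,
    grid_single_cell_data,
    homo_area_configs,
    make_synthetic_reference,
    realize_design,
    sample_spot,
)


class TestSyntheticReference:
    def test_marker_blocks_separate_types(self):
        counts, labels = make_synthetic_reference(n_types=2, n_genes=50,
                                                  n_markers_per_type=10, seed=0)
        profiles = counts.groupby(labels).mean()
        a, b = profiles.to_numpy()
        between = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        # within-type: split each type's cells in half
        half = counts[labels == "type_0"].iloc[:10].mean().to_numpy()
        other = counts[labels == "type_0"].iloc[10:].mean().to_numpy()
        within = half @ other / (np.linalg.norm(half) * np.linalg.norm(other))
        assert between < within

    def test_same_seed_identical(self):
        c1, l1 = make_synthetic_reference(seed=9)
        c2, l2 = make_synthetic_reference(seed=9)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_series_equal(l1, l2)

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            make_synthetic_reference(n_cells_per_type=0)
        with pytest.raises(ValueError):
            make_synthetic_reference(n_types=5, n_genes=20, n_markers_per_type=10)


class TestSampleSpot:
    def test_replays_seeded_draws_exactly(self, tiny_reference):
        counts, labels = tiny_reference
        pool = _ReferencePool(counts, labels)
        rng = np.random.default_rng(4)
        row, realized = sample_spot({"type_0": 6.0}, pool, rng)
        # replay with a fresh generator at the same state
        rng2 = np.random.default_rng(4)
        k = int(rng2.poisson(6.0))
        chosen = rng2.choice(pool.by_type["type_0"], size=k, replace=True)
        np.testing.assert_array_equal(row, pool.counts[chosen].sum(axis=0))
        assert realized == {"type_0": k}

    def test_all_zero_expectations_give_empty_spot(self, tiny_reference):
        counts, labels = tiny_reference
        pool = _ReferencePool(counts, labels)
        row, realized = sample_spot({"type_0": 0.0}, pool,
                                    np.random.default_rng(0))
        assert row.sum() == 0 and realized == {}

    def test_mean_realized_count_matches_expectation(self, tiny_reference):
        counts, labels = tiny_reference
        pool = _ReferencePool(counts, labels)
        rng = np.random.default_rng(1)
        draws = [sample_spot({"type_1": 6.0}, pool, rng)[1].get("type_1", 0)
                 for _ in range(10_000)]
        assert abs(np.mean(draws) - 6.0) / 6.0 < 0.02

    def test_too_many_types_rejected(self, tiny_reference):
        counts, labels = tiny_reference
        pool = _ReferencePool(counts, labels)
        comp = {f"t{k}": 1.0 for k in range(5)}
        with pytest.raises(ValueError, match="at most"):
            sample_spot(comp, pool, np.random.default_rng(0))

    def test_unknown_type_rejected(self, tiny_reference):
        counts, labels = tiny_reference
        pool = _ReferencePool(counts, labels)
        with pytest.raises(KeyError):
            sample_spot({"nosuch": 2.0}, pool, np.random.default_rng(0))


TYPES = [f"type_{t}" for t in range(12)]


class TestHomoDesign:
    def test_dominant_abundance_level(self):
        d = design_homo_area("dominant_abundance", 8, TYPES, seed=0)
        exp = d.expectations
        assert (exp.max(axis=1) == 8).all()
        assert d.grid_shape == (20, 20) and d.n_spots == 400

    def test_one_dominant_three_sparse(self):
        d = design_homo_area("n_dominant", 1, TYPES, seed=0)
        row = d.expectations.iloc[0]
        assert (row == 6.0).sum() == 1 and (row == 0.1).sum() == 3

    def test_sparse_abundance_zero(self):
        d = design_homo_area("sparse_abundance", 0.0, TYPES, seed=0)
        row = d.expectations.iloc[0]
        assert (row > 0).sum() == 1  # only the dominant remains

    def test_unknown_scenario_lists_valid(self):
        with pytest.raises(ValueError, match="dominant_abundance"):
            design_homo_area("nope", 1, TYPES)


class TestCompoDesign:
    def test_four_layer_jump_geometry(self):
        d = design_compo_area("layer", "jump", 4, TYPES, seed=0)
        labels = d.region_label.reshape(20, 40)
        # four contiguous 20x10 vertical bands
        for r in range(4):
            assert (labels[:, r * 10:(r + 1) * 10] == r).all()
        assert d.buffer_width == 0

    def test_gradient_midpoint_is_even_mixture(self):
        d = design_compo_area("layer", "gradient", 2, TYPES, seed=0,
                              buffer_width=3)
        exp = d.expectations.to_numpy().reshape(20, 40, -1)
        dom_a = exp[0, 0].argmax()
        dom_b = exp[0, 39].argmax()
        mid = exp[10, 20]  # centre buffer column
        assert mid[dom_a] == pytest.approx(3.0)
        assert mid[dom_b] == pytest.approx(3.0)

    def test_mix_buffer_is_uniform_mean(self):
        d = design_compo_area("layer", "mix", 2, TYPES, seed=0, buffer_width=4)
        exp = d.expectations.to_numpy().reshape(20, 40, -1)
        dom_a = exp[0, 0].argmax()
        buffer_cols = exp[:, 18:22]
        assert np.allclose(buffer_cols[..., dom_a], 3.0)

    def test_block_counts(self):
        for n in (2, 4, 8):
            d = design_compo_area("block", "jump", n, TYPES, seed=0)
            assert len(np.unique(d.region_label)) == n

    def test_background_patches(self):
        d = design_compo_area("background", "jump", 3, TYPES, seed=0)
        assert len(np.unique(d.region_label)) == 3
        # background dominates
        assert (d.region_label == 0).mean() > 0.5

    def test_incompatible_arguments_rejected(self):
        with pytest.raises(ValueError):
            design_compo_area("layer", "jump", 7, TYPES)
        with pytest.raises(ValueError):
            design_compo_area("block", "gradient", 2, TYPES)
        with pytest.raises(ValueError):
            design_compo_area("background", "jump", 9, TYPES)

    def test_at_most_four_types_positive_per_spot(self):
        for transition in ("jump", "gradient", "mix"):
            d = design_compo_area("layer", transition, 2, TYPES, seed=1)
            assert ((d.expectations.to_numpy() > 0).sum(axis=1) <= 4).all()


class TestRealize:
    def test_truth_on_simplex_and_capped(self, tiny_reference):
        counts, labels = tiny_reference
        types = sorted(labels.unique())
        d = design_homo_area("dominant_abundance", 4, types, seed=3,
                             grid_shape=(5, 5))
        ds, truth = realize_design(d, counts, labels, seed=3)
        occupied = ~truth.empty_spots
        np.testing.assert_allclose(
            truth.proportions[occupied].sum(axis=1), 1.0, atol=1e-12
        )
        assert ((truth.cell_counts > 0).sum(axis=1) <= 4).all()
        assert ds.n_spots == 25 and ds.counts.shape[1] == counts.shape[1]

    def test_deterministic_given_seed(self, tiny_reference):
        counts, labels = tiny_reference
        types = sorted(labels.unique())
        d = design_homo_area("n_dominant", 2, types, seed=5, grid_shape=(4, 4))
        ds1, _ = realize_design(d, counts, labels, seed=5)
        ds2, _ = realize_design(d, counts, labels, seed=5)
        np.testing.assert_array_equal(ds1.counts, ds2.counts)


class TestGridding:
    def test_one_cell_per_bin_snaps_to_centres(self):
        coords = np.array([[0.1, 0.1], [1.4, 0.2], [0.3, 1.2]])
        counts = pd.DataFrame(np.eye(3), columns=["g0", "g1", "g2"])
        ds, truth = grid_single_cell_data(coords, counts, ["A", "B", "A"], 1.0)
        assert ds.n_spots == 3
        np.testing.assert_array_equal(ds.counts.sum(axis=0), [1, 1, 1])

    def test_two_cells_same_bin_summed_with_split_truth(self):
        coords = np.array([[0.2, 0.2], [0.7, 0.7]])
        counts = pd.DataFrame([[3, 0], [1, 2]], columns=["g0", "g1"])
        ds, truth = grid_single_cell_data(coords, counts, ["A", "B"], 1.0)
        assert ds.n_spots == 1
        np.testing.assert_array_equal(ds.counts[0], [4, 2])
        np.testing.assert_allclose(truth.proportions[0], [0.5, 0.5])

    def test_conservation_and_scaling(self, rng):
        coords = rng.uniform(0, 10, size=(200, 2))
        counts = pd.DataFrame(rng.poisson(2.0, size=(200, 5)))
        labels = rng.choice(["A", "B"], 200)
        for size in (2.0, 1.0):
            ds, truth = grid_single_cell_data(coords, counts, labels, size)
            assert ds.counts.sum() == counts.to_numpy().sum()
            assert truth.cell_counts.sum() == 200
        big, _ = grid_single_cell_data(coords, counts, labels, 2.0)
        small, _ = grid_single_cell_data(coords, counts, labels, 1.0)
        # quartering the bin area roughly quarters mean cells per occupied bin
        assert small.n_spots > 2 * big.n_spots


class TestSchemeEnumeration:
    def test_homo_scheme_counts_80_datasets(self):
        configs = homo_area_configs()
        assert len(configs) == 16
        assert len(configs) * 5 == 80

    def test_compo_scheme_counts_95_datasets(self):
        configs = compo_area_configs()
        assert len(configs) == 19
        assert len(configs) * 5 == 95

    def test_scenario_grids_cover_printed_endpoints(self):
        assert HOMO_SCENARIOS["dominant_abundance"][0] == 8
        assert HOMO_SCENARIOS["dominant_abundance"][-1] == 2
        assert HOMO_SCENARIOS["n_dominant"] == [4, 3, 2, 1]
        assert HOMO_SCENARIOS["sparse_abundance"][0] == 0.3
        assert HOMO_SCENARIOS["sparse_abundance"][-1] == 0.0
        assert COMPO_SCENARIOS["layer"] == [2, 3, 4, 5]
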