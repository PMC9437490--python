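"""Generator invariants: determinism, containment, planting consistency."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from gutmorph.scene_sim import (
    PhenotypeParams,
    PlacementError,
    build_scene,
    default_config,
    render_grayscale,
)

from conftest import make_small_config


class TestDefaultConfig:
    def test_composition_totals_twenty_cells_seven_exocrine(self):
        config = default_config()
        comp = dict(config.composition)
        assert sum(comp.values()) == 20
        assert comp["exocrine"] == 7
        assert comp["differentiating"] == 2

    def test_voxel_spacing_matches_acquisition_geometry(self):
        assert default_config().voxel_spacing_nm == (50.0, 15.0, 15.0)

    def test_apical_bias_values_are_probabilities(self):
        for params in default_config().phenotypes.values():
            assert 0.0 <= params.apical_bias <= 1.0


class TestBuildScene:
    def test_determinism_bit_identical(self, small_config):
        s1, t1 = build_scene(small_config, seed=7)
        s2, t2 = build_scene(small_config, seed=7)
        for a, b in ((s1.cells, s2.cells), (s1.nuclei, s2.nuclei), (s1.vesicles, s2.vesicles), (s1.lumen, s2.lumen)):
            np.testing.assert_array_equal(a.values, b.values)
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        pd.testing.assert_frame_equal(t1.vesicles, t2.vesicles)

    def test_distinct_cells_nuclei_and_lumen_present(self, small_scene):
        scene, truth = small_scene
        cells = scene.cells.values
        assert set(np.unique(cells[cells > 0])) == {1, 2, 3}
        nuclei = scene.nuclei.values
        assert set(np.unique(nuclei[nuclei > 0])) == {1, 2, 3}
        assert scene.lumen.values.any()

    def test_every_cell_apical_face_touches_lumen(self, small_scene):
        scene, _ = small_scene
        cells = scene.cells.values
        lumen = scene.lumen.values.astype(bool)
        lumen_above = np.zeros_like(lumen)
        lumen_above[:-1] = lumen[1:]  # True where the voxel above is lumen
        touching = np.unique(cells[lumen_above & (cells > 0)])
        assert set(touching.tolist()) == {1, 2, 3}

    def test_vesicle_census_matches_ground_truth(self, small_scene):
        scene, truth = small_scene
        ves = scene.vesicles.values
        labels = np.unique(ves[ves > 0])
        assert len(labels) == len(truth.vesicles)
        assert set(labels.tolist()) == set(truth.vesicles["vesicle_id"].tolist())

    def test_per_cell_truth_counts_equal_vesicle_rows(self, small_scene):
        _, truth = small_scene
        per_cell = truth.vesicles.groupby("cell_id")
        for _, row in truth.cells.iterrows():
            rows = truth.vesicles[truth.vesicles["cell_id"] == row["cell_id"]]
            assert (rows["size_class"] == "secretory").sum() == row["n_secretory"]
            assert (rows["size_class"] == "large").sum() == row["n_large"]
            sec = rows[rows["size_class"] == "secretory"]
            assert sec["apical"].sum() == row["n_apical_secretory"]

    def test_containment_exhaustive(self, small_scene):
        """Every vesicle voxel lies in its owner cell; none touches a nucleus."""
        scene, truth = small_scene
        ves = scene.vesicles.values
        cells = scene.cells.values
        nuclei = scene.nuclei.values
        owner = dict(zip(truth.vesicles["vesicle_id"], truth.vesicles["cell_id"]))
        inside = ves > 0
        assert not nuclei[inside].any()
        for label, cell in owner.items():
            assert (cells[ves == label] == cell).all()

    def test_vesicles_are_connected_and_disjoint(self, small_scene):
        """Each vesicle label forms exactly one 6-connected component."""
        scene, truth = small_scene
        ves = scene.vesicles.values
        struct = ndimage.generate_binary_structure(3, 1)
        for sl, label in zip(
            ndimage.find_objects(ves), range(1, int(ves.max()) + 1)
        ):
            if sl is None:
                continue
            _, n = ndimage.label(ves[sl] == label, structure=struct)
            assert n == 1

    def test_planted_apical_flags_match_planting_rule(self, small_scene):
        """Apical flag <=> centre above the nucleus apical extent (axis 0)."""
        scene, truth = small_scene
        vz = scene.nuclei.spacing_nm[0]
        for cell_id, rows in truth.vesicles.groupby("cell_id"):
            zmax = np.nonzero((scene.nuclei.values == cell_id).any(axis=(1, 2)))[0].max()
            extent = (zmax + 0.5) * vz
            sec = rows[rows["size_class"] == "secretory"]
            np.testing.assert_array_equal(
                sec["apical"].to_numpy(), (sec["center_z_nm"] > extent).to_numpy()
            )

    def test_planted_fraction_converges_to_apical_bias(self):
        """Pooled apical share across cells is binomial around the bias."""
        bias, mean = 0.7, 40
        config = make_small_config(
            cell_grid=(1, 4),
            composition=(("exocrine", 4),),
            phenotypes={
                "exocrine": PhenotypeParams("exocrine", vesicle_count_mean=mean, apical_bias=bias)
            },
        )
        _, truth = build_scene(config, seed=11)
        sec = truth.vesicles[truth.vesicles["size_class"] == "secretory"]
        n = len(sec)
        p_hat = sec["apical"].mean()
        assert abs(p_hat - bias) <= 3 * np.sqrt(bias * (1 - bias) / n)

    def test_zero_count_mean_gives_empty_vesicle_grid(self):
        config = make_small_config(
            composition=(("stomach", 3),),
            phenotypes={
                "stomach": PhenotypeParams(
                    "stomach",
                    vesicle_count_mean=0.0,
                    apical_bias=0.5,
                    large_vesicle_count_range=(0, 0),
                )
            },
        )
        scene, truth = build_scene(config, seed=0)
        assert not scene.vesicles.values.any()
        assert len(truth.vesicles) == 0
        assert (truth.cells["n_secretory"] == 0).all()

    def test_composition_must_fill_the_grid(self):
        with pytest.raises(ValueError, match="capacity"):
            make_small_config(composition=(("exocrine", 5),))

    def test_overcrowded_cell_raises_placement_error(self):
        config = make_small_config(
            composition=(("exocrine", 3),),
            phenotypes={
                "exocrine": PhenotypeParams(
                    "exocrine",
                    vesicle_count_mean=2000,  # cannot fit in the cell volume
                    apical_bias=0.9,
                )
            },
            placement_max_attempts=50,
        )
        with pytest.raises(PlacementError, match="cell"):
            build_scene(config, seed=0)


class TestRender:
    def test_noise_free_render_hits_configured_means(self, small_config):
        config = make_small_config()
        config.render.noise_sd = 0.0
        scene, truth = build_scene(config, seed=0)
        img = render_grayscale(scene, config, seed=0).values
        rp = config.render
        assert (img[scene.nuclei.values > 0] == rp.nucleus).all()
        assert (img[scene.lumen.values > 0] == rp.lumen).all()
        sec_ids = truth.vesicles.loc[
            truth.vesicles["size_class"] == "secretory", "vesicle_id"
        ].to_numpy()
        large_ids = truth.vesicles.loc[
            truth.vesicles["size_class"] == "large", "vesicle_id"
        ].to_numpy()
        ves = scene.vesicles.values
        assert (img[np.isin(ves, sec_ids)] == rp.secretory_vesicle).all()
        assert (img[np.isin(ves, large_ids)] == rp.large_vesicle).all()

    def test_secretory_brighter_than_large_under_noise(self, small_scene, small_config):
        scene, truth = small_scene
        img = render_grayscale(scene, small_config, seed=0).values
        ves = scene.vesicles.values
        sec_ids = truth.vesicles.loc[
            truth.vesicles["size_class"] == "secretory", "vesicle_id"
        ].to_numpy()
        large_ids = truth.vesicles.loc[
            truth.vesicles["size_class"] == "large", "vesicle_id"
        ].to_numpy()
        assert img[np.isin(ves, sec_ids)].mean() > img[np.isin(ves, large_ids)].mean()

    def test_render_deterministic_for_fixed_seed(self, small_scene, small_config):
        scene, _ = small_scene
        a = render_grayscale(scene, small_config, seed=5).values
        b = render_grayscale(scene, small_config, seed=5).values
        np.testing.assert_array_equal(a, b)
        c = render_grayscale(scene, small_config, seed=6).values
        assert (a != c).any()
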