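"""Shared fixtures: a small fast scene and the default 20-cell study runs."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from gutmorph import PipelineConfig, run_pipeline
from gutmorph.scene_sim import PhenotypeParams, SceneConfig, build_scene


def make_small_config(**overrides) -> SceneConfig:
    """A 3-cell scene (one cell per phenotype) that builds in well under a
    second, for unit tests that need real geometry but not the full study."""
    params = dict(
        cell_grid=(1, 3),
        cell_footprint_nm=1500.0,
        cell_height_nm=6500.0,
        nucleus_semiaxes_nm=(400.0, 300.0, 300.0),
        nucleus_center_height_nm=1100.0,
        composition=(
            ("exocrine", 1),
            ("differentiating", 1),
            ("stomach", 1),
        ),
        phenotypes={
            "exocrine": PhenotypeParams("exocrine", vesicle_count_mean=12, apical_bias=0.9),
            "differentiating": PhenotypeParams(
                "differentiating", vesicle_count_mean=10, apical_bias=0.4
            ),
            "stomach": PhenotypeParams("stomach", vesicle_count_mean=4, apical_bias=0.5),
        },
    )
    params.update(overrides)
    config = SceneConfig(**params)
    config.validate()
    return config


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    return make_small_config()


@pytest.fixture(scope="session")
def small_scene(small_config):
    return build_scene(small_config, seed=0)


@pytest.fixture(scope="session")
def default_run0():
    """Full pipeline output on the default 20-cell scene, seed 0."""
    return run_pipeline(PipelineConfig(), seed=0)


@dataclass
class SlimRun:
    """Lightweight per-seed record (tables only, no label grids)."""

    seed: int
    calls: pd.DataFrame
    truth_cells: pd.DataFrame
    ratio_exocrine_vs_stomach: float


@pytest.fixture(scope="session")
def default_runs(default_run0):
    """The study: default scenes for seeds 0-19, keeping only the tables."""
    runs = [
        SlimRun(
            seed=0,
            calls=default_run0.calls,
            truth_cells=default_run0.truth.cells,
            ratio_exocrine_vs_stomach=default_run0.summary.count_ratio_exocrine_vs_stomach,
        )
    ]
    for seed in range(1, 20):
        res = run_pipeline(PipelineConfig(), seed=seed)
        runs.append(
            SlimRun(
                seed=seed,
                calls=res.calls,
                truth_cells=res.truth.cells,
                ratio_exocrine_vs_stomach=res.summary.count_ratio_exocrine_vs_stomach,
            )
        )
    return runs
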