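"""End-to-end pipeline: simulate -> (segment) -> measure -> polarity -> classify.

One root seed drives every stochastic stage.  The default route measures
the planted vesicle labels directly, mirroring a workflow in which
instance labels come from (semi-)manual segmentation; the segmentation
route instead renders a grayscale volume and recovers vesicle instances
by thresholding inside the cell mask before measuring.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .morphometrics import SIZE_CUTOFF_NM, measure_vesicles
from .phenotype import PhenotypeThresholds, SummaryReport, classify_cells, summarize
from .polarity import polarity_table
from .scene_sim import (
    GroundTruthTable,
    LabelScene,
    SceneConfig,
    build_scene,
    render_grayscale,
    write_scene,
)
from .segment import SegmentationParams, threshold_components
from .volio import check_keys

__all__ = ["PipelineConfig", "RunResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    ``use_segmentation`` switches the vesicle source from the planted
    labels to threshold segmentation of the rendered volume.
    """

    scene: SceneConfig = field(default_factory=SceneConfig)
    use_segmentation: bool = False
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    size_cutoff_nm: float = SIZE_CUTOFF_NM
    ownership_rule: str = "overlap"  # or "centroid"
    nucleus_base_percentile: float = 100.0
    global_axis: tuple[float, float, float] | None = None
    include_large: bool = False
    thresholds: PhenotypeThresholds = field(default_factory=PhenotypeThresholds)
    reference_cell_ids: tuple[int, ...] | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        allowed = {f.name for f in cls.__dataclass_fields__.values()}
        check_keys(data, allowed, "pipeline config")
        kwargs = dict(data)
        if "scene" in kwargs:
            kwargs["scene"] = SceneConfig.from_dict(kwargs["scene"] or {})
        if "segmentation" in kwargs:
            seg = kwargs["segmentation"] or {}
            check_keys(
                seg,
                {f.name for f in SegmentationParams.__dataclass_fields__.values()},
                "segmentation",
            )
            kwargs["segmentation"] = SegmentationParams(**seg)
        if "thresholds" in kwargs:
            thr = kwargs["thresholds"] or {}
            check_keys(
                thr,
                {f.name for f in PhenotypeThresholds.__dataclass_fields__.values()},
                "thresholds",
            )
            kwargs["thresholds"] = PhenotypeThresholds(**thr)
        for key in ("global_axis", "reference_cell_ids"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["scene"] = self.scene.to_dict()
        for key in ("global_axis", "reference_cell_ids"):
            if data[key] is not None:
                data[key] = list(data[key])
        return data

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    """Everything one run produced."""

    scene: LabelScene
    truth: GroundTruthTable
    objects: pd.DataFrame
    polarity: pd.DataFrame
    calls: pd.DataFrame
    summary: SummaryReport
    timings_s: dict[str, float]
    seed: int


def run_pipeline(
    config: PipelineConfig | None = None,
    seed: int | None = None,
    outdir=None,
) -> RunResult:
    """Run the full pipeline under one root seed.

    When ``outdir`` is given, the scene stacks, tables and a run log
    (tool version, config hash, seed, per-stage timings) are written
    there.
    """
    config = config or PipelineConfig()
    if seed is None:
        seed = config.scene.seed
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    scene, truth = build_scene(config.scene, seed=seed)
    timings["simulate"] = time.perf_counter() - t0

    render = None
    if config.use_segmentation:
        t0 = time.perf_counter()
        render = render_grayscale(scene, config.scene, seed=seed)
        vesicle_source = threshold_components(
            render, config.segmentation, mask=scene.cells
        )
        timings["segment"] = time.perf_counter() - t0
    else:
        vesicle_source = scene.vesicles

    t0 = time.perf_counter()
    objects = measure_vesicles(
        vesicle_source,
        scene.cells,
        cutoff_nm=config.size_cutoff_nm,
        rule=config.ownership_rule,
    )
    timings["measure"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    pol = polarity_table(
        scene.cells,
        scene.nuclei,
        scene.lumen,
        objects,
        percentile=config.nucleus_base_percentile,
        global_axis=config.global_axis,
        include_large=config.include_large,
    )
    timings["polarity"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    calls = classify_cells(
        pol,
        thresholds=config.thresholds,
        reference_cell_ids=config.reference_cell_ids,
    )
    summary = summarize(calls, ground_truth=truth.cells)
    timings["classify"] = time.perf_counter() - t0

    result = RunResult(
        scene=scene,
        truth=truth,
        objects=objects,
        polarity=pol,
        calls=calls,
        summary=summary,
        timings_s=timings,
        seed=int(seed),
    )
    if outdir is not None:
        _write_run(result, config, render, Path(outdir))
    return result


def _write_run(result: RunResult, config: PipelineConfig, render, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    write_scene(result.scene, result.truth, config.scene, outdir, render=render)
    result.objects.to_csv(outdir / "objects.csv", index=False)
    result.polarity.to_csv(outdir / "polarity.csv", index=False)
    result.calls.to_csv(outdir / "calls.csv", index=False)
    result.summary.per_phenotype.to_csv(outdir / "report.csv")
    if result.summary.confusion is not None:
        result.summary.confusion.to_csv(outdir / "confusion.csv")
    log = {
        "tool": "gutmorph",
        "version": __version__,
        "seed": result.seed,
        "config_hash": config.config_hash(),
        "timings_s": {k: round(v, 3) for k, v in result.timings_s.items()},
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    (outdir / "pipeline_config.yaml").write_text(
        yaml.safe_dump({"kind": "pipeline", **config.to_dict()}, sort_keys=False)
    )
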