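"""Seeded synthetic block-face-EM scene generator.

Emulates a polarized columnar midgut epithelium seen in a stack-of-slices
volume: a flat monolayer of columnar cells whose apical faces abut a lumen
slab at the +axis0 end of the stack, each cell carrying one ellipsoidal
nucleus seated in its basal half, a handful of large (~1 µm) electron-dense
vesicles, and a phenotype-dependent load of small (~300 nm) electron-lucent
secretory vesicles.

Three phenotypes are planted:

* ``exocrine`` — acinar-like cells: many secretory vesicles, strongly
  biased to the supranuclear (apical) compartment;
* ``differentiating`` — equally vesicle-rich but only weakly polarized;
* ``stomach`` — ordinary absorptive cells with few vesicles.

The planting rule for "apical" is the same rule the measurement stage
applies: a vesicle is apical when its centre lies above the apical-most
extent of its cell's nucleus along the apico-basal axis, so planted flags
are recoverable by measurement.  The geometry is a flat slab rather than a
curved gut wall: the true polarity axis is then exactly +axis0, which
separates axis-estimation error from statistic error in tests.

Randomness: one root seed; each cell draws from its own deterministic
substream, so changing one cell's parameters never perturbs another
cell's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .volio import VoxelGrid, check_keys, write_volume

__all__ = [
    "PhenotypeParams",
    "RenderParams",
    "SceneConfig",
    "LabelScene",
    "GroundTruthTable",
    "PlacementError",
    "default_config",
    "build_scene",
    "render_grayscale",
    "write_scene",
]

PHENOTYPE_NAMES = ("exocrine", "differentiating", "stomach")


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place a vesicle in a cell."""


@dataclass
class PhenotypeParams:
    """Vesicle statistics of one planted cell phenotype.

    ``vesicle_count_mean`` is the Poisson mean of the secretory-vesicle
    census; ``apical_bias`` is the probability that each secretory vesicle
    is planted in the supranuclear compartment.  Diameters are drawn from
    normals truncated at +-3 SD so vesicles stay well inside cells.
    """

    name: str
    vesicle_count_mean: float
    apical_bias: float
    secretory_diam_mean_nm: float = 300.0
    secretory_diam_sd_nm: float = 30.0
    large_vesicle_count_range: tuple[int, int] = (1, 3)
    large_diam_mean_nm: float = 1000.0
    large_diam_sd_nm: float = 100.0

    def validate(self, cell_height_nm: float) -> None:
        if not 0.0 <= self.apical_bias <= 1.0:
            raise ValueError(
                f"phenotype {self.name!r}: apical_bias must lie in [0, 1], "
                f"got {self.apical_bias}"
            )
        if self.vesicle_count_mean < 0:
            raise ValueError(
                f"phenotype {self.name!r}: vesicle_count_mean must be >= 0"
            )
        for attr in (
            "secretory_diam_mean_nm",
            "secretory_diam_sd_nm",
            "large_diam_mean_nm",
            "large_diam_sd_nm",
        ):
            if getattr(self, attr) <= 0:
                raise ValueError(f"phenotype {self.name!r}: {attr} must be > 0")
        lo, hi = self.large_vesicle_count_range
        if not (0 <= lo <= hi):
            raise ValueError(
                f"phenotype {self.name!r}: invalid large_vesicle_count_range"
            )
        for attr in ("secretory_diam_mean_nm", "large_diam_mean_nm"):
            if getattr(self, attr) >= cell_height_nm:
                raise ValueError(
                    f"phenotype {self.name!r}: {attr} must be smaller than "
                    f"the cell height ({cell_height_nm} nm)"
                )

    @classmethod
    def from_dict(cls, name: str, data: dict) -> "PhenotypeParams":
        check_keys(
            data,
            {
                "vesicle_count_mean",
                "apical_bias",
                "secretory_diam_mean_nm",
                "secretory_diam_sd_nm",
                "large_vesicle_count_range",
                "large_diam_mean_nm",
                "large_diam_sd_nm",
            },
            f"phenotype {name!r}",
        )
        kwargs = dict(data)
        if "large_vesicle_count_range" in kwargs:
            kwargs["large_vesicle_count_range"] = tuple(
                int(v) for v in kwargs["large_vesicle_count_range"]
            )
        return cls(name=name, **kwargs)


def _default_phenotypes() -> dict[str, PhenotypeParams]:
    return {
        "exocrine": PhenotypeParams("exocrine", vesicle_count_mean=100.0, apical_bias=0.9),
        "differentiating": PhenotypeParams(
            "differentiating", vesicle_count_mean=100.0, apical_bias=0.4
        ),
        "stomach": PhenotypeParams("stomach", vesicle_count_mean=25.0, apical_bias=0.5),
    }


@dataclass
class RenderParams:
    """Grayscale rendering: per-compartment 8-bit means plus Gaussian noise.

    Secretory vesicles render bright (electron-lucent content), the large
    vesicles dark (electron-dense content), nuclei mid-dark, and cell
    boundaries as 1-voxel darkened seams.
    """

    noise_sd: float = 10.0
    cytoplasm: int = 128
    secretory_vesicle: int = 220
    large_vesicle: int = 40
    nucleus: int = 90
    boundary: int = 60
    lumen: int = 150
    background: int = 150

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("render noise_sd must be >= 0")
        for attr in (
            "cytoplasm",
            "secretory_vesicle",
            "large_vesicle",
            "nucleus",
            "boundary",
            "lumen",
            "background",
        ):
            v = getattr(self, attr)
            if not 0 <= v <= 255:
                raise ValueError(f"render intensity {attr} must be in [0, 255]")

    @classmethod
    def from_dict(cls, data: dict) -> "RenderParams":
        check_keys(data, {f.name for f in cls.__dataclass_fields__.values()}, "render")
        return cls(**data)


@dataclass
class SceneConfig:
    """Everything that defines one synthetic scene.

    Defaults encode the study conditions: voxel spacing (50, 15, 15) nm
    ordered (slice, row, column); a 4 x 5 monolayer of 20 columnar cells
    with 7 exocrine, 2 differentiating and 11 main-stomach cells.
    """

    voxel_spacing_nm: tuple[float, float, float] = (50.0, 15.0, 15.0)
    cell_grid: tuple[int, int] = (4, 5)  # rows x columns of cells
    cell_footprint_nm: float = 1800.0
    cell_height_nm: float = 10000.0
    nucleus_semiaxes_nm: tuple[float, float, float] = (800.0, 500.0, 500.0)
    nucleus_center_height_nm: float = 3400.0
    composition: tuple[tuple[str, int], ...] = (
        ("exocrine", 7),
        ("differentiating", 2),
        ("stomach", 11),
    )
    phenotypes: dict[str, PhenotypeParams] = field(default_factory=_default_phenotypes)
    seed: int = 0
    lumen_thickness_nm: float = 300.0
    basal_margin_nm: float = 200.0
    boundary_jitter_nm: float = 30.0
    plant_margin_nm: float = 150.0
    wall_gap_nm: float = 30.0
    placement_max_attempts: int = 1000
    render: RenderParams = field(default_factory=RenderParams)

    # -- derived geometry -------------------------------------------------
    @property
    def footprint_voxels(self) -> tuple[int, int]:
        return (
            int(round(self.cell_footprint_nm / self.voxel_spacing_nm[1])),
            int(round(self.cell_footprint_nm / self.voxel_spacing_nm[2])),
        )

    @property
    def height_voxels(self) -> int:
        return int(round(self.cell_height_nm / self.voxel_spacing_nm[0]))

    @property
    def capacity(self) -> int:
        return self.cell_grid[0] * self.cell_grid[1]

    @property
    def n_cells(self) -> int:
        return sum(count for _, count in self.composition)

    def validate(self) -> None:
        if any(s <= 0 for s in self.voxel_spacing_nm):
            raise ValueError("voxel spacing must be strictly positive")
        if min(self.cell_grid) < 1:
            raise ValueError("cell_grid must have at least one row and column")
        for name, count in self.composition:
            if name not in self.phenotypes:
                raise ValueError(f"composition names unknown phenotype {name!r}")
            if count < 0:
                raise ValueError("composition counts must be >= 0")
        if self.n_cells > self.capacity:
            raise ValueError(
                f"composition ({self.n_cells} cells) exceeds grid capacity "
                f"({self.capacity})"
            )
        if self.n_cells != self.capacity:
            raise ValueError(
                f"composition must fill the cell grid exactly: "
                f"{self.n_cells} cells for capacity {self.capacity}"
            )
        a0, a1, a2 = self.nucleus_semiaxes_nm
        if min(a0, a1, a2) <= 0:
            raise ValueError("nucleus semiaxes must be positive")
        if self.nucleus_center_height_nm + a0 >= self.cell_height_nm:
            raise ValueError("nucleus protrudes through the apical membrane")
        if self.nucleus_center_height_nm - a0 <= 0:
            raise ValueError("nucleus protrudes through the basal membrane")
        if 2 * max(a1, a2) >= self.cell_footprint_nm - 2 * self.boundary_jitter_nm:
            raise ValueError("nucleus is wider than the cell footprint")
        for params in self.phenotypes.values():
            params.validate(self.cell_height_nm)
        self.render.validate()

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "SceneConfig":
        allowed = {f.name for f in cls.__dataclass_fields__.values()}
        check_keys(data, allowed, "scene config")
        kwargs = dict(data)
        for key in ("voxel_spacing_nm", "cell_grid", "nucleus_semiaxes_nm"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "composition" in kwargs:
            comp = []
            for entry in kwargs["composition"]:
                if isinstance(entry, dict):
                    comp.append((str(entry["phenotype"]), int(entry["count"])))
                else:
                    comp.append((str(entry[0]), int(entry[1])))
            kwargs["composition"] = tuple(comp)
        if "phenotypes" in kwargs:
            merged = _default_phenotypes()
            for name, pdata in kwargs["phenotypes"].items():
                base = (
                    {
                        k: v
                        for k, v in asdict(merged[name]).items()
                        if k != "name"
                    }
                    if name in merged
                    else {}
                )
                base.update(pdata or {})
                merged[name] = PhenotypeParams.from_dict(name, base)
            kwargs["phenotypes"] = merged
        if "render" in kwargs:
            base = asdict(RenderParams())
            base.update(kwargs["render"] or {})
            kwargs["render"] = RenderParams.from_dict(base)
        config = cls(**kwargs)
        config.validate()
        return config

    def to_dict(self) -> dict:
        data = asdict(self)
        data["composition"] = [
            {"phenotype": name, "count": count} for name, count in self.composition
        ]
        data["phenotypes"] = {
            name: {k: v for k, v in asdict(p).items() if k != "name"}
            for name, p in self.phenotypes.items()
        }
        for key in ("voxel_spacing_nm", "cell_grid", "nucleus_semiaxes_nm"):
            data[key] = list(data[key])
        for p in data["phenotypes"].values():
            p["large_vesicle_count_range"] = list(p["large_vesicle_count_range"])
        return data


@dataclass
class LabelScene:
    """Aligned label grids of one scene: cells, nuclei, vesicles, lumen."""

    cells: VoxelGrid
    nuclei: VoxelGrid
    vesicles: VoxelGrid
    lumen: VoxelGrid

    def __post_init__(self):
        for grid in (self.nuclei, self.vesicles, self.lumen):
            if not grid.same_geometry_as(self.cells):
                raise ValueError("scene grids must share shape and spacing")

    @property
    def spacing_nm(self):
        return self.cells.spacing_nm


@dataclass
class GroundTruthTable:
    """Planted truth: one row per cell and one row per vesicle."""

    cells: pd.DataFrame
    vesicles: pd.DataFrame

    CELL_COLUMNS = (
        "cell_id",
        "phenotype",
        "n_secretory",
        "n_large",
        "n_apical_secretory",
    )
    VESICLE_COLUMNS = (
        "vesicle_id",
        "cell_id",
        "size_class",
        "center_z_nm",
        "center_y_nm",
        "center_x_nm",
        "diameter_nm",
        "apical",
    )


def default_config() -> SceneConfig:
    """The documented default scene: 20 cells (7/2/11), (50, 15, 15) nm."""
    config = SceneConfig()
    config.validate()
    return config


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal draw rejected outside mean +- 3 SD."""
    while True:
        value = rng.normal(mean, sd)
        if abs(value - mean) <= 3.0 * sd:
            return value


def _sphere_index_box(center_nm, radius_nm, spacing, shape):
    """Index ranges of the voxel bounding box of a sphere (clipped)."""
    lo = []
    hi = []
    for axis in range(3):
        c, r, s = center_nm[axis], radius_nm, spacing[axis]
        lo.append(max(0, int(math.ceil((c - r) / s - 0.5))))
        hi.append(min(shape[axis] - 1, int(math.floor((c + r) / s - 0.5))))
    return tuple(lo), tuple(hi)


def _sphere_mask(center_nm, radius_nm, spacing, lo, hi):
    """Boolean mask over the [lo, hi] index box: voxel centres inside sphere."""
    zz = (np.arange(lo[0], hi[0] + 1, dtype=np.float64) + 0.5) * spacing[0]
    yy = (np.arange(lo[1], hi[1] + 1, dtype=np.float64) + 0.5) * spacing[1]
    xx = (np.arange(lo[2], hi[2] + 1, dtype=np.float64) + 0.5) * spacing[2]
    dz = (zz - center_nm[0])[:, None, None] ** 2
    dy = (yy - center_nm[1])[None, :, None] ** 2
    dx = (xx - center_nm[2])[None, None, :] ** 2
    return dz + dy + dx <= radius_nm**2


_STRUCT6 = ndimage.generate_binary_structure(3, 1)


def _jittered_edges(n_cells: int, step: int, jitter_vox: int, rng) -> np.ndarray:
    edges = np.arange(n_cells + 1, dtype=np.int64) * step
    if jitter_vox > 0 and n_cells > 1:
        edges[1:-1] += rng.integers(-jitter_vox, jitter_vox + 1, size=n_cells - 1)
    return edges


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def build_scene(config: SceneConfig, seed: int | None = None):
    """Build one scene: label grids plus the planted ground truth.

    Returns ``(LabelScene, GroundTruthTable)``.  Bit-identical for a given
    ``(config, seed)``; ``seed`` defaults to ``config.seed``.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    root = int(seed) % (2**32)
    spacing = config.voxel_spacing_nm
    vz, vy, vx = spacing
    fz = config.height_voxels
    fy, fx = config.footprint_voxels
    rows, cols = config.cell_grid
    basal_vox = int(round(config.basal_margin_nm / vz))
    lumen_vox = max(1, int(round(config.lumen_thickness_nm / vz)))
    shape = (basal_vox + fz + lumen_vox, rows * fy, cols * fx)

    scene_rng = np.random.default_rng(np.random.SeedSequence(root, spawn_key=(0,)))
    jy = int(round(config.boundary_jitter_nm / vy))
    jx = int(round(config.boundary_jitter_nm / vx))
    y_edges = _jittered_edges(rows, fy, jy, scene_rng)
    x_edges = _jittered_edges(cols, fx, jx, scene_rng)

    cells = np.zeros(shape, dtype=np.uint16)
    nuclei = np.zeros(shape, dtype=np.uint16)
    vesicles = np.zeros(shape, dtype=np.uint16)
    lumen = np.zeros(shape, dtype=np.uint8)
    lumen[basal_vox + fz :] = 1

    z0, z1 = basal_vox, basal_vox + fz
    zb0_nm, zb1_nm = z0 * vz, z1 * vz

    phenotype_of_cell = []
    for name, count in config.composition:
        phenotype_of_cell.extend([name] * count)

    cell_rows = []
    vesicle_rows = []
    vesicle_id = 0
    a0, a1, a2 = config.nucleus_semiaxes_nm

    for cell_index in range(config.n_cells):
        cell_id = cell_index + 1
        r, c = divmod(cell_index, cols)
        ylo, yhi = int(y_edges[r]), int(y_edges[r + 1])
        xlo, xhi = int(x_edges[c]), int(x_edges[c + 1])
        cells[z0:z1, ylo:yhi, xlo:xhi] = cell_id

        # Nucleus: ellipsoid centred laterally in the cell, seated basally.
        center = np.array(
            [
                zb0_nm + config.nucleus_center_height_nm,
                (ylo + yhi) / 2.0 * vy,
                (xlo + xhi) / 2.0 * vx,
            ]
        )
        lo, hi = _sphere_index_box(center, max(a0, a1, a2), spacing, shape)
        zz = (np.arange(lo[0], hi[0] + 1) + 0.5) * vz
        yy = (np.arange(lo[1], hi[1] + 1) + 0.5) * vy
        xx = (np.arange(lo[2], hi[2] + 1) + 0.5) * vx
        ell = (
            ((zz - center[0]) / a0)[:, None, None] ** 2
            + ((yy - center[1]) / a1)[None, :, None] ** 2
            + ((xx - center[2]) / a2)[None, None, :] ** 2
        ) <= 1.0
        box = (slice(lo[0], hi[0] + 1), slice(lo[1], hi[1] + 1), slice(lo[2], hi[2] + 1))
        nuclei[box][ell] = cell_id

        nz = np.nonzero(ell.any(axis=(1, 2)))[0]
        nucleus_extent_nm = (lo[0] + nz.max() + 0.5) * vz

        params = config.phenotypes[phenotype_of_cell[cell_index]]
        rng = np.random.default_rng(
            np.random.SeedSequence(root, spawn_key=(cell_id,))
        )

        wall = config.wall_gap_nm
        y0w, y1w = ylo * vy, yhi * vy
        x0w, x1w = xlo * vx, xhi * vx

        def place(radius_nm, z_lo_nm, z_hi_nm, label):
            """Rejection-sample one non-overlapping sphere; stamp it."""
            if z_hi_nm <= z_lo_nm:
                raise PlacementError(
                    f"cell {cell_id}: no room along the axis for a vesicle of "
                    f"radius {radius_nm:.0f} nm"
                )
            for _ in range(config.placement_max_attempts):
                cz = rng.uniform(z_lo_nm, z_hi_nm)
                cy = rng.uniform(y0w + radius_nm + wall, y1w - radius_nm - wall)
                cx = rng.uniform(x0w + radius_nm + wall, x1w - radius_nm - wall)
                center = (cz, cy, cx)
                lo, hi = _sphere_index_box(center, radius_nm, spacing, shape)
                mask = _sphere_mask(center, radius_nm, spacing, lo, hi)
                if not mask.any():
                    continue
                box = (
                    slice(lo[0], hi[0] + 1),
                    slice(lo[1], hi[1] + 1),
                    slice(lo[2], hi[2] + 1),
                )
                if (cells[box][mask] != cell_id).any():
                    continue
                if nuclei[box][mask].any():
                    continue
                # 1-voxel clearance from other vesicles so distinct vesicles
                # never become face-adjacent (keeps 6-connected components
                # separable in renders).
                elo = tuple(max(0, l - 1) for l in lo)
                ehi = tuple(min(s - 1, h + 1) for s, h in zip(shape, hi))
                ebox = (
                    slice(elo[0], ehi[0] + 1),
                    slice(elo[1], ehi[1] + 1),
                    slice(elo[2], ehi[2] + 1),
                )
                pad = np.zeros(tuple(e - s + 1 for s, e in zip(elo, ehi)), dtype=bool)
                inner = tuple(
                    slice(l - el, l - el + m)
                    for l, el, m in zip(lo, elo, mask.shape)
                )
                pad[inner] = mask
                grown = ndimage.binary_dilation(pad, structure=_STRUCT6)
                if vesicles[ebox][grown].any():
                    continue
                vesicles[box][mask] = label
                return center
            raise PlacementError(
                f"cell {cell_id}: failed to place a vesicle of radius "
                f"{radius_nm:.0f} nm after {config.placement_max_attempts} attempts"
            )

        # Large electron-dense vesicles first (they need the most room).
        n_large = int(
            rng.integers(
                params.large_vesicle_count_range[0],
                params.large_vesicle_count_range[1] + 1,
            )
        )
        for _ in range(n_large):
            diam = _truncated_normal(rng, params.large_diam_mean_nm, params.large_diam_sd_nm)
            radius = diam / 2.0
            vesicle_id += 1
            center = place(radius, zb0_nm + radius, zb1_nm - radius, vesicle_id)
            vesicle_rows.append(
                (
                    vesicle_id,
                    cell_id,
                    "large",
                    center[0],
                    center[1],
                    center[2],
                    diam,
                    bool(center[0] > nucleus_extent_nm),
                )
            )

        # Secretory vesicles: Bernoulli(apical_bias) chooses the compartment.
        n_secretory = int(rng.poisson(params.vesicle_count_mean))
        n_apical = 0
        for _ in range(n_secretory):
            apical = bool(rng.random() < params.apical_bias)
            diam = _truncated_normal(
                rng, params.secretory_diam_mean_nm, params.secretory_diam_sd_nm
            )
            radius = diam / 2.0
            margin = config.plant_margin_nm
            if apical:
                z_lo = max(zb0_nm + radius, nucleus_extent_nm + margin)
                z_hi = zb1_nm - radius
            else:
                z_lo = zb0_nm + radius
                z_hi = min(zb1_nm - radius, nucleus_extent_nm - margin)
            vesicle_id += 1
            center = place(radius, z_lo, z_hi, vesicle_id)
            n_apical += apical
            vesicle_rows.append(
                (
                    vesicle_id,
                    cell_id,
                    "secretory",
                    center[0],
                    center[1],
                    center[2],
                    diam,
                    apical,
                )
            )

        cell_rows.append(
            (
                cell_id,
                phenotype_of_cell[cell_index],
                n_secretory,
                n_large,
                n_apical,
            )
        )

    if vesicle_id > 65535:
        raise ValueError(
            f"scene contains {vesicle_id} vesicles, exceeding uint16 labels"
        )

    scene = LabelScene(
        cells=VoxelGrid(cells, spacing),
        nuclei=VoxelGrid(nuclei, spacing),
        vesicles=VoxelGrid(vesicles, spacing),
        lumen=VoxelGrid(lumen, spacing),
    )
    truth = GroundTruthTable(
        cells=pd.DataFrame(cell_rows, columns=list(GroundTruthTable.CELL_COLUMNS)),
        vesicles=pd.DataFrame(
            vesicle_rows, columns=list(GroundTruthTable.VESICLE_COLUMNS)
        ),
    )
    return scene, truth


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_grayscale(
    scene: LabelScene, config: SceneConfig, seed: int | None = None
) -> VoxelGrid:
    """Render an 8-bit grayscale volume from the label grids.

    Vesicle labels are split into bright secretory and dark large classes
    by their equivalent spherical diameter (600 nm cutoff).  Gaussian noise
    of ``config.render.noise_sd`` is added and clipped to [0, 255];
    deterministic given ``seed`` (defaults to ``config.seed``).
    """
    if seed is None:
        seed = config.seed
    rp = config.render
    cells = scene.cells.values
    out = np.full(cells.shape, rp.background, dtype=np.uint8)
    out[cells > 0] = rp.cytoplasm

    # Darken 1-voxel seams where two different cell labels meet.
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        left, right = cells[tuple(a)], cells[tuple(b)]
        seam = (left != right) & (left > 0) & (right > 0)
        view = out[tuple(a)]
        view[seam] = rp.boundary

    out[scene.nuclei.values > 0] = rp.nucleus

    ves = scene.vesicles.values
    counts = np.bincount(ves.ravel())
    if len(counts) > 1:
        voxvol = scene.vesicles.voxel_volume_nm3
        eq_diam = np.zeros(len(counts))
        present = counts > 0
        eq_diam[present] = (6.0 * counts[present] * voxvol / math.pi) ** (1.0 / 3.0)
        lut = np.full(len(counts), rp.cytoplasm, dtype=np.uint8)
        lut[present & (eq_diam < 600.0)] = rp.secretory_vesicle
        lut[present & (eq_diam >= 600.0)] = rp.large_vesicle
        lut[0] = 0
        inside = ves > 0
        out[inside] = lut[ves[inside]]

    out[scene.lumen.values > 0] = rp.lumen

    if rp.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(int(seed) % (2**32), spawn_key=(999,))
        )
        noisy = out.astype(np.float32)
        noisy += rng.standard_normal(out.shape, dtype=np.float32) * np.float32(rp.noise_sd)
        out = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    return VoxelGrid(out, scene.spacing_nm)


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_scene(
    scene: LabelScene,
    truth: GroundTruthTable,
    config: SceneConfig,
    outdir,
    render: VoxelGrid | None = None,
    fmt: str = "tif",
) -> None:
    """Write label stacks, ground-truth tables and a config echo to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(scene.cells, outdir / f"cells.{fmt}")
    write_volume(scene.nuclei, outdir / f"nuclei.{fmt}")
    write_volume(scene.vesicles, outdir / f"vesicles.{fmt}")
    write_volume(scene.lumen, outdir / f"lumen.{fmt}")
    if render is not None:
        write_volume(render, outdir / f"render.{fmt}")
    truth.cells.to_csv(outdir / "ground_truth_cells.csv", index=False)
    truth.vesicles.to_csv(outdir / "ground_truth_vesicles.csv", index=False)
    (outdir / "scene_config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False)
    )
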