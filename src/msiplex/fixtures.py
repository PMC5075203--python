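"""Synthetic cultured-cell confocal fixtures with known ground truth.

Cultured-cell style scenes — scattered, non-overlapping, roughly round cells,
no crypt architecture — rendered into three channels: a DAPI-like nuclear
channel, an ER-like cytoplasm channel with strictly zero inter-cell background
(so background seeding works), and one organelle-marker channel painted from
organelle instances drawn by the simulator.  The ground-truth label maps and
feature table make the whole segmentation/learning pipeline testable without
any external image download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .distributions import FittedPDF
from .io import ChannelStack, write_stack
from .learning import FEATURE_COLUMNS, LabelMap
from .organelles import OrganelleInstance, populate_cell
from .proteins import procedural_texture
from .raster import rasterize_polygon, rasterize_sample
from .scaffold import CellGeometry, TissueSample, deformed_circle


class FixturePlacementError(RuntimeError):
    pass


@dataclass
class FixtureSpec:
    n_cells: int = 10
    organelle: str = "nucleoli"
    pdfs: dict[str, FittedPDF] | dict[tuple[str, str], FittedPDF] = field(
        default_factory=dict)
    nucleus_diameter_um: tuple[float, float] = (9.0, 13.0)
    cell_radius_um: float = 12.0
    pixel_size: float = 0.25
    width: int = 512
    height: int = 512
    noise: float = 0.0
    seed: int = 0
    # minimum clearance between planted organelles (px); None allows touching
    min_separation_px: float | None = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_diameter_um
        if not (0 < lo <= hi < 40):
            raise ValueError("nucleus diameter range must sit inside (0, 40) um")
        if not 0 <= self.noise < 1:
            raise ValueError("noise level must be in [0, 1)")


@dataclass
class FixtureResult:
    stack: ChannelStack
    nuclei: LabelMap
    cells: LabelMap
    organelles: LabelMap
    features: pd.DataFrame
    sample: TissueSample
    instances: list[OrganelleInstance]


def _place_cells(spec: FixtureSpec, rng: np.random.Generator
                 ) -> list[CellGeometry]:
    r_px = spec.cell_radius_um / spec.pixel_size
    irr = 0.06
    max_r = r_px * (1 + irr) + 1
    margin = max_r + 2
    # jittered grid: scattered but guaranteed non-overlapping
    spacing = 2 * max_r + 4
    nx = int((spec.width - 2 * margin) // spacing) + 1
    ny = int((spec.height - 2 * margin) // spacing) + 1
    if nx * ny < spec.n_cells:
        raise FixturePlacementError(
            "cannot place cells without overlap at this density")
    slots = [(margin + i * spacing, margin + j * spacing)
             for j in range(ny) for i in range(nx)]
    chosen = rng.choice(len(slots), size=spec.n_cells, replace=False)
    jitter = (spacing - 2 * max_r - 2) / 2
    centres = [np.asarray(slots[int(k)], dtype=float)
               + rng.uniform(-jitter, jitter, 2) for k in chosen]
    cells = []
    nuc_px = (spec.nucleus_diameter_um[0] / spec.pixel_size,
              spec.nucleus_diameter_um[1] / spec.pixel_size)
    for cid, c in enumerate(centres, start=1):
        poly = deformed_circle(c, r_px * rng.uniform(0.92, 1.0), r_px, irr,
                               24, rng, rotation=rng.uniform(0, 2 * np.pi))
        diam = rng.uniform(*nuc_px)
        nuc_irr = 0.04
        minor_semi = diam / 2
        ar = rng.uniform(0.88, 1.0)
        major_semi = min(minor_semi / ar, (r_px * 0.9) / (1 + nuc_irr))
        minor_semi = min(minor_semi, major_semi)
        npoly = deformed_circle(c, minor_semi, major_semi, nuc_irr, 24, rng,
                                rotation=rng.uniform(0, 2 * np.pi))
        cells.append(CellGeometry(cid, "epithelial", poly, npoly,
                                  (float(c[0]), float(c[1])),
                                  2 * minor_semi, 2 * major_semi,
                                  crypt_id=None))
    return cells


def _truth_features(cells: list[CellGeometry],
                    instances: list[OrganelleInstance],
                    organelle: str) -> pd.DataFrame:
    by_cell: dict[int, CellGeometry] = {c.cell_id: c for c in cells}
    counts: dict[int, int] = {}
    for inst in instances:
        counts[inst.cell_id] = counts.get(inst.cell_id, 0) + 1
    rows = []
    for inst in instances:
        cell = by_cell[inst.cell_id]
        shape = Polygon(inst.polygon)
        ref = (cell.nucleus_shape().area if organelle == "nucleoli"
               else cell.cell_shape().area)
        rows.append({
            "cell_id": inst.cell_id, "organelle": organelle,
            "count_per_cell": counts[inst.cell_id],
            "minor_axis_ratio": inst.minor_axis / cell.nucleus_minor_axis,
            "axes_ratio": inst.minor_axis / inst.major_axis,
            "D": inst.D,
            "solidity": shape.area / shape.convex_hull.area,
            "area_fraction": shape.area / ref,
        })
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def generate_fixture(spec: FixtureSpec) -> FixtureResult:
    """Render a three-channel fixture plus label-map/feature ground truth."""
    rng = np.random.default_rng(spec.seed)
    cells = _place_cells(spec, rng)
    sample = TissueSample(width=spec.width, height=spec.height,
                          pixel_size=spec.pixel_size, magnification="40x",
                          grade="healthy", cells=cells, seed=spec.seed)
    instances: list[OrganelleInstance] = []
    for cell in cells:
        drawn = populate_cell(cell, spec.organelle, spec.pdfs, rng)
        if spec.min_separation_px is not None:
            # keep the planted set separable so object-level ground truth
            # is well defined; touching-organelle behaviour is tested with
            # hand-built adjacency scenes instead
            kept: list[OrganelleInstance] = []
            shapes = []
            for inst in drawn:
                shape = Polygon(inst.polygon)
                if all(shape.distance(o) >= spec.min_separation_px
                       for o in shapes):
                    kept.append(inst)
                    shapes.append(shape)
            drawn = kept
        instances.extend(drawn)
    rasters = rasterize_sample(sample, {spec.organelle: instances})
    shape = rasters.shape

    chrom = procedural_texture(shape, "chromatin", rng=rng)
    smooth = procedural_texture(shape, "smooth_noise", rng=rng)
    dapi = np.where(rasters.nucleus_labels > 0, 0.55 + 0.4 * chrom, 0.0)
    er = np.where(rasters.cell_labels > 0, 0.35 + 0.4 * smooth, 0.0)
    org_mask = rasters.organelle_labels[spec.organelle] > 0
    marker = np.where(org_mask, 0.75 + 0.25 * smooth, 0.0)
    channels = {"dapi": dapi, "er": er, "marker": marker}
    if spec.noise > 0:
        for name in channels:
            noisy = channels[name] + rng.normal(0, spec.noise, shape)
            channels[name] = np.clip(noisy, 0.0, 1.0)

    stack = ChannelStack(channels=channels, pixel_size=spec.pixel_size)
    features = _truth_features(cells, instances, spec.organelle)
    # ground-truth organelle label map: one label per instance
    org_labels = np.zeros(shape, dtype=np.int32)
    for k, inst in enumerate(instances, start=1):
        rr, cc = rasterize_polygon(inst.polygon, shape)
        org_labels[rr, cc] = k
    return FixtureResult(
        stack=stack,
        nuclei=LabelMap(rasters.nucleus_labels.copy(), spec.pixel_size),
        cells=LabelMap(rasters.cell_labels.copy(), spec.pixel_size),
        organelles=LabelMap(org_labels, spec.pixel_size),
        features=features, sample=sample, instances=instances)


def write_fixture(result: FixtureResult, out_dir: str | Path,
                  stem: str = "fixture") -> dict[str, Path]:
    """Write TIFF channels plus ground-truth CSV/JSON to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, img in result.stack.channels.items():
        p = out / f"{stem}_{name}.tif"
        write_stack(ChannelStack({name: img}, result.stack.pixel_size), p)
        paths[name] = p
    fpath = out / f"{stem}_features.csv"
    result.features.to_csv(fpath, index=False)
    paths["features"] = fpath
    gpath = out / f"{stem}_geometry.json"
    gpath.write_text(result.sample.to_json())
    paths["geometry"] = gpath
    return paths
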