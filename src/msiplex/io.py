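"""Channel stacks, configuration and the end-to-end sample generator.

Stacks are written as multi-page TIFF with channel names and pixel size in the
image description (JSON), intensities stored as 16-bit scaled from [0, 1].
``generate_sample`` orchestrates scaffold -> organelles -> mutation status ->
expression -> rendered channels, and returns a ground-truth sidecar (plain
dict, JSON-serialisable) with the full geometry, organelle instances, mutation
status and per-cell expression for downstream benchmarking.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import tifffile
import yaml

from . import proteins as prot
from .distributions import PDFSet, load_default_pdfs, load_parameter_file
from .organelles import populate_sample
from .raster import rasterize_sample
from .scaffold import ScaffoldConfig, generate_scaffold

logger = logging.getLogger("msiplex")

MAGNIFICATION_PIXEL_SIZE_UM = {"20x": 0.5, "40x": 0.25}

REFERENCE_CHANNELS = ("nuclear", "cytoplasm")


class StackFormatError(ValueError):
    pass


@dataclass
class ChannelStack:
    """Named co-registered 2-D intensity channels in [0, 1]."""

    channels: dict[str, np.ndarray]
    pixel_size: float

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise StackFormatError("channels differ in shape")

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def as_array(self) -> np.ndarray:
        return np.stack(list(self.channels.values()))


def write_stack(stack: ChannelStack, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise StackFormatError(f"unknown extension {path.suffix!r}")
    arr = np.clip(stack.as_array(), 0.0, 1.0)
    u16 = np.round(arr * 65535.0).astype(np.uint16)
    meta = {"channel_names": stack.channel_names,
            "pixel_size_um": stack.pixel_size}
    tifffile.imwrite(path, u16, description=json.dumps(meta),
                     photometric="minisblack")
    return path


def read_stack(path: str | Path) -> ChannelStack:
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise StackFormatError(f"unknown extension {path.suffix!r}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description or ""
    if arr.ndim == 2:
        arr = arr[None]
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / float(np.iinfo(arr.dtype).max)
    names = [f"channel_{i}" for i in range(arr.shape[0])]
    pixel_size = 1.0
    try:
        meta = json.loads(desc)
        names = list(meta.get("channel_names", names))
        pixel_size = float(meta.get("pixel_size_um", pixel_size))
    except (json.JSONDecodeError, TypeError):
        pass
    return ChannelStack(channels=dict(zip(names, arr)), pixel_size=pixel_size)


@dataclass
class GenerationConfig:
    """Everything needed to generate one synthetic tissue sample."""

    scaffold: ScaffoldConfig
    seed: int
    params_path: str | None = None  # None -> packaged defaults
    # per protein: {"imaged": bool, "epithelial_fraction": float | None}
    proteins: dict[str, dict] = field(default_factory=dict)
    mutation: dict = field(default_factory=lambda: {"representative": True,
                                                    "gene": None})
    levels: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.proteins:
            if name not in prot.PROTEINS:
                raise prot.ConfigurationError(
                    f"no compartment profile for protein {name!r}")

    @property
    def imaged_proteins(self) -> list[str]:
        return [p for p, cfg in self.proteins.items() if cfg.get("imaged")]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GenerationConfig":
        doc = yaml.safe_load(Path(path).read_text())
        if "seed" not in doc:
            raise prot.ConfigurationError("config must set a seed")
        sc = dict(doc.get("scaffold", {}))
        sc.setdefault("seed", doc["seed"])
        mag = sc.get("magnification")
        if mag and "pixel_size_um" not in sc:
            sc["pixel_size_um"] = MAGNIFICATION_PIXEL_SIZE_UM[mag]
        return cls(scaffold=ScaffoldConfig(**sc), seed=int(doc["seed"]),
                   params_path=doc.get("params"),
                   proteins=dict(doc.get("proteins", {})),
                   mutation=dict(doc.get("mutation",
                                         {"representative": True,
                                          "gene": None})),
                   levels=dict(doc.get("levels", {})))

    def config_hash(self) -> str:
        blob = json.dumps({
            "scaffold": self.scaffold.__dict__, "seed": self.seed,
            "params": self.params_path, "proteins": self.proteins,
            "mutation": self.mutation, "levels": self.levels,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_pdfs(config: GenerationConfig) -> PDFSet:
    if config.params_path:
        return load_parameter_file(config.params_path)
    return load_default_pdfs()


def generate_sample(config: GenerationConfig
                    ) -> tuple[ChannelStack, dict]:
    """Run the full generative pipeline for one sample.

    Returns the channel stack (nuclear + cytoplasm reference channels plus one
    channel per imaged protein) and the ground-truth sidecar dict.
    """
    t0 = time.perf_counter()
    logger.info("generate_sample config=%s seed=%d",
                config.config_hash(), config.seed)
    rng = np.random.default_rng(config.seed)
    sample = generate_scaffold(config.scaffold, rng)
    pdfs = _load_pdfs(config)
    organelles = populate_sample(sample, pdfs, rng)

    overrides: dict = {}
    gene = config.mutation.get("gene")
    if gene is not None:
        overrides["mutated_gene"] = gene
    fractions = {p: cfg["epithelial_fraction"]
                 for p, cfg in config.proteins.items()
                 if cfg.get("epithelial_fraction") is not None}
    if fractions:
        overrides["epithelial_fraction"] = fractions
    status = prot.sample_mutation_status(
        population_representative=bool(config.mutation.get("representative",
                                                           True)),
        user_overrides=overrides or None, rng=rng)
    expression = prot.assign_expression(sample, status, rng)

    rasters = rasterize_sample(sample, organelles)
    channels: dict[str, np.ndarray] = {}
    nuc_tex = prot.procedural_texture(rasters.shape, "chromatin", rng=rng)
    cyto_tex = prot.procedural_texture(rasters.shape, "smooth_noise", rng=rng)
    channels["nuclear"] = np.where(rasters.nucleus_labels > 0,
                                   0.55 + 0.4 * nuc_tex, 0.0)
    channels["cytoplasm"] = np.where(rasters.cell_labels > 0,
                                     0.35 + 0.4 * cyto_tex, 0.0)
    for protein in config.imaged_proteins:
        channels[protein] = prot.render_channel(
            protein, sample, organelles, expression, rng,
            rasters=rasters, levels=config.levels or None)
    stack = ChannelStack(channels=channels, pixel_size=sample.pixel_size)

    per_cell: dict[int, dict] = {}
    for cell in sample.cells:
        per_cell[cell.cell_id] = {
            "phenotype": cell.phenotype,
            "crypt_id": cell.crypt_id,
            "cell_area": cell.cell_shape().area,
            "nucleus_area": cell.nucleus_shape().area,
            "organelle_area": {o: 0.0 for o in organelles},
            "organelle_count": {o: 0 for o in organelles},
        }
    instances = []
    for org, insts in organelles.items():
        for inst in insts:
            rec = per_cell[inst.cell_id]
            rec["organelle_area"][org] += inst.area
            rec["organelle_count"][org] += 1
            instances.append({
                "organelle": org, "cell_id": inst.cell_id,
                "centre": list(inst.centre), "minor_axis": inst.minor_axis,
                "major_axis": inst.major_axis, "D": inst.D,
                "area": inst.area,
            })
    ground_truth = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "pixel_size_um": sample.pixel_size,
        "grade": sample.grade,
        "mutation_status": {
            "mutated_gene": status.mutated_gene,
            "lost_proteins": sorted(prot.lost_proteins(status.mutated_gene)),
            "p53_overexpressed": status.p53_overexpressed,
            "pten_stromal_fraction": status.pten_stromal_fraction,
            "epithelial_fraction": status.epithelial_fraction,
        },
        "expression": {p: sorted(ids)
                       for p, ids in expression.expressors.items()},
        "cells": per_cell,
        "organelles": instances,
        "geometry_json": sample.to_json(),
    }
    logger.info("generate_sample done in %.1fs (%d cells, %d organelles)",
                time.perf_counter() - t0, len(sample.cells), len(instances))
    return stack, ground_truth


def save_ground_truth(ground_truth: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(ground_truth))
    return path
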