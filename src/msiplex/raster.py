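"""Rasterisation of scene geometry into label images.

Polygons use (x, y) pixel coordinates; arrays are indexed [row, col] = [y, x].
Cell and nucleus label images carry the cell_id of the owning cell; organelle
rasters likewise carry the owning cell_id so channel rendering can restrict a
compartment to the cells that express a protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon

from .organelles import OrganelleInstance
from .scaffold import TissueSample


def rasterize_polygon(poly: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of pixels inside a polygon, clipped to the image."""
    poly = np.asarray(poly)
    rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=shape)
    return rr, cc


@dataclass
class CompartmentRasters:
    """Label images for all compartments of a tissue sample."""

    shape: tuple[int, int]
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    organelle_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def compartment_mask(self, compartment: str) -> np.ndarray:
        """Label image (owning cell_id per pixel) for a named compartment."""
        if compartment == "nucleus":
            return self.nucleus_labels
        if compartment == "cytoplasm":
            return np.where(self.nucleus_labels > 0, 0, self.cell_labels)
        if compartment == "nucleus_minus_nucleoli":
            nucleoli = self.organelle_labels.get("nucleoli")
            if nucleoli is None:
                raise KeyError(
                    "compartment 'nucleus_minus_nucleoli' needs a nucleoli layer")
            return np.where(nucleoli > 0, 0, self.nucleus_labels)
        if compartment in ("nucleoli", "golgi", "vesicles"):
            try:
                return self.organelle_labels[compartment]
            except KeyError:
                raise KeyError(
                    f"missing organelle layer for compartment {compartment!r}")
        raise KeyError(f"unknown compartment {compartment!r}")


def rasterize_sample(sample: TissueSample,
                     organelles: Mapping[str, Sequence[OrganelleInstance]] | None = None
                     ) -> CompartmentRasters:
    shape = (sample.height, sample.width)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    for cell in sample.cells:
        rr, cc = rasterize_polygon(cell.cell_polygon, shape)
        cell_labels[rr, cc] = cell.cell_id
        rr, cc = rasterize_polygon(cell.nucleus_polygon, shape)
        nucleus_labels[rr, cc] = cell.cell_id
    organelle_labels: dict[str, np.ndarray] = {}
    for org, instances in (organelles or {}).items():
        layer = np.zeros(shape, dtype=np.int32)
        for inst in instances:
            rr, cc = rasterize_polygon(inst.polygon, shape)
            layer[rr, cc] = inst.cell_id
        organelle_labels[org] = layer
    return CompartmentRasters(shape=shape, cell_labels=cell_labels,
                              nucleus_labels=nucleus_labels,
                              organelle_labels=organelle_labels)
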