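"""Segmentation and feature-learning pipeline for confocal-style images.

The pipeline mirrors how organelle models are learned from real
immunofluorescence data of cultured cells: nuclei are segmented from the
DAPI channel by modal-intensity thresholding and cleaned seeds, cells by a
seeded watershed on the inverted endoplasmic-reticulum channel, nucleoli by
thresholding plus watershed with a [0.5, 3] um diameter filter, and small
punctate organelles (golgi, vesicles) by local-mean highlighting followed by
Otsu thresholding with a 5-pixel noise floor.  Six morphological features per
organelle feed maximum-likelihood distribution fits that the simulator can
consume directly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .distributions import PDFSet, fit_pdf  # re-exported for the pipeline
from .organelles import PositionMeasurement

NUCLEUS_DIAMETER_UM = (5.0, 20.0)
NUCLEOLUS_DIAMETER_UM = (0.5, 3.0)
MIN_PUNCTA_PIXELS = 5

EROSION_RADIUS_PX = 2
SMALL_OBJECT_CUTOFF_PX = 50
ADAPTIVE_MEAN_WINDOW_PX = 15

FEATURE_COLUMNS = ["cell_id", "organelle", "count_per_cell",
                   "minor_axis_ratio", "axes_ratio", "D", "solidity",
                   "area_fraction"]


@dataclass
class LabelMap:
    """Integer label image: 0 is background, labels contiguous 1..K."""

    labels: np.ndarray
    pixel_size: float = 1.0
    connectivity: int = 2

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())


def _contiguous(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def _modal_threshold(image: np.ndarray) -> float:
    """Intensity of the most common pixel, on a 256-bin quantisation."""
    finite = image[np.isfinite(image)]
    hist, edges = np.histogram(finite, bins=256)
    k = int(np.argmax(hist))
    return float((edges[k] + edges[k + 1]) / 2)


def _diameter_filter(labels: np.ndarray, pixel_size: float,
                     diam_range_um: tuple[float, float]) -> np.ndarray:
    out = labels.copy()
    for region in measure.regionprops(labels):
        diam_um = region.equivalent_diameter_area * pixel_size
        if not diam_range_um[0] <= diam_um <= diam_range_um[1]:
            out[labels == region.label] = 0
    return _contiguous(out)


def segment_nuclei(dapi: np.ndarray, pixel_size: float) -> LabelMap:
    """Nuclei from the DAPI channel by modal thresholding and seed cleaning.

    Threshold at the modal intensity, erode, drop small objects and objects
    touching the border, then remove nuclei whose equivalent diameter falls
    outside the [5, 20] um plausibility band.
    """
    thr = _modal_threshold(dapi)
    binary = dapi > thr
    if not binary.any():
        return LabelMap(np.zeros(dapi.shape, np.int32), pixel_size)
    binary = morphology.erosion(binary, morphology.disk(EROSION_RADIUS_PX))
    binary = morphology.remove_small_objects(
        binary, max_size=SMALL_OBJECT_CUTOFF_PX - 1)
    binary = segmentation.clear_border(binary)
    labels = measure.label(binary, connectivity=2).astype(np.int32)
    labels = _diameter_filter(labels, pixel_size, NUCLEUS_DIAMETER_UM)
    return LabelMap(labels, pixel_size)


def segment_cells(er: np.ndarray, nuclei: LabelMap) -> LabelMap:
    """Seeded watershed on the inverted ER channel.

    Nuclei are the foreground seeds; large zero-intensity ER areas are the
    background seed.  The result has exactly one region per nucleus seed,
    labelled to match the nucleus labels.
    """
    if er.shape != nuclei.labels.shape:
        raise ValueError("ER image and nucleus labels differ in shape")
    if nuclei.n_objects == 0:
        return LabelMap(np.zeros(er.shape, np.int32), nuclei.pixel_size)
    er_s = ndimage.median_filter(er, size=3)
    background = er_s <= 0
    background = morphology.remove_small_objects(
        background, max_size=SMALL_OBJECT_CUTOFF_PX - 1)
    bg_label = nuclei.n_objects + 1
    markers = nuclei.labels.copy()
    markers[background & (markers == 0)] = bg_label
    ws = segmentation.watershed(-er_s, markers=markers)
    ws[ws == bg_label] = 0
    return LabelMap(ws.astype(np.int32), nuclei.pixel_size)


def segment_nucleoli(channel: np.ndarray, nuclei: LabelMap,
                     pixel_size: float) -> LabelMap:
    """Nucleoli by background-noise thresholding, watershed and size filter.

    The background threshold reuses the modal-intensity rule; objects with
    equivalent diameter outside [0.5, 3] um are removed.
    """
    thr = _modal_threshold(channel)
    binary = channel > thr
    if not binary.any():
        return LabelMap(np.zeros(channel.shape, np.int32), pixel_size)
    components = measure.label(binary, connectivity=2)
    eroded = morphology.erosion(binary, morphology.disk(1))
    seed_mask = eroded.copy()
    # objects too small to survive erosion keep their full footprint as seed
    surviving = np.unique(components[eroded])
    lost = np.setdiff1d(np.unique(components[components > 0]), surviving)
    if lost.size:
        seed_mask |= np.isin(components, lost)
    seeds = measure.label(seed_mask, connectivity=2)
    bg_label = int(seeds.max()) + 1
    markers = seeds.copy()
    markers[~morphology.dilation(binary, morphology.disk(2))] = bg_label
    ws = segmentation.watershed(-channel, markers=markers, mask=binary)
    ws[ws == bg_label] = 0
    labels = _diameter_filter(ws.astype(np.int32), pixel_size,
                              NUCLEOLUS_DIAMETER_UM)
    return LabelMap(labels, pixel_size)


def segment_puncta(channel: np.ndarray, cells: LabelMap) -> LabelMap:
    """Small punctate organelles by adaptive-mean highlighting + Otsu.

    The local mean (15 px window) is subtracted to highlight punctate
    features, the result is Otsu-thresholded, and components below 5 pixels
    are discarded as noise.  Touching organelles merge into one object — an
    accepted resolution limit of thresholding-based segmentation.
    """
    smoothed = filters.gaussian(channel, sigma=1.0, preserve_range=True)
    highlight = smoothed - ndimage.uniform_filter(smoothed,
                                                  ADAPTIVE_MEAN_WINDOW_PX)
    # Otsu with a robust noise floor: on sparse punctate images Otsu alone
    # splits the background mode, so the threshold is floored at a MAD-based
    # estimate of the background fluctuation; hysteresis growing preserves
    # the footprint of small objects that strong thresholding would shrink
    med = float(np.median(highlight))
    mad = float(np.median(np.abs(highlight - med))) * 1.4826
    high = max(float(filters.threshold_otsu(highlight)), med + 5 * mad)
    low = med + 2 * mad
    binary = filters.apply_hysteresis_threshold(highlight, low, high)
    # the 5-pixel noise rule is applied to the un-smoothed support of each
    # component, so smoothing cannot inflate a sub-threshold speck past it
    raw = channel - ndimage.uniform_filter(channel, ADAPTIVE_MEAN_WINDOW_PX)
    rmed = float(np.median(raw))
    rmad = float(np.median(np.abs(raw - rmed))) * 1.4826
    support = raw > max(float(filters.threshold_otsu(raw)), rmed + 5 * rmad)
    labels = measure.label(binary, connectivity=2).astype(np.int32)
    keep = np.zeros_like(labels)
    for region in measure.regionprops(labels):
        inside = labels[region.slice] == region.label
        if support[region.slice][inside].sum() >= MIN_PUNCTA_PIXELS:
            keep[labels == region.label] = region.label
    return LabelMap(_contiguous(keep), cells.pixel_size)


def _march_distance(mask: np.ndarray, origin: np.ndarray,
                    direction: np.ndarray, step: float = 0.25) -> float:
    """Distance along a ray until the mask is first left (nearest-pixel)."""
    h, w = mask.shape
    t = 0.0
    max_t = math.hypot(h, w) + 2
    while t < max_t:
        x = origin[0] + t * direction[0]
        y = origin[1] + t * direction[1]
        r, c = int(round(y)), int(round(x))
        if not (0 <= r < h and 0 <= c < w) or not mask[r, c]:
            return t
        t += step
    return max_t


def position_feature_from_masks(nucleus_mask: np.ndarray,
                                cell_mask: np.ndarray,
                                nucleus_centre: np.ndarray,
                                point: np.ndarray) -> PositionMeasurement:
    """Pixel-mask analogue of the polygon position feature."""
    vec = point - nucleus_centre
    o = float(np.hypot(*vec))
    direction = vec / o if o > 1e-9 else np.array([1.0, 0.0])
    n = _march_distance(nucleus_mask, nucleus_centre, direction)
    total = _march_distance(cell_mask, nucleus_centre, direction)
    return PositionMeasurement(N=max(n, 0.25), O=o, C=max(total - n, 0.0))


def extract_features(organelles: LabelMap, cells: LabelMap, nuclei: LabelMap,
                     organelle_name: str = "organelle") -> pd.DataFrame:
    """Per-organelle morphological features, referenced to the owning cell.

    Organelles are assigned to the cell containing their centroid; an
    organelle landing in a cell with no nucleus is dropped with a warning.
    Axes come from second-central-moment ellipse fits; the area fraction uses
    the nuclear area for nucleoli and the cell area otherwise.
    """
    cell_props = {r.label: r for r in measure.regionprops(cells.labels)}
    nuc_props = {r.label: r for r in measure.regionprops(nuclei.labels)}
    mask_cache: dict[int, tuple[np.ndarray, np.ndarray, tuple[int, int]]] = {}

    def masks_for(cell_id: int):
        # masks cropped to the cell bounding box to keep memory bounded
        if cell_id not in mask_cache:
            minr, minc, maxr, maxc = cell_props[cell_id].bbox
            window = (slice(minr, maxr), slice(minc, maxc))
            mask_cache[cell_id] = (nuclei.labels[window] == cell_id,
                                   cells.labels[window] == cell_id,
                                   (minr, minc))
        return mask_cache[cell_id]

    rows = []
    counts: dict[int, int] = {}
    for region in measure.regionprops(organelles.labels):
        cy, cx = region.centroid
        cell_id = int(cells.labels[int(round(cy)), int(round(cx))])
        if cell_id == 0 or cell_id not in cell_props:
            continue
        nuc = nuc_props.get(cell_id)
        if nuc is None:
            warnings.warn(f"organelle {region.label} in cell {cell_id} "
                          "with no nucleus; row dropped")
            continue
        counts[cell_id] = counts.get(cell_id, 0) + 1
        nuc_cy, nuc_cx = nuc.centroid
        nuc_mask, cell_mask, (minr, minc) = masks_for(cell_id)
        pm = position_feature_from_masks(
            nuc_mask, cell_mask,
            np.array([nuc_cx - minc, nuc_cy - minr]),
            np.array([cx - minc, cy - minr]))
        minor = region.axis_minor_length
        major = max(region.axis_major_length, 1e-6)
        # tiny rasterised objects can have a degenerate zero minor axis
        minor = max(minor, 1.0)
        major = max(major, minor)
        ref_area = (nuc.area if organelle_name == "nucleoli"
                    else cell_props[cell_id].area)
        rows.append({
            "cell_id": cell_id, "organelle": organelle_name,
            "count_per_cell": 0,  # filled below
            "minor_axis_ratio": minor / max(nuc.axis_minor_length, 1e-6),
            "axes_ratio": min(minor / major, 1.0),
            "D": pm.D,
            "solidity": region.solidity,
            "area_fraction": region.area / ref_area,
        })
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if len(df):
        df["count_per_cell"] = df["cell_id"].map(counts)
    return df


def fit_organelle_pdfs(features: pd.DataFrame, organelle: str) -> PDFSet:
    """MLE fits of the four model distributions for one organelle type.

    Counts and both ratios use gamma; the position feature uses gamma for the
    intranuclear nucleoli and the heavy-tailed t location-scale for golgi and
    vesicles.  Zero counts are clipped to 0.5 so the continuous gamma density
    can be evaluated.
    """
    sub = features[features["organelle"] == organelle]
    counts = (sub.drop_duplicates("cell_id")["count_per_cell"]
              .astype(float).clip(lower=0.5))
    out: PDFSet = {}
    out[(organelle, "count")] = fit_pdf(
        counts, "gamma", (0.0, math.inf), organelle, "count")
    pos_family = "gamma" if organelle == "nucleoli" else "t_location_scale"
    pos_support = (0.0, 1.0) if organelle == "nucleoli" else (0.0, 2.0)
    pos = sub["D"].clip(upper=pos_support[1]).astype(float)
    out[(organelle, "position")] = fit_pdf(
        pos, pos_family, pos_support, organelle, "position")
    for feature in ("minor_axis_ratio", "axes_ratio"):
        vals = sub[feature].astype(float).clip(upper=1.0)
        out[(organelle, feature)] = fit_pdf(
            vals, "gamma", (0.0, 1.0), organelle, feature)
    return out
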