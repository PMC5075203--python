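"""Organelle placement from fitted feature distributions.

Nucleoli, golgi and vesicles are placed per cell as deformed circles whose
count, size ratio (organelle minor axis / nucleus minor axis), shape ratio
(minor/major) and radial position are drawn from the corresponding
:class:`~msiplex.distributions.FittedPDF`.  The dimensionless position feature

    D = 1 - (N - O) / (N + C)

measures where a point sits along the ray from the nucleus centre: N is the
distance from the nucleus centre to the nuclear membrane along that ray, O the
distance to the point, and C the distance from the nuclear membrane to the
plasma membrane.  D < 1 is intranuclear, D = 1 on the nuclear membrane and
D > 1 cytoplasmic (up to 2 at the plasma membrane).

Placement enforces hard per-cell area caps, counting the candidate itself:
nucleoli may take at most 20 % of the nuclear area, golgi 12 % and vesicles
18 % of the cell area.  Candidates that would break the cap are discarded,
silently reducing the realised count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, Point, Polygon

from .distributions import FittedPDF, PDFSet
from .scaffold import CellGeometry, deformed_circle

AREA_CAPS = {"nucleoli": 0.20, "golgi": 0.12, "vesicles": 0.18}

_N_VERTICES = 20
_ORGANELLE_IRREGULARITY = 0.10


class ContractError(ValueError):
    pass


class ResampleSignal(RuntimeError):
    """Raised when an inverted position lands outside the cell polygon."""


@dataclass(frozen=True)
class PositionMeasurement:
    N: float
    O: float
    C: float

    @property
    def D(self) -> float:
        return 1.0 - (self.N - self.O) / (self.N + self.C)


@dataclass
class OrganelleInstance:
    organelle: str
    cell_id: int
    centre: tuple[float, float]
    minor_axis: float  # full axis length, px
    major_axis: float
    polygon: np.ndarray
    D: float

    @property
    def area(self) -> float:
        return _shoelace(self.polygon)


def _shoelace(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _ray_crossings(nucleus: Polygon, cell: Polygon, origin: np.ndarray,
                   direction: np.ndarray, reach: float) -> tuple[float, float]:
    """Distances from origin to the nuclear (N) and plasma (N+C) membranes."""
    end = origin + reach * direction
    ray = LineString([tuple(origin), tuple(end)])

    def first_crossing(poly: Polygon) -> float:
        inter = ray.intersection(poly.exterior)
        if inter.is_empty:
            raise ResampleSignal("ray does not cross the membrane")
        pts = getattr(inter, "geoms", [inter])
        dists = []
        for g in pts:
            coords = g.coords if g.geom_type != "LineString" else g.coords
            for xy in coords:
                dists.append(math.hypot(xy[0] - origin[0], xy[1] - origin[1]))
        return min(d for d in dists if d > 1e-9)

    n = first_crossing(nucleus)
    total = first_crossing(cell)
    return n, max(total - n, 0.0)


def _reach(cell: CellGeometry) -> float:
    poly = np.asarray(cell.cell_polygon)
    span = poly.max(axis=0) - poly.min(axis=0)
    return float(np.hypot(*span)) * 2 + 10


def position_feature(cell: CellGeometry, point: Sequence[float],
                     _shapes: tuple[Polygon, Polygon] | None = None
                     ) -> PositionMeasurement:
    """Measure (N, O, C) for a point inside the cell and derive D.

    At the nucleus centre the direction is undefined; the ray defaults to +x
    and the defined limit D = 1 - N/(N+C) is returned with O = 0.
    """
    nucleus, cshape = _shapes or (cell.nucleus_shape(), cell.cell_shape())
    origin = np.asarray(cell.nucleus_centre, dtype=float)
    p = np.asarray(point, dtype=float)
    if not cshape.covers(Point(p)):
        raise ValueError("point lies outside the cell polygon")
    vec = p - origin
    o = float(np.hypot(*vec))
    direction = vec / o if o > 1e-9 else np.array([1.0, 0.0])
    n, c = _ray_crossings(nucleus, cshape, origin, direction, _reach(cell))
    return PositionMeasurement(N=n, O=o if o > 1e-9 else 0.0, C=c)


def invert_position(cell: CellGeometry, D: float, direction: Sequence[float],
                    _shapes: tuple[Polygon, Polygon] | None = None
                    ) -> np.ndarray:
    """Point along ``direction`` from the nucleus centre realising feature D.

    Inverse of :func:`position_feature`: O = N - (1 - D)(N + C).  Raises
    :class:`ResampleSignal` if the point falls outside the cell (possible for
    concave geometry), signalling the caller to redraw.
    """
    if not 0 < D <= 2:
        raise ContractError("D must lie in (0, 2]")
    nucleus, cshape = _shapes or (cell.nucleus_shape(), cell.cell_shape())
    origin = np.asarray(cell.nucleus_centre, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.hypot(*d)
    n, c = _ray_crossings(nucleus, cshape, origin, d, _reach(cell))
    o = n - (1.0 - D) * (n + c)
    if o < -1e-9:
        # D below the on-ray minimum 1 - N/(N+C) has no realisation along
        # this direction (the organelle would sit on the opposite ray)
        raise ResampleSignal("sampled D below the on-ray minimum")
    p = origin + max(o, 0.0) * d
    if not cshape.covers(Point(p)):
        raise ResampleSignal("inverted point outside cell polygon")
    return p


def sample_count(pdf: FittedPDF, rng: np.random.Generator) -> int:
    """Draw an organelle count: gamma draw rounded to nearest int, floored at 0."""
    if pdf.feature != "count":
        raise ContractError(f"expected a count PDF, got {pdf.feature!r}")
    x = float(pdf.rvs(1, rng)[0])
    return max(int(round(x)), 0)


def _clip_polygon(poly: np.ndarray, container: Polygon,
                  subtract: Polygon | None = None) -> np.ndarray | None:
    shape = Polygon(poly)
    if not shape.is_valid:
        shape = shape.buffer(0)
    clipped = shape.intersection(container)
    if subtract is not None:
        clipped = clipped.difference(subtract)
    if clipped.is_empty:
        return None
    if clipped.geom_type == "MultiPolygon":
        clipped = max(clipped.geoms, key=lambda g: g.area)
    if clipped.geom_type != "Polygon" or clipped.area < 1.0:
        return None
    return np.asarray(clipped.exterior.coords[:-1], dtype=float)


def populate_cell(cell: CellGeometry, organelle: str,
                  pdfs: Mapping[tuple[str, str], FittedPDF] | Mapping[str, FittedPDF],
                  rng: np.random.Generator,
                  max_oversample: int = 10) -> list[OrganelleInstance]:
    """Place organelles of one type in a cell under the area cap.

    ``pdfs`` may be a full parameter set keyed by (organelle, feature) or a
    per-organelle mapping keyed by feature alone.  A candidate is accepted only
    if the cumulative area of this organelle type, including the candidate,
    stays at or below the cap; candidates are drawn for at most
    ``max_oversample`` times the target count before giving up.
    """
    def get(feature: str) -> FittedPDF:
        if (organelle, feature) in pdfs:  # type: ignore[operator]
            return pdfs[(organelle, feature)]  # type: ignore[index]
        return pdfs[feature]  # type: ignore[index]

    if organelle not in AREA_CAPS:
        raise ContractError(f"unknown organelle {organelle!r}")
    nucleus = cell.nucleus_shape()
    cshape = cell.cell_shape()
    shapes = (nucleus, cshape)
    cap = AREA_CAPS[organelle]
    ref_area = nucleus.area if organelle == "nucleoli" else cshape.area
    budget = cap * ref_area

    target = sample_count(get("count"), rng)
    placed: list[OrganelleInstance] = []
    cum_area = 0.0
    attempts = 0
    cap_rejects_in_row = 0
    max_attempts = max_oversample * max(target, 1)
    nuc_boundary = nucleus.exterior
    cell_boundary = cshape.exterior

    # candidate parameters are drawn in batches: scipy's inverse-CDF sampling
    # is far cheaper vectorised than draw-by-draw
    queue: list[tuple[float, float, float, float, float]] = []

    def refill(n: int) -> None:
        ratios = get("minor_axis_ratio").rvs(n, rng)
        ars = get("axes_ratio").rvs(n, rng)
        Ds = get("position").rvs(n, rng)
        angs = rng.uniform(0, 2 * np.pi, n)
        rots = rng.uniform(0, 2 * np.pi, n)
        queue.extend(zip(ratios, ars, Ds, angs, rots))

    while len(placed) < target and attempts < max_attempts:
        attempts += 1
        if not queue:
            refill(max(target - len(placed) + 4, 8))
        ratio, ar, D, ang, rot = queue.pop()
        minor = max(float(ratio) * cell.nucleus_minor_axis, 1.0)
        if ar > 1:
            ar = 1.0 / ar  # fold reciprocal back into (0, 1]
        major = minor / float(ar)
        D = float(D)
        if organelle == "nucleoli" and D > 1:
            continue  # nucleoli are intranuclear; redraw
        direction = np.array([np.cos(ang), np.sin(ang)])
        try:
            centre = invert_position(cell, D, direction, _shapes=shapes)
        except ResampleSignal:
            continue
        poly = deformed_circle(centre, minor / 2, major / 2,
                               _ORGANELLE_IRREGULARITY, _N_VERTICES, rng,
                               rotation=float(rot))
        max_r = (major / 2) * (1 + _ORGANELLE_IRREGULARITY)
        cp = Point(centre)
        if organelle == "nucleoli":
            # fast path: fully inside the nucleus, no clipping needed
            if nucleus.covers(cp) and nuc_boundary.distance(cp) > max_r:
                area = _shoelace(poly)
            else:
                poly2 = _clip_polygon(poly, nucleus)
                if poly2 is None:
                    continue
                poly, area = poly2, _shoelace(poly2)
        else:
            inside_cell = cell_boundary.distance(cp) > max_r and cshape.covers(cp)
            clear_of_nucleus = (D > 1 and not nucleus.covers(cp)
                                and nuc_boundary.distance(cp) > max_r)
            if inside_cell and (D <= 1 or clear_of_nucleus):
                area = _shoelace(poly)
            else:
                poly2 = _clip_polygon(poly, cshape,
                                      subtract=nucleus if D > 1 else None)
                if poly2 is None:
                    continue
                poly, area = poly2, _shoelace(poly2)
        if cum_area + area > budget:
            # once the cap is effectively exhausted, stop burning attempts
            cap_rejects_in_row += 1
            if cap_rejects_in_row >= 40:
                break
            continue
        cap_rejects_in_row = 0
        cum_area += area
        placed.append(OrganelleInstance(
            organelle=organelle, cell_id=cell.cell_id,
            centre=(float(centre[0]), float(centre[1])),
            minor_axis=minor, major_axis=major, polygon=poly, D=D))
    return placed


def populate_sample(sample, pdfs: PDFSet, rng: np.random.Generator,
                    organelle_types: Sequence[str] = ("nucleoli", "golgi", "vesicles"),
                    ) -> dict[str, list[OrganelleInstance]]:
    """Place all requested organelle types in every cell of a tissue sample."""
    out: dict[str, list[OrganelleInstance]] = {o: [] for o in organelle_types}
    for cell in sample.cells:
        for org in organelle_types:
            out[org].extend(populate_cell(cell, org, pdfs, rng))
    return out
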