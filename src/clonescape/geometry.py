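"""Genet footprint geometry: convex hulls, constant-area buffers, overlap.

A genet sampled at three or more non-collinear ramets gets the convex hull
of its ramets as footprint; genets with one or two ramets — the majority in
a phalanx population — cannot support a hull, so their occupied area is
imputed from the mean hull area of 3-ramet genets (divided by 3 for
singletons, by 1.5 for pairs) and realised as a constant-area buffer
polygon: a disc around a lone ramet, a stadium (segment buffer) around a
pair.  Overlap between footprints measures how much genets intermingle; a
phalanx architecture shows almost none.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Optional, Sequence

import numpy as np
from shapely.geometry import LineString, MultiPoint, Point, Polygon
from shapely.ops import unary_union

from .clones import MLGPartition
from .io import Dataset, SampleUnit

__all__ = [
    "GenetFootprint",
    "OverlapReport",
    "genet_hulls",
    "impute_agen",
    "buffer_polygons",
    "genet_footprints",
    "overlap_report",
    "patch_areas",
]

#: circle discretisation for buffers (segments per quarter circle)
_QUAD_SEGS = 64


@dataclass
class GenetFootprint:
    """Footprint polygon of one genet.

    ``area`` is the closed-form A_GEN (hull area, or the buffer's exact
    target area); ``polygon.area`` may differ from it by the buffer
    discretisation error only.
    """

    mlg_id: int
    polygon: Polygon
    area: float
    method: str  # hull | buffer_single | buffer_pair | imputed_only

    def __post_init__(self):
        if self.area < 0:
            raise ValueError("negative area")
        if self.polygon is not None and not self.polygon.is_valid:
            raise ValueError(f"genet {self.mlg_id}: invalid polygon")


@dataclass
class OverlapReport:
    pairwise: list  # (mlg_a, mlg_b, intersection area)
    union_area: float
    multi_area: float  # area covered by >= 2 footprints
    percent: float
    max_multiplicity: int

    def to_dict(self) -> dict:
        return {
            "union_area": self.union_area,
            "multi_cover_area": self.multi_area,
            "percent_overlap": self.percent,
            "max_multiplicity": self.max_multiplicity,
            "n_overlapping_pairs": len(self.pairwise),
        }


def _points_by_mlg(units: Sequence[SampleUnit], partition: MLGPartition) -> Dict[int, np.ndarray]:
    by = {}
    for u in units:
        by.setdefault(partition.mlg_of(u.sample_id), []).append((u.x, u.y))
    return {g: np.array(p) for g, p in by.items()}


def genet_hulls(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
):
    """Convex hull footprints for genets with >= 3 sampled ramets.

    Returns ``(footprints, degenerate)``: collinear genets whose hull
    collapses to a segment get no hull and are listed in ``degenerate``
    for buffer treatment downstream.
    """
    pts = _points_by_mlg(units, partition)
    footprints, degenerate = [], []
    for mlg, xy in sorted(pts.items()):
        if len(xy) < 3:
            continue
        hull = MultiPoint([tuple(p) for p in xy]).convex_hull
        if isinstance(hull, Polygon) and hull.area > 0:
            footprints.append(GenetFootprint(mlg, hull, float(hull.area), "hull"))
        else:
            warnings.warn(f"genet {mlg}: collinear ramets, zero-area hull; buffer treatment")
            degenerate.append(mlg)
    return footprints, degenerate


def impute_agen(
    hull_footprints: Sequence[GenetFootprint],
    partition: MLGPartition,
    a3_override: Optional[float] = None,
) -> Dict[int, float]:
    """Complete A_GEN for every genet, imputing the unhullable majority.

    The mean hull area of genets with exactly three sampled ramets (A3)
    calibrates the imputation: singletons get A3/3, two-ramet genets
    A3/1.5; genets with a hull keep their hull area.  When no 3-ramet
    genet exists, ``a3_override`` must supply the calibration area.
    """
    sizes = partition.clone_sizes()
    hull_area = {f.mlg_id: f.area for f in hull_footprints}
    three = [a for g, a in hull_area.items() if sizes[g] == 3 and a > 0]
    if three:
        a3 = float(np.mean(three))
    elif a3_override is not None:
        a3 = float(a3_override)
    else:
        raise ValueError(
            "no 3-ramet genet with a positive hull area; pass a3_override to calibrate imputation"
        )
    agen = {}
    for g in range(partition.n_mlg):
        if g in hull_area:
            agen[g] = hull_area[g]
        elif sizes[g] == 1:
            agen[g] = a3 / 3.0
        elif sizes[g] == 2:
            agen[g] = a3 / 1.5
        else:  # collinear >= 3-ramet genet: calibrated like a 3-ramet genet
            agen[g] = a3
    return agen


def stadium_half_width(d: float, target_area: float) -> float:
    """Half-width w of a stadium of axis length d with area pi w^2 + 2 d w."""
    if target_area <= 0:
        raise ValueError("target area must be positive")
    return (-d + np.sqrt(d * d + np.pi * target_area)) / np.pi


def buffer_polygons(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
    target_area: Dict[int, float],
) -> list:
    """Constant-area buffer footprints for genets without a usable hull.

    Singletons become discs of radius ``sqrt(A/pi)``; two-ramet genets (and
    collinear multi-ramet genets, via their two extreme ramets) become
    stadiums whose half-width solves ``pi w**2 + 2 d w = A``.  The stored
    ``area`` is the exact target; the polygon approximates it to the
    discretisation tolerance.
    """
    pts = _points_by_mlg(units, partition)
    out = []
    for mlg, area in sorted(target_area.items()):
        if area <= 0:
            raise ValueError(f"genet {mlg}: nonpositive target area")
        xy = pts.get(mlg)
        if xy is None:
            continue
        if len(xy) == 1:
            r = float(np.sqrt(area / np.pi))
            poly = Point(*xy[0]).buffer(r, quad_segs=_QUAD_SEGS)
            out.append(GenetFootprint(mlg, poly, area, "buffer_single"))
        else:
            if len(xy) == 2:
                p, q = xy
            else:  # collinear genet: span between the two most distant ramets
                d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1)
                i, j = np.unravel_index(np.argmax(d2), d2.shape)
                p, q = xy[i], xy[j]
            d = float(np.hypot(*(q - p)))
            w = stadium_half_width(d, area)
            if d == 0:
                poly = Point(*p).buffer(w, quad_segs=_QUAD_SEGS)
            else:
                poly = LineString([tuple(p), tuple(q)]).buffer(w, quad_segs=_QUAD_SEGS)
            out.append(GenetFootprint(mlg, poly, area, "buffer_pair"))
    return out


def genet_footprints(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
    a3_override: Optional[float] = None,
) -> list:
    """Full footprint set: hulls where possible, calibrated buffers elsewhere."""
    hulls, degenerate = genet_hulls(units, partition)
    agen = impute_agen(hulls, partition, a3_override=a3_override)
    hulled = {f.mlg_id for f in hulls}
    targets = {g: a for g, a in agen.items() if g not in hulled}
    return sorted(hulls + buffer_polygons(units, partition, targets), key=lambda f: f.mlg_id)


def overlap_report(footprints: Sequence[GenetFootprint]) -> OverlapReport:
    """Pairwise overlap areas and the share of ground covered by >= 2 genets.

    ``percent = 100 * area(covered by >=2 footprints) / area(union of all
    footprints)``.  Multiplicity beyond 2 is detected exactly by testing
    triple intersections among mutually overlapping pairs.
    """
    polys = [(f.mlg_id, f.polygon) for f in footprints if f.polygon is not None and f.polygon.area > 0]
    if len(polys) < 2:
        raise ValueError("need at least 2 footprints")
    union = unary_union([p for _, p in polys])
    pairwise, inter_polys, graph = [], [], {}
    for (ga, pa), (gb, pb) in combinations(polys, 2):
        if not pa.intersects(pb):
            continue
        inter = pa.intersection(pb)
        if inter.area > 0:
            pairwise.append((ga, gb, float(inter.area)))
            inter_polys.append(inter)
            graph.setdefault(ga, set()).add(gb)
            graph.setdefault(gb, set()).add(ga)
    multi = unary_union(inter_polys).area if inter_polys else 0.0
    max_mult = 1 if polys else 0
    if pairwise:
        max_mult = 2
        poly_of = dict(polys)
        for ga, gb, _ in pairwise:
            for gc in graph.get(ga, set()) & graph.get(gb, set()):
                triple = poly_of[ga].intersection(poly_of[gb]).intersection(poly_of[gc])
                if triple.area > 1e-12:
                    max_mult = 3
    percent = 100.0 * multi / union.area if union.area > 0 else 0.0
    return OverlapReport(pairwise, float(union.area), float(multi), float(percent), max_mult)


def patch_areas(dataset: Dataset) -> Dict[str, float]:
    """Planar area (m^2) of each digitised patch outline."""
    out = {}
    for pid, verts in dataset.patch_outlines.items():
        poly = Polygon(verts)
        if not poly.is_valid:
            raise ValueError(f"patch {pid}: self-intersecting or invalid outline")
        out[pid] = float(poly.area)
    return out
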