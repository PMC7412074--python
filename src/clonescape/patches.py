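"""Patch-level genotypic structure: R_p, E_H, S_mix and their area regressions.

Each spatially well-defined patch of ramets is scored by three indices on
[0, 1]: within-patch genotypic richness ``R_p = (G_p - 1)/(n_p - 1)``,
Shannon-Wiener equitability ``E_H`` of within-patch clone sizes, and the
genotypic spatial mixing index ``S_mix = N_Pdif / N_Ptot`` — the fraction of
nearest-neighbour ramet relations inside the patch that connect different
genets.  All three rise with richness, evenness and spatial intermingling
of genets, so regressing them on patch area ``A_P`` tests whether larger
(older) patches have lost genotypic structure.  A local-richness surface
interpolated over the mapped area visualises the same signal continuously.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .clones import MLGPartition
from .diversity import equitability, genotypic_richness
from .io import SampleUnit
from .spatial import nearest_neighbour_indices

__all__ = [
    "RegressionResult",
    "RichnessSurface",
    "smix",
    "patch_stats",
    "patch_regressions",
    "local_richness",
    "richness_surface",
]


@dataclass
class RegressionResult:
    response: str
    slope: float
    intercept: float
    r: float
    p_value: float
    n: int

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            "p_value": self.p_value,
            "n": self.n,
        }


@dataclass
class RichnessSurface:
    """Gridded local genotypic richness with an off-species mask."""

    x: np.ndarray  # grid x coordinates (nx,)
    y: np.ndarray  # grid y coordinates (ny,)
    values: np.ndarray  # (ny, nx), NaN outside the mask
    points: np.ndarray  # (n, 2) ramet positions
    local_values: np.ndarray  # per-ramet local richness


def smix(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
    mode: str = "directed",
) -> float:
    """Genotypic spatial mixing index of one patch.

    Every ramet contributes its nearest within-patch neighbour (ties by
    smallest sample_id); ``S_mix`` is the fraction of those relations that
    connect different genets.  0 when the patch is monoclonal, 1 when every
    nearest neighbour belongs to another genet; the inverse, in meaning, of
    the aggregation index.  ``mode='unordered'`` collapses mutual pairs to
    one relation before counting.
    """
    if len(units) < 2:
        raise ValueError("S_mix undefined for a single-unit patch")
    nn = nearest_neighbour_indices(units)
    labels = np.array([partition.mlg_of(u.sample_id) for u in units])
    if mode == "directed":
        return float(np.mean(labels[nn] != labels))
    if mode == "unordered":
        pairs = {(min(i, j), max(i, j)) for i, j in enumerate(nn)}
        diff = sum(labels[i] != labels[j] for i, j in pairs)
        return float(diff / len(pairs))
    raise ValueError(f"unknown mode {mode!r}")


def patch_stats(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
    areas: Optional[Dict[str, float]] = None,
    smix_mode: str = "directed",
):
    """Per-patch n, G, R_p, E_H, S_mix and A_P as a DataFrame.

    Patches with a single sampled unit are excluded with a warning; a
    patch without a digitised outline gets ``A_P = NaN`` and drops out of
    the regressions.
    """
    import pandas as pd

    by_patch = {}
    for u in units:
        by_patch.setdefault(u.patch_id, []).append(u)
    rows = []
    for pid in sorted(by_patch):
        members = by_patch[pid]
        if len(members) < 2:
            warnings.warn(f"patch {pid}: single unit, indices undefined; skipped")
            continue
        labels = [partition.mlg_of(u.sample_id) for u in members]
        sizes = np.bincount(np.unique(labels, return_inverse=True)[1])
        a_p = np.nan if areas is None else areas.get(pid, np.nan)
        if areas is not None and pid not in areas:
            warnings.warn(f"patch {pid}: no outline; A_P missing")
        rows.append(
            {
                "patch_id": pid,
                "n_units": len(members),
                "n_genets": len(sizes),
                "R_p": genotypic_richness(len(members), len(sizes)),
                "E_H": equitability(sizes),
                "S_mix": smix(members, partition, mode=smix_mode),
                "A_P": a_p,
            }
        )
    return pd.DataFrame(
        rows, columns=["patch_id", "n_units", "n_genets", "R_p", "E_H", "S_mix", "A_P"]
    )


def patch_regressions(stats) -> list:
    """Univariate OLS of R_p, E_H and S_mix on patch area A_P.

    Returns one :class:`RegressionResult` per response, with Pearson r and
    the two-sided p-value from the t distribution on n - 2 df.
    """
    complete = stats.dropna(subset=["A_P"])
    if len(complete) < 3:
        raise ValueError("need at least 3 patches with known area")
    if np.isclose(complete["A_P"].var(), 0.0):
        raise ValueError("patch areas have zero variance")
    out = []
    for resp in ("R_p", "E_H", "S_mix"):
        fit = sps.linregress(complete["A_P"], complete[resp])
        out.append(
            RegressionResult(
                resp,
                float(fit.slope),
                float(fit.intercept),
                float(fit.rvalue),
                float(fit.pvalue),
                len(complete),
            )
        )
    return out


def local_richness(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
    radius: float = 1.0,
) -> np.ndarray:
    """Genotypic richness in a disc of ``radius`` m around each ramet.

    ``(G_local - 1)/(N_local - 1)`` over the units within the disc (the
    focal unit included); 0 for an isolated unit.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    xy = np.array([(u.x, u.y) for u in units])
    labels = np.array([partition.mlg_of(u.sample_id) for u in units])
    d = squareform(pdist(xy)) if len(units) > 1 else np.zeros((1, 1))
    vals = np.empty(len(units))
    for i in range(len(units)):
        within = d[i] <= radius
        n_loc = int(within.sum())
        g_loc = len(np.unique(labels[within]))
        vals[i] = 0.0 if n_loc < 2 else (g_loc - 1) / (n_loc - 1)
    return vals


def _idw(points: np.ndarray, values: np.ndarray, query: np.ndarray, power: float = 2.0) -> np.ndarray:
    """Shepard inverse-distance-weighted interpolation; exact at data points."""
    d = np.sqrt(((query[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    out = np.empty(len(query))
    exact = d < 1e-9
    hit = exact.any(axis=1)
    out[hit] = values[np.argmax(exact[hit], axis=1)]
    if (~hit).any():
        w = 1.0 / np.maximum(d[~hit], 1e-12) ** power
        out[~hit] = (w * values).sum(axis=1) / w.sum(axis=1)
    return out


def richness_surface(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
    radius: float = 1.0,
    grid_resolution: float = 0.5,
    mask_radius: Optional[float] = None,
    power: float = 2.0,
) -> RichnessSurface:
    """Interpolated local-richness surface over the sampled area.

    Per-ramet local richness (disc of ``radius`` m) is spread onto a
    regular grid by inverse-distance weighting — a smooth interpolant that
    reproduces the input values at the data points and never overshoots
    their range.  Grid cells farther than ``mask_radius`` (default:
    ``radius``) from any ramet are masked NaN (no species present).
    """
    if radius <= 0 or grid_resolution <= 0:
        raise ValueError("radius and grid_resolution must be positive")
    if mask_radius is None:
        mask_radius = radius
    xy = np.array([(u.x, u.y) for u in units])
    vals = local_richness(units, partition, radius)
    pad = mask_radius
    gx = np.arange(xy[:, 0].min() - pad, xy[:, 0].max() + pad + grid_resolution, grid_resolution)
    gy = np.arange(xy[:, 1].min() - pad, xy[:, 1].max() + pad + grid_resolution, grid_resolution)
    mx, my = np.meshgrid(gx, gy)
    query = np.column_stack([mx.ravel(), my.ravel()])
    surface = _idw(xy, vals, query, power=power)
    d_near = np.sqrt(((query[:, None, :] - xy[None, :, :]) ** 2).sum(-1)).min(axis=1)
    surface[d_near > mask_radius] = np.nan
    return RichnessSurface(gx, gy, surface.reshape(my.shape), xy, vals)
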