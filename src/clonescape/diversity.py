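"""Clone-censored population genetics and clonal diversity statistics.

All per-locus statistics are computed on one representative ramet per MLG
("removing the replicates"), since clonal copies would otherwise inflate
homozygosity/heterozygosity counts.  Population-level clonal diversity is
summarised by genotypic richness ``R = (G - 1)/(N - 1)``, the Shannon-Wiener
equitability of clone sizes, the slope of the cumulative Pareto clone-size
distribution, the maximum clone size, and the clonal subrange (largest
distance between two clonemates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .clones import MLGPartition
from .io import Dataset, SampleUnit, allele_frequencies

__all__ = [
    "DiversityStats",
    "locus_stats",
    "locus_stats_table",
    "genotypic_richness",
    "equitability",
    "pareto_slope",
    "clonal_subrange",
    "diversity_stats",
]


@dataclass
class DiversityStats:
    """Population-level clonal diversity summary."""

    n_units: int
    n_mlg: int
    richness: float
    pareto_beta: Optional[float]
    clonal_subrange: float
    equitability: float
    max_ng: int

    def to_dict(self) -> dict:
        return {
            "N": self.n_units,
            "G": self.n_mlg,
            "R": self.richness,
            "pareto_beta": self.pareto_beta,
            "clonal_subrange_m": self.clonal_subrange,
            "E_H": self.equitability,
            "max_ng": self.max_ng,
        }


def _censored_units(dataset: Dataset, partition: MLGPartition) -> list:
    units = {u.sample_id: u for u in dataset.units}
    return [units[s] for _, s in sorted(partition.representatives().items())]


def locus_stats(dataset: Dataset, partition: MLGPartition):
    """Per-locus Na, Ho, He, PIC and FIS on the clone-censored dataset.

    He is the uncorrected gene diversity ``1 - sum(p**2)``; PIC follows
    Botstein's ``1 - sum(p_i**2) - sum_{i<j} 2 p_i**2 p_j**2``; and
    ``FIS = (He - Ho)/He`` (reported as NaN, with a warning, at
    monomorphic loci).  Rows are loci; use :func:`locus_stats_table` for a
    table with the Mean row appended.
    """
    import pandas as pd

    if partition.n_mlg < 2:
        raise ValueError("need at least 2 MLGs")
    reps = _censored_units(dataset, partition)
    freqs = allele_frequencies(reps, dataset.locus_names, weighting="per_ramet")
    rows = []
    for li, name in enumerate(dataset.locus_names):
        p = np.array(list(freqs[li].values()))
        na = len(p)
        het = [u.genotype.is_heterozygous(li) for u in reps]
        het = [h for h in het if h is not None]
        ho = float(np.mean(het)) if het else np.nan
        he = float(1.0 - np.sum(p**2))
        pic = float(1.0 - np.sum(p**2) - (np.sum(p**2) ** 2 - np.sum(p**4)))
        if he > 0:
            fis = (he - ho) / he
        else:
            warnings.warn(f"locus {name} is monomorphic; FIS undefined")
            fis = np.nan
        rows.append({"locus": name, "Na": na, "Ho": ho, "He": he, "PIC": pic, "FIS": fis})
    return pd.DataFrame(rows).set_index("locus")


def locus_stats_table(stats) -> "object":
    """Append the across-loci Mean row (mean of per-locus values)."""
    mean = stats.mean(numeric_only=True)
    mean.name = "Mean"
    out = stats.copy()
    out.loc["Mean"] = mean
    return out


def genotypic_richness(n_units: int, n_mlg: int) -> float:
    """Dorken-Eckert genotypic richness ``R = (G - 1)/(N - 1)``."""
    if n_units < 2:
        raise ValueError("richness undefined for fewer than 2 units")
    if not 1 <= n_mlg <= n_units:
        raise ValueError("need 1 <= G <= N")
    return (n_mlg - 1) / (n_units - 1)


def equitability(clone_sizes: Sequence[int]) -> float:
    """Shannon-Wiener equitability ``E_H`` of clone sizes.

    ``E_H = (-sum p_i ln p_i)/ln S`` with ``p_i`` the share of ramets in
    genet ``i`` of ``S`` genets; 0 when a single genet holds all ramets,
    1 at complete evenness.
    """
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if sizes.size < 1:
        raise ValueError("need at least one genet")
    if np.any(sizes <= 0):
        raise ValueError("clone sizes must be positive")
    if sizes.size == 1:
        return 0.0
    p = sizes / sizes.sum()
    h = -np.sum(p * np.log(p))
    return float(h / np.log(sizes.size))


def pareto_slope(
    clone_sizes: Sequence[int],
    drop_largest: bool = False,
    weighted: bool = False,
) -> float:
    """Slope ``beta`` of the cumulative Pareto clone-size distribution.

    Ordinary least squares of ``log N(>=X)`` on ``log X`` over the
    distinct observed clone sizes ``X``; ``beta`` is the negated slope.
    Large ``beta`` means small clones dominate.  ``drop_largest`` excludes
    the largest size class; ``weighted`` weights each size class by its
    count of genets.
    """
    sizes = np.asarray(list(clone_sizes), dtype=float)
    if np.any(sizes <= 0):
        raise ValueError("clone sizes must be positive")
    xs, counts = np.unique(sizes, return_counts=True)
    if drop_largest and len(xs) > 2:
        xs, counts = xs[:-1], counts[:-1]
    if len(xs) < 2:
        raise ValueError("Pareto slope undefined: fewer than 2 distinct clone sizes")
    n_ge = counts[::-1].cumsum()[::-1]  # genets with size >= X
    lx, ly = np.log(xs), np.log(n_ge)
    w = counts.astype(float) if weighted else np.ones_like(lx)
    slope = np.polyfit(lx, ly, 1, w=np.sqrt(w))[0]
    return float(-slope)


def clonal_subrange(units: Sequence[SampleUnit], partition: MLGPartition) -> float:
    """Maximum distance (m) between two ramets of the same genet."""
    pos = {u.sample_id: (u.x, u.y) for u in units}
    best = 0.0
    found = False
    sizes = partition.clone_sizes()
    for mlg in np.nonzero(sizes >= 2)[0]:
        pts = np.array([pos[s] for s in partition.members(int(mlg)) if s in pos])
        if len(pts) < 2:
            continue
        found = True
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        best = max(best, float(d.max()))
    if not found:
        warnings.warn("no repeated MLG: clonal subrange is 0")
    return best


def diversity_stats(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
) -> DiversityStats:
    """Bundle the population-level clonal diversity statistics."""
    sizes = partition.clone_sizes()
    try:
        beta = pareto_slope(sizes)
    except ValueError:
        beta = None
    return DiversityStats(
        n_units=partition.n_units,
        n_mlg=partition.n_mlg,
        richness=genotypic_richness(partition.n_units, partition.n_mlg),
        pareto_beta=beta,
        clonal_subrange=clonal_subrange(units, partition),
        equitability=equitability(sizes),
        max_ng=partition.max_ng,
    )
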