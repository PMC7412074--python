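"""Spatial aggregation of clonemates and kinship-based spatial genetic structure.

Two complementary views of how clonal growth structures a population in
space:

* the aggregation index ``Ac`` — the excess probability that a unit's
  nearest neighbour is a clonemate relative to the all-pairs expectation,
  normalised to 0 (random placement) .. 1 (every nearest neighbour a
  clonemate), with permutation significance;
* distance-class profiles of the Loiselle kinship coefficient ``F_ij``,
  computed at the ramet level (all units) and at the genet level (one
  genotype per MLG placed at the centroid of its ramets), with permutation
  envelopes obtained by shuffling spatial positions among individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .clones import MLGPartition
from .io import AlleleFrequencies, Genotype, SampleUnit, allele_frequencies

__all__ = [
    "AggregationResult",
    "KinshipProfile",
    "aggregation_index",
    "loiselle_kinship",
    "sgs_profile",
    "nearest_neighbour_indices",
]


@dataclass
class AggregationResult:
    ac: float
    psp: float
    psg: float
    p_value: float
    n_permutations: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "Ac": self.ac,
            "Psp": self.psp,
            "Psg": self.psg,
            "p_value": self.p_value,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


@dataclass
class KinshipProfile:
    """Per-distance-class mean F_ij with permutation envelopes."""

    table: "object"  # DataFrame: class, max_distance, n_pairs, mean_fij, lower, upper, p_value, significant
    level: str
    n_permutations: int
    seed: Optional[int]


def nearest_neighbour_indices(units: Sequence[SampleUnit]) -> np.ndarray:
    """Index of each unit's nearest neighbour (Euclidean).

    Ties are broken by the smallest sample_id, so the relation is
    deterministic under any input ordering.
    """
    xy = np.array([(u.x, u.y) for u in units])
    n = len(units)
    if n < 2:
        raise ValueError("need at least 2 units")
    d = squareform(pdist(xy))
    np.fill_diagonal(d, np.inf)
    # scan candidates in lexicographic sample order so argmin's first hit
    # is the smallest sample_id among ties
    order = np.argsort(np.array([u.sample_id for u in units], dtype=object))
    nn_sorted = np.argmin(d[:, order], axis=1)
    return order[nn_sorted]


def aggregation_index(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
) -> AggregationResult:
    """Aggregation index of clonemates with permutation significance.

    ``Psp`` is the observed fraction of units whose nearest neighbour is a
    clonemate; ``Psg = sum n_g (n_g - 1) / (N (N - 1))`` is the probability
    two random distinct units are clonemates; ``Ac = (Psp - Psg)/(1 - Psg)``.
    The null permutes spatial positions among units (equivalently, genotype
    labels over the fixed nearest-neighbour graph); the p-value is the
    one-sided ``(#{Ac_perm >= Ac_obs} + 1)/(n_perm + 1)``.
    """
    n = len(units)
    if n < 3:
        raise ValueError("need at least 3 units")
    labels = np.array([partition.mlg_of(u.sample_id) for u in units])
    sizes = np.bincount(labels)
    psg = float((sizes * (sizes - 1)).sum() / (n * (n - 1)))
    if psg >= 1.0:
        raise ValueError("all units belong to one clone; Ac undefined")
    if psg == 0.0:
        warnings.warn("all MLGs are singletons; Ac is 0 by construction")
    nn = nearest_neighbour_indices(units)

    def _ac(lab: np.ndarray) -> float:
        psp = float(np.mean(lab[nn] == lab))
        return (psp - psg) / (1.0 - psg)

    obs_psp = float(np.mean(labels[nn] == labels))
    obs = (obs_psp - psg) / (1.0 - psg)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        if _ac(rng.permutation(labels)) >= obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AggregationResult(obs, obs_psp, psg, p, n_permutations, seed)


def _indicator_matrix(genotypes: Sequence[Genotype], freqs: AlleleFrequencies):
    """Within-individual allele frequencies x_ia stacked over (locus, allele).

    Returns (X, p) where columns run over every allele of every locus in
    ``freqs`` and ``p`` is the matching reference-frequency vector.
    """
    cols, p = [], []
    for li in range(len(freqs.locus_names)):
        for allele, freq in freqs[li].items():
            cols.append((li, allele))
            p.append(freq)
    p = np.array(p)
    X = np.zeros((len(genotypes), len(cols)))
    col_index = {c: j for j, c in enumerate(cols)}
    for i, g in enumerate(genotypes):
        for li, pair in enumerate(g.alleles):
            if pair is None:
                raise ValueError("kinship requires complete genotypes")
            for allele in pair:
                key = (li, allele)
                if key not in col_index:
                    raise ValueError(
                        f"allele {allele} at locus {freqs.locus_names[li]} absent from frequencies"
                    )
                X[i, col_index[key]] += 0.5
    return X, p


def loiselle_kinship(genotypes: Sequence[Genotype], freqs: AlleleFrequencies) -> np.ndarray:
    """Pairwise Loiselle kinship coefficient matrix.

    ``F_ij = sum_l sum_a (x_ia - p_a)(x_ja - p_a) / sum_l sum_a p_a (1 - p_a)
    + 1/(n - 1)`` with ``x_ia`` individual i's within-individual frequency
    of allele ``a`` (0, 0.5 or 1) and ``p_a`` the reference frequency.  The
    additive ``1/(n - 1)`` term corrects for the sampling bias of ``p``.
    """
    n = len(genotypes)
    if n < 3:
        raise ValueError("need at least 3 individuals")
    X, p = _indicator_matrix(genotypes, freqs)
    denom = float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all loci monomorphic; kinship undefined")
    dev = X - p
    return dev @ dev.T / denom + 1.0 / (n - 1)


def _equal_count_classes(dist_condensed: np.ndarray, n_classes: int):
    """Split sorted pairwise distances into classes with counts differing <= 1.

    Returns (class_of_pair, max_distance_per_class) over condensed indexing.
    """
    n_pairs = len(dist_condensed)
    if n_classes > n_pairs:
        raise ValueError(f"{n_classes} classes exceed {n_pairs} pairs")
    order = np.argsort(dist_condensed, kind="stable")
    cls = np.empty(n_pairs, dtype=int)
    chunks = np.array_split(order, n_classes)
    edges = np.empty(n_classes)
    for c, chunk in enumerate(chunks):
        cls[chunk] = c
        edges[c] = dist_condensed[chunk].max()
    return cls, edges


def sgs_profile(
    units: Sequence[SampleUnit],
    partition: MLGPartition,
    level: str = "ramet",
    n_classes: int = 10,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
    locus_names: Optional[Sequence[str]] = None,
    freqs: Optional[AlleleFrequencies] = None,
) -> KinshipProfile:
    """Distance-class Loiselle kinship profile with permutation envelopes.

    ``level='ramet'`` uses every unit at its sampled position with
    per-ramet allele frequencies; ``level='genet'`` collapses each MLG to
    one genotype placed at the arithmetic centroid of its ramets, with
    clone-censored frequencies — the contrast separates the imprint of
    clonal growth from genuine isolation by distance.  Distance classes
    hold equal pair counts (differing by at most one).  The null permutes
    spatial positions among individuals; envelopes are the 2.5% / 97.5%
    quantiles of permuted class means and ``p_value`` is the two-sided
    permutation probability.
    """
    import pandas as pd

    if locus_names is None:
        n_loci = units[0].genotype.n_loci
        locus_names = [f"L{i+1}" for i in range(n_loci)]

    if level == "ramet":
        pts = np.array([(u.x, u.y) for u in units])
        genotypes = [u.genotype for u in units]
        if freqs is None:
            freqs = allele_frequencies(units, locus_names, weighting="per_ramet")
    elif level == "genet":
        pos = {u.sample_id: (u.x, u.y) for u in units}
        geno = {u.sample_id: u.genotype for u in units}
        pts, genotypes = [], []
        for mlg_id, rep in sorted(partition.representatives().items()):
            member_pts = np.array([pos[s] for s in partition.members(mlg_id) if s in pos])
            pts.append(member_pts.mean(axis=0))
            genotypes.append(geno[rep])
        pts = np.array(pts)
        if freqs is None:
            censored = [u for u in units if u.sample_id in set(partition.representatives().values())]
            freqs = allele_frequencies(censored, locus_names, weighting="per_ramet")
    else:
        raise ValueError(f"unknown level {level!r}")

    n = len(genotypes)
    F = loiselle_kinship(genotypes, freqs)
    dist = pdist(pts)
    cls, edges = _equal_count_classes(dist, n_classes)
    iu, ju = np.triu_indices(n, k=1)
    class_pairs = [(iu[cls == c], ju[cls == c]) for c in range(n_classes)]
    obs = np.array([F[i, j].mean() for i, j in class_pairs])

    rng = np.random.default_rng(seed)
    perm_means = np.empty((n_permutations, n_classes))
    for t in range(n_permutations):
        pi = rng.permutation(n)
        for c, (i, j) in enumerate(class_pairs):
            perm_means[t, c] = F[pi[i], pi[j]].mean()
    lower = np.quantile(perm_means, 0.025, axis=0)
    upper = np.quantile(perm_means, 0.975, axis=0)
    # two-sided permutation p per class
    ge = (perm_means >= obs).sum(axis=0)
    le = (perm_means <= obs).sum(axis=0)
    p = np.minimum(1.0, 2.0 * (np.minimum(ge, le) + 1) / (n_permutations + 1))
    table = pd.DataFrame(
        {
            "class": np.arange(n_classes),
            "max_distance": edges,
            "n_pairs": [len(i) for i, _ in class_pairs],
            "mean_fij": obs,
            "lower": lower,
            "upper": upper,
            "p_value": p,
            "significant": (obs < lower) | (obs > upper),
        }
    )
    return KinshipProfile(table, level, n_permutations, seed)
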