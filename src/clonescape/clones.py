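"""Clone discrimination from multilocus genotypes.

Sampling units are resolved into multilocus genotypes (MLGs) by exact
genotype identity, or into multilocus lineages (MLLs) by single-linkage
merging of genotypes whose pairwise allelic mismatch count does not exceed
a threshold ``t`` (``t = 0`` reproduces exact MLGs).  The confidence that
repeated genotypes are clonal rather than products of independent sexual
events is quantified by the Pgen / Psex family of probabilities, under
Hardy-Weinberg equilibrium or with a stated departure ``F_IS``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import binom

from .io import AlleleFrequencies, Dataset, Genotype, SampleUnit

__all__ = [
    "MLGPartition",
    "mismatch_matrix",
    "mismatch_histogram",
    "assign_mlg",
    "pgen",
    "psex",
    "estimate_fis",
    "clone_confidence",
    "genotype_accumulation",
]


@dataclass
class MLGPartition:
    """Partition of sampling units into MLGs/MLLs.

    ``mlg_ids[i]`` is the integer lineage id of ``sample_ids[i]``; ids are
    dense (0..G-1) and assigned by first occurrence after lexicographic
    sort of sample_id, so the labelling is order-independent.
    """

    sample_ids: list
    mlg_ids: np.ndarray
    threshold: int = 0

    def __post_init__(self):
        self.mlg_ids = np.asarray(self.mlg_ids, dtype=int)
        if len(self.sample_ids) != len(self.mlg_ids):
            raise ValueError("sample_ids and mlg_ids length mismatch")
        self._index = {s: i for i, s in enumerate(self.sample_ids)}

    @property
    def n_units(self) -> int:
        return len(self.sample_ids)

    @property
    def n_mlg(self) -> int:
        return len(np.unique(self.mlg_ids))

    def clone_sizes(self) -> np.ndarray:
        """n_g per MLG, indexed by MLG id."""
        return np.bincount(self.mlg_ids, minlength=self.n_mlg)

    @property
    def max_ng(self) -> int:
        return int(self.clone_sizes().max())

    def mlg_of(self, sample_id: str) -> int:
        return int(self.mlg_ids[self._index[sample_id]])

    def members(self, mlg_id: int) -> list:
        return [s for s, g in zip(self.sample_ids, self.mlg_ids) if g == mlg_id]

    def representatives(self) -> dict:
        """Lexicographically first sample_id per MLG."""
        reps = {}
        for s in sorted(self.sample_ids):
            g = self.mlg_of(s)
            reps.setdefault(g, s)
        return reps

    def to_dataframe(self):
        import pandas as pd

        sizes = self.clone_sizes()
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "mlg_id": self.mlg_ids,
                "n_g": sizes[self.mlg_ids],
            }
        )

    @classmethod
    def from_dataframe(cls, df, threshold: int = 0) -> "MLGPartition":
        return cls(list(df["sample_id"]), df["mlg_id"].to_numpy(), threshold)


def _genotype_arrays(genotypes: Sequence[Genotype]):
    """Stack genotypes into two (N, L) arrays of sorted allele labels."""
    n, L = len(genotypes), genotypes[0].n_loci
    a1 = np.empty((n, L), dtype=np.int64)
    a2 = np.empty((n, L), dtype=np.int64)
    for i, g in enumerate(genotypes):
        for l, pair in enumerate(g.alleles):
            if pair is None:
                raise ValueError("mismatch matrix requires complete genotypes")
            a1[i, l], a2[i, l] = pair
    return a1, a2


def mismatch_matrix(units: Sequence[SampleUnit]) -> np.ndarray:
    """Symmetric matrix of pairwise allelic mismatch counts.

    Per locus the contribution is ``2 - |multiset intersection|`` of the two
    allele pairs, summed over loci; entries therefore lie in ``[0, 2L]``.
    """
    genotypes = [u.genotype for u in units]
    a1, a2 = _genotype_arrays(genotypes)
    n, L = a1.shape
    out = np.zeros((n, n), dtype=np.int64)
    for l in range(L):
        x1, x2 = a1[:, l], a2[:, l]
        eq_full = (x1[:, None] == x1[None, :]) & (x2[:, None] == x2[None, :])
        any_shared = (
            (x1[:, None] == x1[None, :])
            | (x1[:, None] == x2[None, :])
            | (x2[:, None] == x1[None, :])
            | (x2[:, None] == x2[None, :])
        )
        # sorted pairs: identical pair -> 2 shared, any common label -> 1
        shared = np.where(eq_full, 2, np.where(any_shared, 1, 0))
        out += 2 - shared
    return out


def mismatch_histogram(matrix: np.ndarray, n_loci: Optional[int] = None) -> np.ndarray:
    """Histogram of upper-triangle mismatch counts over classes 0..2L."""
    m = np.asarray(matrix)
    if m.shape[0] < 2:
        raise ValueError("need at least 2 units")
    iu = np.triu_indices_from(m, k=1)
    minlength = (2 * n_loci + 1) if n_loci is not None else int(m.max()) + 1
    return np.bincount(m[iu], minlength=minlength)


def assign_mlg(
    matrix: np.ndarray,
    sample_ids: Sequence[str],
    threshold: int = 0,
) -> MLGPartition:
    """Group units by single linkage over pairs with mismatch <= threshold.

    ``threshold = 0`` reproduces exact multilocus genotypes; positive
    thresholds merge genotypes separated by putative somatic mutations or
    scoring errors into multilocus lineages (chaining applies).
    """
    m = np.asarray(matrix)
    n = m.shape[0]
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    adj = csr_matrix(m <= threshold)
    _, labels = connected_components(adj, directed=False)
    # relabel by first occurrence in lexicographic sample order
    order = np.argsort(np.asarray(sample_ids, dtype=object))
    remap, next_id = {}, 0
    for i in order:
        if labels[i] not in remap:
            remap[labels[i]] = next_id
            next_id += 1
    mlg = np.array([remap[l] for l in labels], dtype=int)
    return MLGPartition(list(sample_ids), mlg, threshold)


def pgen(genotype: Genotype, freqs: AlleleFrequencies, fis: float = 0.0) -> float:
    """Probability of drawing ``genotype`` from the population frequencies.

    Under HWE (``fis = 0``) a homozygote contributes ``p**2`` and a
    heterozygote ``2 p q``; a departure from HWE scales these to
    ``p**2 + p (1 - p) fis`` and ``2 p q (1 - fis)``.  Missing loci are
    skipped.  The product over loci is returned.  A negative ``fis``
    (heterozygote excess) can push the homozygote form below zero for rare
    alleles; per-locus terms are clamped to [0, 1], the admissible range.
    """
    prob = 1.0
    for li, pair in enumerate(genotype.alleles):
        if pair is None:
            continue
        f = freqs[li]
        a, b = pair
        for allele in {a, b}:
            if allele not in f:
                raise ValueError(
                    f"allele {allele} at locus {freqs.locus_names[li]} absent from frequencies"
                )
        p, q = f[a], f[b]
        if a == b:
            term = p * p + p * (1.0 - p) * fis
        else:
            term = 2.0 * p * q * (1.0 - fis)
        prob *= min(1.0, max(0.0, term))
    return float(prob)


def psex(p_gen: float, n_samples: int, n_copies: int) -> float:
    """Probability of observing an MLG at least ``n_copies`` times among
    ``n_samples`` independent sexual events.

    ``Psex = P(X >= n)`` with ``X ~ Binomial(N, Pgen)``: the classical
    binomial-tail test that repeated genotypes are clonal, small values
    meaning chance recurrence is implausible.
    """
    if not 0.0 <= p_gen <= 1.0:
        raise ValueError("p_gen must be in [0, 1]")
    if not 1 <= n_copies <= n_samples:
        raise ValueError("need 1 <= n_copies <= n_samples")
    return float(binom.sf(n_copies - 1, n_samples, p_gen))


def estimate_fis(dataset: Dataset, partition: MLGPartition) -> float:
    """Multilocus inbreeding coefficient from the clone-censored dataset.

    ``F_IS = (mean He - mean Ho) / mean He`` over loci, computed on one
    representative unit per MLG.
    """
    from .diversity import locus_stats

    stats = locus_stats(dataset, partition)
    he, ho = stats["He"].mean(), stats["Ho"].mean()
    if he == 0:
        raise ValueError("all loci monomorphic; F_IS undefined")
    return float((he - ho) / he)


def clone_confidence(
    dataset: Dataset,
    partition: MLGPartition,
    freqs: Optional[AlleleFrequencies] = None,
    fis: Optional[float] = None,
):
    """Pgen / Psex table for every MLG observed at least twice.

    Frequencies default to the round-robin clone-censored estimates and
    ``fis`` to the clone-censored multilocus estimate, giving the
    conservative Pgen(FIS)/Psex(FIS) companions alongside the HWE forms.
    """
    import pandas as pd

    from .io import round_robin_frequencies

    if freqs is None:
        freqs = round_robin_frequencies(dataset)
    if fis is None:
        fis = estimate_fis(dataset, partition)
    units = {u.sample_id: u for u in dataset.units}
    sizes = partition.clone_sizes()
    n_total = partition.n_units
    rows = []
    for mlg_id, rep in sorted(partition.representatives().items()):
        ng = int(sizes[mlg_id])
        if ng < 2:
            continue
        g = units[rep].genotype
        p0 = pgen(g, freqs, 0.0)
        pf = pgen(g, freqs, fis)
        rows.append(
            {
                "mlg_id": mlg_id,
                "n_g": ng,
                "pgen": p0,
                "pgen_fis": pf,
                "psex": psex(p0, n_total, ng),
                "psex_fis": psex(pf, n_total, ng),
            }
        )
    return pd.DataFrame(rows, columns=["mlg_id", "n_g", "pgen", "pgen_fis", "psex", "psex_fis"])


def genotype_accumulation(
    dataset: Dataset,
    n_permutations: int = 100,
    seed: Optional[int] = None,
):
    """Genotype accumulation curve: distinct MLGs detected vs. loci assayed.

    For each subset size ``k < L``, ``n_permutations`` random draws of
    ``k`` loci are taken without replacement and the distinct multilocus
    genotypes among complete units are counted; ``k = L`` is the single
    full-data count.  A curve that plateaus before ``L`` indicates the
    marker set saturates clone detection.

    Returns a DataFrame with columns ``n_loci``, ``replicate``, ``n_mlg``.
    """
    import pandas as pd

    if dataset.n_loci < 2:
        raise ValueError("need at least 2 loci")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    units = dataset.complete_units()
    genos = [u.genotype for u in units]
    L = dataset.n_loci
    rows = []
    for k in range(1, L + 1):
        if k == L:
            draws = [tuple(range(L))]
        else:
            draws = [tuple(sorted(rng.choice(L, size=k, replace=False))) for _ in range(n_permutations)]
        for rep, loci in enumerate(draws):
            distinct = {g.subset(loci).alleles for g in genos}
            rows.append({"n_loci": k, "replicate": rep, "n_mlg": len(distinct)})
    return pd.DataFrame(rows)
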