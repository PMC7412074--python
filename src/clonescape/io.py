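"""Domain types and I/O for codominant multilocus genotype surveys.

A sampled ramet is a :class:`SampleUnit`: an id, planar coordinates in
metres, the patch it was collected from, and a diploid genotype at ``L``
microsatellite loci.  A :class:`Dataset` bundles the units with the locus
names and, optionally, digitised patch outline polygons.

Two table layouts are supported: a plain CSV with two allele columns per
locus, and the GenAlEx codominant export layout (two header rows, then one
row per sample).  Allele labels are opaque positive integers (fragment
sizes as scored upstream); ``0`` or an empty field encodes a missing call.
"""

from __future__ import annotations

import csv
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Genotype",
    "SampleUnit",
    "Dataset",
    "AlleleFrequencies",
    "read_dataset",
    "write_dataset",
    "read_patch_outlines",
    "write_patch_outlines",
    "allele_frequencies",
    "round_robin_frequencies",
]

#: reserved allele label for a missing call
MISSING = 0


@dataclass(frozen=True)
class Genotype:
    """Diploid multilocus genotype: one unordered allele pair per locus.

    ``alleles[i]`` is a sorted ``(a, b)`` tuple of positive integer labels,
    or ``None`` when locus ``i`` was not scored.
    """

    alleles: tuple

    def __post_init__(self):
        norm = []
        for loc, pair in enumerate(self.alleles):
            if pair is None:
                norm.append(None)
                continue
            if len(pair) != 2:
                raise ValueError(f"locus {loc}: expected 2 allele calls, got {len(pair)}")
            a, b = int(pair[0]), int(pair[1])
            if a <= 0 or b <= 0:
                raise ValueError(f"locus {loc}: allele labels must be positive integers")
            norm.append((a, b) if a <= b else (b, a))
        object.__setattr__(self, "alleles", tuple(norm))

    @property
    def n_loci(self) -> int:
        return len(self.alleles)

    @property
    def is_complete(self) -> bool:
        return all(p is not None for p in self.alleles)

    def subset(self, loci: Sequence[int]) -> "Genotype":
        """Genotype restricted to the given locus indices."""
        return Genotype(tuple(self.alleles[i] for i in loci))

    def is_heterozygous(self, locus: int):
        pair = self.alleles[locus]
        return None if pair is None else pair[0] != pair[1]


@dataclass(frozen=True)
class SampleUnit:
    """One sampled ramet: id, planar position (m), patch, genotype."""

    sample_id: str
    x: float
    y: float
    patch_id: str
    genotype: Genotype

    def __post_init__(self):
        import math

        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"sample {self.sample_id!r}: non-finite coordinates")
        if not self.patch_id:
            raise ValueError(f"sample {self.sample_id!r}: empty patch_id")


@dataclass
class Dataset:
    """A genotyped, geocoded sample of a (partially) clonal population."""

    locus_names: list
    units: list
    patch_outlines: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("locus names must be unique")
        seen = set()
        for u in self.units:
            if u.sample_id in seen:
                raise ValueError(f"duplicate sample_id {u.sample_id!r}")
            seen.add(u.sample_id)
            if u.genotype.n_loci != self.n_loci:
                raise ValueError(
                    f"sample {u.sample_id!r}: {u.genotype.n_loci} loci, expected {self.n_loci}"
                )

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    @property
    def n_units(self) -> int:
        return len(self.units)

    def complete_units(self) -> list:
        """Units with a call at every locus (admitted to clone discrimination)."""
        return [u for u in self.units if u.genotype.is_complete]

    def incomplete_ids(self) -> list:
        return [u.sample_id for u in self.units if not u.genotype.is_complete]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for u in self.units:
            row = {"sample_id": u.sample_id, "x": u.x, "y": u.y, "patch_id": u.patch_id}
            for name, pair in zip(self.locus_names, u.genotype.alleles):
                a, b = (MISSING, MISSING) if pair is None else pair
                row[f"{name}_1"], row[f"{name}_2"] = a, b
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AlleleFrequencies:
    """Per-locus relative allele frequencies."""

    locus_names: list
    freqs: list  # one {allele: frequency} mapping per locus

    def __post_init__(self):
        for name, f in zip(self.locus_names, self.freqs):
            tot = sum(f.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"locus {name}: frequencies sum to {tot}, not 1")

    def __getitem__(self, locus: int) -> Mapping[int, float]:
        return self.freqs[locus]

    def n_alleles(self, locus: int) -> int:
        return len(self.freqs[locus])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _parse_allele(tok: str, where: str) -> int:
    tok = tok.strip()
    if tok == "" or tok == str(MISSING):
        return MISSING
    try:
        val = int(tok)
    except ValueError:
        raise ValueError(f"{where}: unparseable allele call {tok!r}") from None
    if val < 0:
        raise ValueError(f"{where}: negative allele label {tok!r}")
    return val


def _pair_to_locus(a: int, b: int, where: str):
    if a == MISSING and b == MISSING:
        return None
    if a == MISSING or b == MISSING:
        raise ValueError(f"{where}: half-missing genotype ({a}/{b})")
    return (a, b)


def read_dataset(path, format: str = "csv") -> Dataset:
    """Read a sample table from ``path``.

    ``format='csv'``: header ``sample_id,x,y,patch_id`` followed by two
    columns per locus named ``<locus>_1``, ``<locus>_2``.
    ``format='genalex'``: GenAlEx codominant layout with coordinates in two
    trailing ``X``/``Y`` columns (the layout :func:`write_dataset` emits).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "genalex":
        return _read_genalex(path)
    raise ValueError(f"unknown format {format!r}")


def _read_csv(path: Path) -> Dataset:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = [h.strip() for h in rows[0]]
    fixed = ["sample_id", "x", "y", "patch_id"]
    if header[: len(fixed)] != fixed:
        raise ValueError(f"{path}: header must start with {fixed}, got {header[:4]}")
    allele_cols = header[len(fixed):]
    if len(allele_cols) % 2 != 0:
        raise ValueError(f"{path}: odd number of allele columns")
    locus_names = []
    for i in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[i], allele_cols[i + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise ValueError(f"{path}: allele columns {c1!r},{c2!r} do not pair up")
        locus_names.append(c1[:-2])
    units = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or all(not c.strip() for c in row):
            continue
        where = f"{path}:{lineno}"
        if len(row) != len(header):
            raise ValueError(f"{where}: expected {len(header)} fields, got {len(row)}")
        sid = row[0].strip()
        try:
            x, y = float(row[1]), float(row[2])
        except ValueError:
            raise ValueError(f"{where}: unparseable coordinates {row[1]!r},{row[2]!r}") from None
        pairs = []
        for li, name in enumerate(locus_names):
            a = _parse_allele(row[4 + 2 * li], where)
            b = _parse_allele(row[5 + 2 * li], where)
            pairs.append(_pair_to_locus(a, b, f"{where} locus {name}"))
        units.append(SampleUnit(sid, x, y, row[3].strip(), Genotype(tuple(pairs))))
    return Dataset(locus_names=locus_names, units=units)


def _read_genalex(path: Path) -> Dataset:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 3:
        raise ValueError(f"{path}: truncated GenAlEx file")
    try:
        n_loci = int(rows[0][0])
        n_samples = int(rows[0][1])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: malformed GenAlEx count row") from None
    header = [h.strip() for h in rows[2]]
    locus_names = [header[2 + 2 * i] for i in range(n_loci)]
    # trailing blank separator column, then X, Y
    units = []
    for lineno, row in enumerate(rows[3: 3 + n_samples], start=4):
        where = f"{path}:{lineno}"
        sid, pop = row[0].strip(), row[1].strip()
        pairs = []
        for li, name in enumerate(locus_names):
            a = _parse_allele(row[2 + 2 * li], where)
            b = _parse_allele(row[3 + 2 * li], where)
            pairs.append(_pair_to_locus(a, b, f"{where} locus {name}"))
        try:
            x = float(row[2 + 2 * n_loci + 1])
            y = float(row[2 + 2 * n_loci + 2])
        except (ValueError, IndexError):
            raise ValueError(f"{where}: missing or unparseable X/Y columns") from None
        units.append(SampleUnit(sid, x, y, pop, Genotype(tuple(pairs))))
    return Dataset(locus_names=locus_names, units=units)


def write_dataset(dataset: Dataset, path, format: str = "csv", title: str = "clonescape export") -> None:
    """Write ``dataset`` to ``path`` in the given table layout (round-trips)."""
    path = Path(path)
    if format == "csv":
        dataset.to_dataframe().to_csv(path, index=False)
        return
    if format != "genalex":
        raise ValueError(f"unknown format {format!r}")
    n_loci, n = dataset.n_loci, dataset.n_units
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([n_loci, n, 1, n])
        w.writerow([title, "", "", "pop1"])
        head = ["Sample", "Pop"]
        for name in dataset.locus_names:
            head += [name, ""]
        head += ["", "X", "Y"]
        w.writerow(head)
        for u in dataset.units:
            row = [u.sample_id, u.patch_id]
            for pair in u.genotype.alleles:
                a, b = (MISSING, MISSING) if pair is None else pair
                row += [a, b]
            row += ["", repr(u.x), repr(u.y)]
            w.writerow(row)


def read_patch_outlines(path) -> dict:
    """Read patch outline polygons from a CSV of (patch_id, vertex_index, x, y)."""
    import pandas as pd

    df = pd.read_csv(path)
    need = {"patch_id", "vertex_index", "x", "y"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(need)}")
    outlines = {}
    for pid, grp in df.groupby("patch_id", sort=False):
        grp = grp.sort_values("vertex_index")
        outlines[str(pid)] = [(float(r.x), float(r.y)) for r in grp.itertuples()]
    return outlines


def write_patch_outlines(outlines: Mapping[str, Sequence], path) -> None:
    import pandas as pd

    rows = [
        {"patch_id": pid, "vertex_index": i, "x": x, "y": y}
        for pid, verts in outlines.items()
        for i, (x, y) in enumerate(verts)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------


def allele_frequencies(
    units: Iterable[SampleUnit],
    locus_names: Sequence[str],
    weighting: str = "per_ramet",
) -> AlleleFrequencies:
    """Relative allele frequencies over ``units``.

    ``per_ramet`` counts every unit's two calls at each non-missing locus.
    ``per_genotype`` first collapses units to distinct multilocus genotypes
    and counts each genotype once (clone-censored frequencies).
    """
    units = list(units)
    if weighting == "per_genotype":
        seen, keep = set(), []
        for u in sorted(units, key=lambda u: u.sample_id):
            key = u.genotype.alleles
            if key not in seen:
                seen.add(key)
                keep.append(u)
        units = keep
    elif weighting != "per_ramet":
        raise ValueError(f"unknown weighting {weighting!r}")

    freqs = []
    for li, name in enumerate(locus_names):
        counts = Counter()
        for u in units:
            pair = u.genotype.alleles[li]
            if pair is not None:
                counts[pair[0]] += 1
                counts[pair[1]] += 1
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"locus {name}: no non-missing calls")
        freqs.append({a: c / total for a, c in sorted(counts.items())})
    return AlleleFrequencies(list(locus_names), freqs)


def round_robin_frequencies(dataset: Dataset) -> AlleleFrequencies:
    """Clone-censored allele frequencies by the round-robin method.

    For each locus, multilocus genotypes are identified from all *other*
    loci, and the frequencies at the focal locus are computed with one
    observation per such genotype (the lexicographically first unit
    represents each genotype).  This removes the upward bias that clonal
    replicates impose on frequency estimates without presupposing the
    clone assignment at the focal locus itself.  Only units with complete
    genotypes contribute.
    """
    if dataset.n_loci < 2:
        raise ValueError("round-robin frequencies require at least 2 loci")
    units = sorted(dataset.complete_units(), key=lambda u: u.sample_id)
    if not units:
        raise ValueError("no complete genotypes in dataset")
    freqs = []
    for li, name in enumerate(dataset.locus_names):
        others = [j for j in range(dataset.n_loci) if j != li]
        reps = {}
        for u in units:
            key = u.genotype.subset(others).alleles
            reps.setdefault(key, u)
        counts = Counter()
        for u in reps.values():
            a, b = u.genotype.alleles[li]
            counts[a] += 1
            counts[b] += 1
        total = sum(counts.values())
        freqs.append({a: c / total for a, c in sorted(counts.items())})
    return AlleleFrequencies(list(dataset.locus_names), freqs)
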