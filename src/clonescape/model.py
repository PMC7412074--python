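"""Model/Results interface orchestrating the full clonal-structure analysis.

:class:`ClonalStructureModel` is built from a :class:`~clonescape.io.Dataset`
(or a CSV path / DataFrame) and holds the analysis configuration — the MLL
mismatch threshold, permutation counts, distance-class count.  Its
:meth:`~ClonalStructureModel.fit` runs the stages in order (clone
discrimination, clone-censored diversity, spatial structure, genet
geometry, patch indices) and returns a :class:`ClonalStructureResults`
carrying every stage's output, with :meth:`~ClonalStructureResults.summary`
printing the headline table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import clones, diversity, geometry, patches, spatial
from .io import Dataset, read_dataset

__all__ = ["ClonalStructureModel", "ClonalStructureResults"]


@dataclass
class ClonalStructureResults:
    """Fitted clonal-structure analysis of one population sample."""

    dataset: Dataset
    excluded_ids: list
    partition: clones.MLGPartition
    mismatch: np.ndarray
    mismatch_hist: np.ndarray
    confidence: "object"
    locus_stats: "object"
    diversity: diversity.DiversityStats
    aggregation: Optional[spatial.AggregationResult]
    sgs_ramet: Optional[spatial.KinshipProfile]
    sgs_genet: Optional[spatial.KinshipProfile]
    footprints: Optional[list]
    overlap: Optional[geometry.OverlapReport]
    patch_stats: Optional["object"]
    regressions: Optional[list]
    seed: Optional[int]

    def summary(self) -> str:
        d = self.diversity
        lines = [
            "Clonal structure analysis",
            "=" * 52,
            f"sampling units (admitted/total) {d.n_units}/{self.dataset.n_units}",
            f"multilocus genotypes (G)        {d.n_mlg}",
            f"genotypic richness R            {d.richness:.2f}",
            f"max clone size (n_g)            {d.max_ng}",
            f"Pareto slope beta               "
            + (f"{d.pareto_beta:.2f}" if d.pareto_beta is not None else "undefined"),
            f"clonal subrange (m)             {d.clonal_subrange:.2f}",
            f"equitability E_H                {d.equitability:.2f}",
        ]
        if self.aggregation is not None:
            a = self.aggregation
            lines.append(
                f"aggregation index Ac            {a.ac:.2f} (p = {max(a.p_value, 0.001):.3f})"
            )
        if self.overlap is not None:
            lines.append(f"genet overlap (% of union)      {self.overlap.percent:.2f}")
        if self.regressions:
            lines.append("patch regressions vs. A_P:")
            for r in self.regressions:
                lines.append(
                    f"  {r.response:<6} r = {r.r:+.3f}  p = {max(r.p_value, 0.001):.3f}  (n = {r.n})"
                )
        lines.append("-" * 52)
        lines.append("per-locus statistics (clone-censored):")
        lines.append(diversity_table_str(self.locus_stats))
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the per-stage artifacts as CSV/JSON into ``outdir``."""
        import json
        from pathlib import Path

        import pandas as pd

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.partition.to_dataframe().to_csv(outdir / "mlg_partition.csv", index=False)
        pd.DataFrame(
            {"mismatches": np.arange(len(self.mismatch_hist)), "n_pairs": self.mismatch_hist}
        ).to_csv(outdir / "mismatch_histogram.csv", index=False)
        self.confidence.to_csv(outdir / "clone_confidence.csv", index=False)
        from .diversity import locus_stats_table

        locus_stats_table(self.locus_stats).to_csv(outdir / "locus_stats.csv")
        summary = {"diversity": self.diversity.to_dict(), "seed": self.seed}
        if self.aggregation is not None:
            summary["aggregation"] = self.aggregation.to_dict()
        if self.overlap is not None:
            summary["overlap"] = self.overlap.to_dict()
        if self.regressions:
            summary["regressions"] = [r.to_dict() for r in self.regressions]
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        for prof, name in ((self.sgs_ramet, "ramet"), (self.sgs_genet, "genet")):
            if prof is not None:
                prof.table.to_csv(outdir / f"sgs_{name}.csv", index=False)
        if self.footprints is not None:
            rows = [
                {"mlg_id": f.mlg_id, "method": f.method, "area": f.area, "wkt": f.polygon.wkt}
                for f in self.footprints
            ]
            pd.DataFrame(rows).to_csv(outdir / "genet_footprints.csv", index=False)
        if self.patch_stats is not None:
            self.patch_stats.to_csv(outdir / "patch_stats.csv", index=False)
        with open(outdir / "summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")


def diversity_table_str(stats) -> str:
    from .diversity import locus_stats_table

    t = locus_stats_table(stats)
    return t.to_string(float_format=lambda v: f"{v:.3f}")


class ClonalStructureModel:
    """Spatial clonal-structure analysis of a genotyped, geocoded sample.

    Parameters
    ----------
    dataset
        The sample to analyse.  Units with missing genotypes are excluded
        from clone discrimination (and flagged on the results) unless
        every locus is scored.
    threshold
        MLL mismatch threshold ``t``: genotypes separated by at most ``t``
        allelic mismatches merge into one lineage (single linkage); 0
        keeps exact multilocus genotypes.
    """

    def __init__(self, dataset: Dataset, threshold: int = 0):
        self.dataset = dataset
        self.threshold = int(threshold)

    @classmethod
    def from_csv(cls, path, format: str = "csv", outlines: Optional[str] = None, **kw):
        from .io import read_patch_outlines

        ds = read_dataset(path, format=format)
        if outlines:
            ds.patch_outlines = read_patch_outlines(outlines)
        return cls(ds, **kw)

    @classmethod
    def from_dataframe(cls, df, locus_names=None, **kw):
        """Build from a DataFrame in the canonical CSV column layout."""
        from .io import Genotype, SampleUnit

        if locus_names is None:
            allele_cols = [c for c in df.columns if c.endswith("_1")]
            locus_names = [c[:-2] for c in allele_cols]
        units = []
        for row in df.itertuples(index=False):
            pairs = []
            for name in locus_names:
                a, b = int(getattr(row, f"{name}_1")), int(getattr(row, f"{name}_2"))
                pairs.append(None if a == 0 and b == 0 else (a, b))
            units.append(
                SampleUnit(str(row.sample_id), float(row.x), float(row.y), str(row.patch_id), Genotype(tuple(pairs)))
            )
        return cls(Dataset(list(locus_names), units), **kw)

    def fit(
        self,
        n_permutations: int = 1000,
        n_classes: int = 10,
        seed: Optional[int] = None,
        compute_sgs: bool = True,
        compute_geometry: bool = True,
        compute_patches: bool = True,
        a3_override: Optional[float] = None,
    ) -> ClonalStructureResults:
        ds = self.dataset
        admitted = ds.complete_units()
        excluded = ds.incomplete_ids()
        if excluded:
            warnings.warn(f"{len(excluded)} units with missing genotypes excluded")
        if len(admitted) < 3:
            raise ValueError("need at least 3 complete units")
        admitted_ds = Dataset(ds.locus_names, admitted, ds.patch_outlines)

        mm = clones.mismatch_matrix(admitted)
        part = clones.assign_mlg(mm, [u.sample_id for u in admitted], self.threshold)
        hist = clones.mismatch_histogram(mm, ds.n_loci)
        conf = clones.clone_confidence(admitted_ds, part)
        lstats = diversity.locus_stats(admitted_ds, part)
        dstats = diversity.diversity_stats(admitted, part)

        agg = sgs_r = sgs_g = None
        if compute_sgs:
            try:
                agg = spatial.aggregation_index(admitted, part, n_permutations, seed)
            except ValueError as err:
                warnings.warn(f"aggregation index skipped: {err}")
            n_pairs = len(admitted) * (len(admitted) - 1) // 2
            k = min(n_classes, n_pairs)
            sgs_r = spatial.sgs_profile(
                admitted, part, "ramet", k, n_permutations, seed, ds.locus_names
            )
            if part.n_mlg >= 3:
                sgs_g = spatial.sgs_profile(
                    admitted, part, "genet", min(k, part.n_mlg * (part.n_mlg - 1) // 2),
                    n_permutations, seed, ds.locus_names,
                )

        foot = ovl = None
        if compute_geometry:
            try:
                foot = geometry.genet_footprints(admitted, part, a3_override=a3_override)
                if len(foot) >= 2:
                    ovl = geometry.overlap_report(foot)
            except ValueError as err:
                warnings.warn(f"genet geometry skipped: {err}")

        pstats = regs = None
        if compute_patches:
            areas = geometry.patch_areas(admitted_ds) if ds.patch_outlines else None
            pstats = patches.patch_stats(admitted, part, areas)
            try:
                regs = patches.patch_regressions(pstats)
            except ValueError as err:
                warnings.warn(f"patch regressions skipped: {err}")

        return ClonalStructureResults(
            dataset=ds,
            excluded_ids=excluded,
            partition=part,
            mismatch=mm,
            mismatch_hist=hist,
            confidence=conf,
            locus_stats=lstats,
            diversity=dstats,
            aggregation=agg,
            sgs_ramet=sgs_r,
            sgs_genet=sgs_g,
            footprints=foot,
            overlap=ovl,
            patch_stats=pstats,
            regressions=regs,
            seed=seed,
        )
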