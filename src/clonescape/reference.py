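"""Published reference values for the mapped *Salvia brachyodon* population.

The intensively grid-sampled mountain-top *S. brachyodon* population whose
survey these methods reproduce reported the per-locus microsatellite table
and headline clonal statistics below.  They serve as arithmetic
cross-checks: the per-locus means and the FIS identity
``FIS = (He - Ho)/He`` must be recoverable from the printed columns, and
the richness ``R`` from the printed N and G.  The raw genotypes and
coordinates behind the remaining headline values are not distributed with
this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["REPORTED_LOCUS_TABLE", "REPORTED"]

REPORTED_LOCUS_TABLE = pd.DataFrame(
    [
        ("SoUZ001", 8, 0.643, 0.661, 0.613, 0.026),
        ("SoUZ002", 5, 0.643, 0.611, 0.562, -0.052),
        ("SoUZ004", 4, 0.369, 0.367, 0.342, -0.005),
        ("SoUZ005", 7, 0.734, 0.739, 0.694, 0.006),
        ("SoUZ006", 16, 0.867, 0.836, 0.818, -0.037),
        ("SoUZ007", 11, 0.909, 0.877, 0.864, -0.036),
        ("SoUZ011", 14, 0.830, 0.759, 0.724, -0.093),
        ("SoUZ014", 8, 0.751, 0.757, 0.715, 0.007),
    ],
    columns=["locus", "Na", "Ho", "He", "PIC", "FIS"],
).set_index("locus")

#: reported Mean row of the per-locus table
REPORTED_LOCUS_MEANS = {"Na": 9.125, "Ho": 0.718, "He": 0.701, "PIC": 0.666, "FIS": -0.023}

#: reported population-level values
REPORTED = {
    "n_units": 687,
    "n_mlg": 241,
    "richness": 0.35,
    "pareto_beta": 0.69,
    "aggregation_ac": 0.73,
    "clonal_subrange_m": 10.90,
    "equitability": 0.91,
    "max_ng": 55,
    "n_unique_mlg": 91,
    "largest_genet_area_m2": 68.0,
    "overlap_percent": 3.45,
    "regression_r": {"R_p": -0.518, "E_H": -0.437, "S_mix": -0.425},
}
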