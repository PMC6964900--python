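"""Bundled example data.

The five-city table holds published daily-maximum validation statistics for
this downscaling model over June-August 2009-2011 (n = 276 days per city):
mean difference and RMSD, in degrees Celsius, of the 12 km coarse product
and the 1 km downscaled product against first-order NWS station
observations.  Three of the cities are coastal (San Francisco, Washington,
Baltimore) — where imposing LST structure helps most — and two are inland
(Atlanta, St. Louis).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["five_city_validation_table", "FIVE_CITY_N"]

#: matched days per city in the five-city evaluation (June-August x 3 years)
FIVE_CITY_N = 276

_ROWS = [
    # city, mean_diff coarse, mean_diff downscaled, rmsd coarse, rmsd downscaled
    ("Atlanta, GA", 0.56, 1.09, 1.87, 2.05),
    ("San Francisco, CA", -3.69, -1.79, 4.44, 3.05),
    ("Washington, DC", -0.53, -0.25, 1.52, 1.45),
    ("Baltimore, MD", -1.11, -0.17, 1.96, 1.63),
    ("St. Louis, MO", 0.02, 1.45, 1.96, 2.38),
]


def five_city_validation_table() -> pd.DataFrame:
    """Per-city validation metrics (deg C) for the coarse and downscaled
    daily-maximum products; see the module docstring."""
    return pd.DataFrame(
        _ROWS,
        columns=[
            "city",
            "mean_diff_coarse",
            "mean_diff_downscaled",
            "rmsd_coarse",
            "rmsd_downscaled",
        ],
    )
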