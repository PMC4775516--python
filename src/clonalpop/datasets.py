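"""Bundled reference data.

`nansei_survey_counts` carries the published per-site clonal counts from
the Nansei Islands *Galaxea fascicularis* survey this package's workflow
targets: colonies analyzed (N), distinct multilocus genotypes (G) and
multilocus lineages (MLL) per site and mitochondrial type, together with
the published clonal diversity R (two decimals; NaN where the table shows
a dash).  These printed counts serve as worked-example inputs for the
clonal-diversity arithmetic; the underlying genotypes were never
deposited, so synthetic data (see :mod:`clonalpop.simulate`) stands in for
the raw sample.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["nansei_survey_counts", "nansei_survey_totals"]

# region, site, code, type, N, G, MLL, published R
_ROWS = [
    ("Amami", "Ayamaru", "A-Aya", "mtL", 10, 9, 9, 0.89),
    ("Amami", "Ayamaru", "A-Aya", "mtS", 5, 5, 5, 1.00),
    ("Amami", "Katetsu", "A-Kat", "mtL", 0, None, None, None),
    ("Amami", "Katetsu", "A-Kat", "mtS", 6, 6, 6, 1.00),
    ("Amami", "Kuninao", "A-Kun", "mtL", 14, 14, 14, 1.00),
    ("Amami", "Kuninao", "A-Kun", "mtS", 19, 19, 19, 1.00),
    ("Okinawa", "Zampa", "O-Zam", "mtL", 53, 10, 10, 0.17),
    ("Okinawa", "Zampa", "O-Zam", "mtS", 44, 10, 7, 0.14),
    ("Okinawa", "Odo", "O-Odo", "mtL", 6, 5, 5, 0.80),
    ("Okinawa", "Odo", "O-Odo", "mtS", 7, 6, 5, 0.67),
    ("Okinawa", "Kume", "O-Kum", "mtL", 20, 20, 18, 0.89),
    ("Okinawa", "Kume", "O-Kum", "mtS", 9, 9, 8, 0.88),
    ("Okinawa", "Kume", "O-Kum", "mtLplus", 10, 10, 10, 1.00),
    ("Miyako", "Ikema", "M-Ike", "mtL", 9, 9, 9, 1.00),
    ("Miyako", "Ikema", "M-Ike", "mtS", 5, 5, 5, 1.00),
    ("Miyako", "Yoshino", "M-Yos", "mtL", 24, 2, 1, 0.00),
    ("Miyako", "Yoshino", "M-Yos", "mtS", 3, 2, 2, 0.50),
    ("Miyako", "Ueno", "M-Uen", "mtL", 6, 6, 5, 0.80),
    ("Miyako", "Ueno", "M-Uen", "mtS", 46, 8, 8, 0.16),
    ("Miyako", "Ueno", "M-Uen", "mtLplus", 1, 1, 1, None),
    ("Yaeyama", "Hirakubo", "Y-Hir", "mtL", 5, 2, 2, 0.25),
    ("Yaeyama", "Hirakubo", "Y-Hir", "mtS", 7, 7, 7, 1.00),
    ("Yaeyama", "Ohama", "Y-Oha", "mtL", 36, 3, 3, 0.06),
    ("Yaeyama", "Ohama", "Y-Oha", "mtS", 2, 1, 1, 0.00),
    ("Yaeyama", "Kannon", "Y-Kan", "mtL", 10, 9, 9, 0.89),
    ("Yaeyama", "Kannon", "Y-Kan", "mtS", 7, 7, 6, 0.83),
    ("Yaeyama", "Taketomi", "Y-Tak", "mtL", 14, 10, 9, 0.62),
    ("Yaeyama", "Taketomi", "Y-Tak", "mtS", 16, 14, 14, 0.87),
    ("Yaeyama", "Kuroshima", "Y-Kur", "mtL", 4, 4, 4, 1.00),
    ("Yaeyama", "Kuroshima", "Y-Kur", "mtS", 9, 9, 8, 0.88),
    ("Yaeyama", "Nakano", "Y-Nak", "mtL", 35, 10, 7, 0.18),
    ("Yaeyama", "Nakano", "Y-Nak", "mtS", 2, 2, 2, 1.00),
    ("Yaeyama", "Amitori", "Y-Ami", "mtL", 37, 27, 16, 0.42),
    ("Yaeyama", "Amitori", "Y-Ami", "mtS", 2, 2, 2, 1.00),
    ("Yaeyama", "Haemida", "Y-Hae", "mtL", 12, 7, 3, 0.18),
    ("Yaeyama", "Haemida", "Y-Hae", "mtS", 15, 15, 15, 1.00),
]

#: Published per-type totals over all 17 sites.
_TOTALS = {
    "mtL": {"N": 295, "G": 147, "MLL": 124},
    "mtS": {"N": 204, "G": 127, "MLL": 120},
    "mtLplus": {"N": 11, "G": 11, "MLL": 11},
}


def nansei_survey_counts() -> pd.DataFrame:
    """Published survey counts as a tidy DataFrame.

    Columns: region, site, code, mito_type, N, G, MLL, R_published.
    Strata absent from the survey (N = 0) carry NaN counts; R is NaN
    where the published table shows a dash (absent or singleton strata).
    """
    df = pd.DataFrame(
        _ROWS,
        columns=["region", "site", "code", "mito_type", "N", "G", "MLL", "R_published"],
    )
    for col in ("G", "MLL", "R_published"):
        df[col] = df[col].astype(float)
    return df


def nansei_survey_totals() -> pd.DataFrame:
    """Published per-type N/G/MLL totals (all sites combined)."""
    return (
        pd.DataFrame(_TOTALS)
        .T.rename_axis("mito_type")
        .reset_index()
        .astype({"N": int, "G": int, "MLL": int})
    )
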