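"""Bundled field-campaign tables from the Huailai corn experiment (2015).

Three small tables are shipped with the package so validation statistics
can be recomputed without any external data:

* the DOY schedule of the destructive (LAILLW) and LAI2000 measurements at
  the five monitored sites;
* the 3x3 MODIS LAI pixel windows around the station for ten 8-day
  composite periods, with their printed window means;
* the 19 ground-truth comparison records: destructive LAI (the reference
  value) and the signed errors of the LAI2000 and the photographic system
  ("+" overestimates the truth, "-" underestimates; estimate = truth + error).
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "MODIS_WINDOWS",
    "FIELD_COMPARISON",
    "DOY_SCHEDULE",
    "modis_windows",
    "field_comparison",
    "doy_schedule",
    "table_fixtures",
]

#: (composite label, 9 window values row-major, printed window mean)
MODIS_WINDOWS = (
    ("A2015145", (0.3, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.4, 0.3), 0.244444),
    ("A2015153", (0.3, 0.3, 0.2, 0.3, 0.4, 0.3, 0.5, 0.5, 0.6), 0.377778),
    ("A2015161", (0.7, 0.8, 0.5, 0.8, 0.8, 0.8, 0.8, 0.8, 0.9), 0.766667),
    ("A2015169", (1.1, 1.1, 1.0, 1.1, 1.1, 1.1, 1.3, 1.4, 1.1), 1.144444),
    ("A2015177", (1.2, 2.0, 1.2, 1.8, 1.8, 2.0, 2.0, 2.0, 1.8), 1.755556),
    ("A2015185", (2.2, 3.2, 1.8, 3.5, 2.8, 2.8, 3.5, 3.5, 3.4), 2.966667),
    ("A2015193", (1.9, 1.9, 1.6, 2.0, 2.0, 2.2, 2.1, 2.1, 1.7), 1.944444),
    ("A2015201", (3.1, 3.4, 2.2, 4.0, 3.1, 3.4, 3.0, 3.0, 3.0), 3.133333),
    ("A2015209", (2.6, 2.6, 1.7, 3.0, 0.8, 0.1, 3.0, 0.7, 0.1), 1.622222),
    ("A2015217", (1.9, 1.9, 1.6, 2.0, 2.0, 2.0, 2.5, 2.5, 2.5), 2.1),
)

#: (LAI_LAILLW truth, signed LAI2000 error, signed LAIS error, DOY)
FIELD_COMPARISON = (
    (0.1405, +0.1305, +0.0047, 150),
    (0.2425, +0.0945, +0.0526, 158),
    (0.4864, -0.0574, +0.0755, 158),
    (0.3727, +0.0603, -0.0392, 164),
    (0.4137, -0.0167, +0.0550, 164),
    (0.8898, -0.0518, +0.0742, 164),
    (0.2175, -0.0415, +0.0030, 171),
    (0.3496, +0.1664, +0.2372, 171),
    (0.6577, +0.3323, +0.2622, 171),
    (1.0343, +0.0257, -0.5361, 171),
    (1.0470, -0.1900, +0.3205, 171),
    (1.5469, -0.0669, -0.1150, 171),
    (1.0983, -0.3883, -0.2882, 185),
    (3.1764, -0.6064, -0.4659, 185),
    (2.0416, -0.4516, +0.3373, 197),
    (2.0571, -0.7121, -0.0588, 197),
    (3.2971, -0.7271, +0.2799, 197),
    (4.2481, -0.7481, -0.1652, 197),
    (2.3530, +0.0770, +0.3845, 210),
)

#: site -> (LAILLW DOYs, LAI2000 DOYs)
DOY_SCHEDULE = {
    1: ((150, 158, 164, 171, 185, 197), (150, 158, 164, 171, 197)),
    2: ((150, 158, 164, 171, 185, 197, 213), (171, 185, 197, 213)),
    3: ((150, 158, 171, 185, 197, 213), (171, 185, 197, 213)),
    4: ((150, 158, 164, 171, 185, 197), (158, 164, 171, 185, 197)),
    5: ((150, 158, 164, 171, 185, 197, 213), (158, 164, 171, 185, 197, 213)),
}


def modis_windows() -> pd.DataFrame:
    """3x3 MODIS LAI windows, one row per composite period."""
    rows = []
    for label, values, printed_mean in MODIS_WINDOWS:
        row = {"label": label, "printed_mean": printed_mean}
        row.update({f"p{i+1}": v for i, v in enumerate(values)})
        rows.append(row)
    return pd.DataFrame(rows)


def field_comparison() -> pd.DataFrame:
    """Ground comparison records with reconstructed estimates.

    Columns ``lai2000`` and ``lais`` are truth + signed error.
    """
    df = pd.DataFrame(
        FIELD_COMPARISON, columns=["lai_true", "err_lai2000", "err_lais", "doy"]
    )
    df["lai2000"] = df["lai_true"] + df["err_lai2000"]
    df["lais"] = df["lai_true"] + df["err_lais"]
    return df


def doy_schedule() -> pd.DataFrame:
    """Long-form measurement schedule: one row per (site, source, doy)."""
    rows = []
    for site, (llw, lai2000) in DOY_SCHEDULE.items():
        rows += [{"site": site, "source": "laillw", "doy": d} for d in llw]
        rows += [{"site": site, "source": "lai2000", "doy": d} for d in lai2000]
    return pd.DataFrame(rows)


def table_fixtures() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All bundled tables: (MODIS windows, comparison records, DOY schedule)."""
    return modis_windows(), field_comparison(), doy_schedule()
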