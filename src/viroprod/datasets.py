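"""Packaged reference tables.

``baltic_env_table`` merges the printed physicochemistry and standing-stock
tables of the Baltic Sea redoxcline study (nine depth-zone samples across
Gotland Deep and Landsort Deep 1/2) into :class:`~viroprod.stats.EnvSample`
records, preserving below-detection entries as missing-with-flag.

``synthetic_cross_study_table`` is a SYNTHETIC stand-in for a cross-study
compilation of abundances, virus production, turnover and burst size; its
rows are internally consistent (VPR = VA/PA, VTT = VA/VP, VT = 1/VTT) but
carry no empirical information.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_cross_study_csv, read_env_csv
from .stats import EnvSample

__all__ = [
    "table1_physicochemistry",
    "table2_abundance",
    "baltic_env_table",
    "synthetic_cross_study_table",
]

_DATA = resources.files("viroprod") / "data"


def table1_physicochemistry() -> pd.DataFrame:
    """Printed physicochemical table; 'n.d.'/'<x' parsed to NaN (flagged)."""
    with resources.as_file(_DATA / "table1_physicochemistry.csv") as p:
        return read_env_csv(p)


def table2_abundance() -> pd.DataFrame:
    """Printed abundance/turnover table with scale factors expanded to mL^-1."""
    with resources.as_file(_DATA / "table2_abundance.csv") as p:
        return read_env_csv(p)


def baltic_env_table() -> list[EnvSample]:
    """The nine depth-zone samples with physicochemistry and standing stocks.

    The virus-to-prokaryote ratio is the printed (rounded) column, not
    recomputed, so rank statistics match the published table layout.
    """
    t1 = table1_physicochemistry()
    t2 = table2_abundance().set_index(["station", "zone"])
    samples = []
    for _, row in t1.iterrows():
        ab = t2.loc[(row["station"], row["zone"])]
        samples.append(
            EnvSample(
                station=row["station"],
                zone=row["zone"],
                depth=row["depth_m"],
                temperature=row["temperature_c"],
                salinity=row["salinity"],
                turbidity=row["turbidity_ntu"],
                PO4=_opt(row["po4_um"]),
                NO2=_opt(row["no2_um"]),
                NO3=_opt(row["no3_um"]),
                NH4=_opt(row["nh4_um"]),
                O2=_opt(row["o2_um"]),
                H2S=_opt(row["h2s_um"]),
                prok_abundance=float(ab["prok_avg"]),
                viral_abundance=float(ab["virus_avg"]),
                vpr=float(ab["vpr"]),
            )
        )
    return samples


def synthetic_cross_study_table() -> pd.DataFrame:
    """SYNTHETIC cross-study compilation (see module docstring)."""
    with resources.as_file(_DATA / "synthetic_cross_study.csv") as p:
        return read_cross_study_csv(p)


def _opt(v) -> float | None:
    return None if pd.isna(v) else float(v)
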