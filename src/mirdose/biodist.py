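"""Gamma-counting biodistribution quantification.

Converts raw organ counting measurements (Bq at harvest time) into the
standard biodistribution quantity, percent injected activity per gram
(%IA/g), optionally decay-corrected to the injection time so that harvest
cohorts at different times are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .nuclide import NuclideProperties, decay_factor

#: exact column set of the raw counting CSV dialect
COUNTING_COLUMNS = ["mouse_id", "organ", "mass_g", "activity_Bq", "time_h", "injected_MBq"]
#: column set of the quantified biodistribution CSV dialect
BIODIST_COLUMNS = ["mouse_id", "organ", "time_h", "pct_ia_per_g", "pct_ia"]


@dataclass(frozen=True)
class OrganMeasurement:
    """One harvested-organ gamma-counting measurement.

    ``measured_activity_Bq`` is assumed already converted from counts with a
    single multiplicative counter-efficiency factor (see ``efficiency``
    arguments downstream); times are hours post-injection with the injection
    at ``injection_time_h`` (normally 0).
    """

    mouse_id: str
    organ: str
    mass_g: float
    measured_activity_Bq: float
    measurement_time_h: float
    injected_activity_MBq: float
    injection_time_h: float = 0.0

    def __post_init__(self) -> None:
        if not self.mass_g > 0:
            raise ValueError(f"mass_g must be > 0, got {self.mass_g}")
        if self.measured_activity_Bq < 0:
            raise ValueError("measured_activity_Bq must be >= 0")
        if self.measurement_time_h < self.injection_time_h:
            raise ValueError("measurement_time_h must be >= injection_time_h")


@dataclass(frozen=True)
class BiodistRecord:
    """One organ reduced to %IA/g (and whole-organ %IA when mass is known)."""

    mouse_id: str
    organ: str
    time_h: float
    pct_ia_per_g: float
    pct_ia: float | None = None

    def __post_init__(self) -> None:
        if self.pct_ia_per_g < 0:
            raise ValueError("pct_ia_per_g must be >= 0")


def to_pct_ia_per_g(
    m: OrganMeasurement,
    nuclide: NuclideProperties,
    decay_correct: bool = True,
    efficiency: float = 1.0,
) -> BiodistRecord:
    """Convert a counting measurement to a %IA/g record.

    %IA/g = 100 * A_ref / A_injected / mass, where A_ref is the measured
    activity divided by the counter efficiency and, when ``decay_correct``
    is set, corrected backwards to the injection time with the physical
    decay constant.

    Parameters
    ----------
    m : OrganMeasurement
    nuclide : NuclideProperties
        Supplies the physical half-life for the correction.
    decay_correct : bool
        Correct to injection time (default). When off, the raw harvest-time
        activity is used and %IA/g values at different harvest times are not
        comparable.
    efficiency : float
        Counts-to-Bq calibration already applied to ``measured_activity_Bq``;
        divided out here. Must be > 0.
    """
    if not m.injected_activity_MBq > 0:
        raise ValueError("injected_activity_MBq must be > 0")
    if not efficiency > 0:
        raise ValueError("efficiency must be > 0")
    a = m.measured_activity_Bq / efficiency
    if decay_correct:
        a *= decay_factor(nuclide, m.measurement_time_h - m.injection_time_h)
    injected_bq = m.injected_activity_MBq * 1e6
    pct_per_g = 100.0 * a / injected_bq / m.mass_g
    return BiodistRecord(
        mouse_id=m.mouse_id,
        organ=m.organ,
        time_h=m.measurement_time_h - m.injection_time_h,
        pct_ia_per_g=pct_per_g,
        pct_ia=pct_per_g * m.mass_g,
    )


def quantify(
    counting: pd.DataFrame,
    nuclide: NuclideProperties,
    decay_correct: bool = True,
    efficiency: float = 1.0,
) -> pd.DataFrame:
    """Vectorised :func:`to_pct_ia_per_g` over a counting table.

    Input columns: ``mouse_id, organ, mass_g, activity_Bq, time_h,
    injected_MBq`` (extra columns such as ``tracer`` are carried through).
    Output columns: ``mouse_id, organ, time_h, pct_ia_per_g, pct_ia`` plus
    any carried columns.
    """
    _require_columns(counting, COUNTING_COLUMNS, "counting table")
    if (counting["mass_g"] <= 0).any():
        bad = counting.loc[counting["mass_g"] <= 0].index[0]
        raise ValueError(f"non-positive mass_g at row {bad}")
    if (counting["injected_MBq"] <= 0).any():
        bad = counting.loc[counting["injected_MBq"] <= 0].index[0]
        raise ValueError(f"non-positive injected_MBq at row {bad}")
    if (counting["activity_Bq"] < 0).any():
        raise ValueError("negative activity_Bq in counting table")
    if not efficiency > 0:
        raise ValueError("efficiency must be > 0")

    import numpy as np

    a = counting["activity_Bq"].to_numpy(float) / efficiency
    if decay_correct:
        a = a * np.exp(nuclide.lambda_phys_per_h * counting["time_h"].to_numpy(float))
    pct_per_g = 100.0 * a / (counting["injected_MBq"].to_numpy(float) * 1e6)
    pct_per_g = pct_per_g / counting["mass_g"].to_numpy(float)

    out = counting.drop(columns=["mass_g", "activity_Bq", "injected_MBq"]).copy()
    out["pct_ia_per_g"] = pct_per_g
    out["pct_ia"] = pct_per_g * counting["mass_g"].to_numpy(float)
    extra = [c for c in out.columns if c not in BIODIST_COLUMNS]
    return out[BIODIST_COLUMNS + extra]


def read_counting_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw counting CSV, validating the column contract."""
    df = pd.read_csv(path, comment="#")
    _require_columns(df, COUNTING_COLUMNS, str(path))
    return df


def read_biodist_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    _require_columns(df, BIODIST_COLUMNS, str(path))
    return df


def records_to_frame(records: Iterable[BiodistRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mouse_id": r.mouse_id,
                "organ": r.organ,
                "time_h": r.time_h,
                "pct_ia_per_g": r.pct_ia_per_g,
                "pct_ia": r.pct_ia,
            }
            for r in records
        ],
        columns=BIODIST_COLUMNS,
    )


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}; found {list(df.columns)}")
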