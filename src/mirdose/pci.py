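"""Peritoneal carcinomatosis index (PCI) scoring and tumor-growth summaries.

The PCI quantifies disseminated peritoneal tumor burden at necropsy: the
abdominopelvic cavity is divided into 13 regions (9 abdominopelvic + 4
small-bowel in the Sugarbaker scheme, adapted for rodents), each scored
0-3 by lesion size, and the index is the sum — maximum 39. Region labels
are configurable so any 13-region dialect can be used; a score of 0 for
every region (index 0) is allowed for generality even though tumor-bearing
study animals score at least 1.

Tumor growth under therapy is followed by whole-animal bioluminescence;
only the scalar total flux (photons/s) per imaging session is handled here.
Because flux is log-normally dispersed and per-mouse calibration constants
cancel in ratios, trajectories are normalised to each mouse's baseline and
group curves are geometric means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sugarbaker region grid adapted for rodents: 9 abdominopelvic + 4 small bowel
SUGARBAKER_REGIONS = (
    "central",
    "right_upper",
    "epigastrium",
    "left_upper",
    "left_flank",
    "left_lower",
    "pelvis",
    "right_lower",
    "right_flank",
    "upper_jejunum",
    "lower_jejunum",
    "upper_ileum",
    "lower_ileum",
)

VALID_SCORES = (0, 1, 2, 3)
MAX_PCI = 39

#: bioluminescence loses linearity with tumor size after this day
GROWTH_MAX_DAY = 20


@dataclass(frozen=True)
class PCIMap:
    """Per-region lesion scores for one animal. Missing regions score 0."""

    mouse_id: str
    region_scores: Mapping[str, int]
    regions: tuple[str, ...] = SUGARBAKER_REGIONS

    def __post_init__(self) -> None:
        if len(self.regions) > 13:
            raise ValueError("at most 13 regions")
        unknown = set(self.region_scores) - set(self.regions)
        if unknown:
            raise ValueError(f"unknown region id(s): {sorted(unknown)}; known: {list(self.regions)}")
        bad = {r: s for r, s in self.region_scores.items() if s not in VALID_SCORES}
        if bad:
            raise ValueError(f"lesion scores must be in {VALID_SCORES}; got {bad}")


def pci_total(pci_map: PCIMap) -> int:
    """Total PCI score: sum of region lesion scores, in [0, 39]."""
    return int(sum(pci_map.region_scores.values()))


def maps_from_frame(df: pd.DataFrame, regions: tuple[str, ...] = SUGARBAKER_REGIONS) -> list[PCIMap]:
    """Build PCIMap objects from a long table (mouse_id, region_id, score).

    A ``group`` column, if present, is preserved by the caller via the
    returned order (grouped summaries should use :func:`group_pci_summary`
    on the frame directly).
    """
    for col in ("mouse_id", "region_id", "score"):
        if col not in df.columns:
            raise ValueError(f"PCI table missing column {col!r}")
    out = []
    for mouse, sub in df.groupby("mouse_id", sort=True):
        scores = dict(zip(sub["region_id"], sub["score"].astype(int)))
        out.append(PCIMap(mouse_id=str(mouse), region_scores=scores, regions=regions))
    return out


def group_pci_summary(
    maps_by_group: Mapping[str, Iterable[PCIMap]],
    dispersion: str = "sd",
) -> pd.DataFrame:
    """Per-group mean and dispersion of total PCI.

    ``dispersion`` is ``"sd"`` (n-1 sample SD, the dosimetry-table
    convention) or ``"sem"``. Groups are ordered by name for determinism.
    """
    if dispersion not in ("sd", "sem"):
        raise ValueError("dispersion must be 'sd' or 'sem'")
    rows = []
    for group in sorted(maps_by_group):
        totals = np.array([pci_total(m) for m in maps_by_group[group]], dtype=float)
        if totals.size == 0:
            raise ValueError(f"empty PCI group {group!r}")
        sd = totals.std(ddof=1) if totals.size > 1 else 0.0
        disp = sd if dispersion == "sd" else sd / np.sqrt(totals.size)
        rows.append(
            {
                "group": group,
                "mean_pci": float(totals.mean()),
                dispersion: float(disp),
                "n": int(totals.size),
            }
        )
    return pd.DataFrame(rows)


def growth_ratio(
    records: pd.DataFrame,
    baseline_day: int = 0,
    max_day: int = GROWTH_MAX_DAY,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline-normalised flux trajectories and group geometric means.

    ``records`` columns: ``mouse_id, group, day, total_flux``. Observations
    beyond ``max_day`` are excluded (bioluminescence is not linear in tumor
    size there). A mouse with no positive flux at ``baseline_day`` is
    dropped with a warning. Per-mouse multiplicative calibration constants
    cancel in the ratio.

    Returns ``(per_mouse, per_group)``: per-mouse ratio table and the
    geometric-mean trajectory per group x day.
    """
    for col in ("mouse_id", "group", "day", "total_flux"):
        if col not in records.columns:
            raise ValueError(f"growth table missing column {col!r}")
    df = records[records["day"] <= max_day].copy()
    base = (
        df[df["day"] == baseline_day]
        .groupby("mouse_id")["total_flux"]
        .first()
    )
    keep = base[base > 0]
    dropped = sorted(set(df["mouse_id"]) - set(keep.index))
    if dropped:
        logger.warning("mice without positive baseline flux at day %s dropped: %s", baseline_day, dropped)
    df = df[df["mouse_id"].isin(keep.index)].copy()
    if df.empty:
        raise ValueError("no mice with a valid baseline flux")
    df["flux_ratio"] = df["total_flux"] / df["mouse_id"].map(keep)
    per_group = (
        df.assign(log_ratio=np.log(df["flux_ratio"].where(df["flux_ratio"] > 0)))
        .groupby(["group", "day"], sort=True)["log_ratio"]
        .mean()
        .pipe(np.exp)
        .rename("geom_mean_ratio")
        .reset_index()
    )
    return df[["mouse_id", "group", "day", "flux_ratio"]].reset_index(drop=True), per_group
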