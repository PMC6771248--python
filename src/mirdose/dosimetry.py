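"""MIRD absorbed-dose assembly and cohort aggregation.

The MIRD schema with self-irradiation only reduces, per region, to

    D = A-tilde x S

with A-tilde the cumulated activity (Bq.s per MBq injected) and S the self
S-value (Gy/Bq/s), giving D in Gy per MBq injected. Doses scale linearly to
the administered activity (both the mean and the SD of a cohort scale by
the same factor).

The module exposes both the functional layer (:func:`absorbed_dose`,
:func:`cohort_dose_table`, :func:`scale_to_administration`) and a
model/results pair: :class:`MIRDDoseModel` is built from a quantified
biodistribution table plus an S-factor table, and ``fit()`` returns a
:class:`MIRDDoseResults` with per-mouse doses, the cohort mean +/- SD table,
therapy-activity scaling and a text summary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .biodist import BIODIST_COLUMNS
from .nuclide import LU177, NuclideProperties
from .svalues import SValueEntry, load_s_table, s_entries_from_table
from .tac import SCHEMES, cumulated_activity, tac_from_biodist, CumulatedActivity

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DoseResult:
    """Absorbed dose for one region, per MBq injected."""

    organ: str
    dose_gy_per_MBq: float
    sd_gy_per_MBq: float = 0.0
    n_mice: int = 1
    tracer: str = ""

    def __post_init__(self) -> None:
        if self.dose_gy_per_MBq < 0:
            raise ValueError("dose must be >= 0")
        if self.sd_gy_per_MBq < 0:
            raise ValueError("sd must be >= 0")


@dataclass(frozen=True)
class AdministeredDose:
    """Absorbed dose for one administration of a given activity (Gy)."""

    organ: str
    dose_gy: float
    sd_gy: float
    administered_MBq: float
    n_mice: int = 1
    tracer: str = ""


def absorbed_dose(a_tilde: CumulatedActivity, s: SValueEntry) -> DoseResult:
    """Per-mouse absorbed dose D = A-tilde x S (Gy/MBq).

    The two inputs must refer to the same region.
    """
    if a_tilde.organ != s.organ:
        raise ValueError(f"organ mismatch: cumulated activity is {a_tilde.organ!r}, S-value is {s.organ!r}")
    return DoseResult(
        organ=s.organ,
        dose_gy_per_MBq=a_tilde.a_tilde_s_per_MBq * s.s_gy_per_bq_s,
    )


def scale_to_administration(d: DoseResult, administered_MBq: float) -> AdministeredDose:
    """Scale a per-MBq dose (mean and SD) to an administered activity."""
    if not administered_MBq > 0:
        raise ValueError("administered_MBq must be > 0")
    return AdministeredDose(
        organ=d.organ,
        dose_gy=d.dose_gy_per_MBq * administered_MBq,
        sd_gy=d.sd_gy_per_MBq * administered_MBq,
        administered_MBq=administered_MBq,
        n_mice=d.n_mice,
        tracer=d.tracer,
    )


def cohort_dose_table(
    per_mouse_doses: pd.DataFrame,
    group_keys: list[str] = ("organ", "tracer"),
    organ_order: list[str] | None = None,
) -> pd.DataFrame:
    """Cohort mean +/- sample SD of per-mouse doses.

    ``per_mouse_doses`` needs columns ``mouse_id, organ, dose_gy_per_MBq``
    (plus any grouping columns such as ``tracer``). SD is the n-1 sample
    standard deviation, reported as 0 for singleton groups (``n_mice``
    carries the flag). Rows are ordered by ``organ_order`` (default: the
    packaged S-factor table order) then the remaining group keys, so the
    output is deterministic under permutation of the input mice.
    """
    group_keys = [k for k in group_keys if k in per_mouse_doses.columns]
    if not group_keys:
        raise ValueError("no usable group keys in per-mouse dose table")
    if per_mouse_doses.empty:
        raise ValueError("empty per-mouse dose table")
    g = per_mouse_doses.groupby(group_keys, sort=False)["dose_gy_per_MBq"]
    out = g.agg(
        dose_gy_per_MBq="mean",
        sd_gy_per_MBq=lambda x: x.std(ddof=1) if len(x) > 1 else 0.0,
        n_mice="count",
    ).reset_index()
    if organ_order is None:
        organ_order = list(load_s_table()["organ"])
    rank = {o: i for i, o in enumerate(organ_order)}
    out["_rank"] = out["organ"].map(lambda o: rank.get(o, len(rank)))
    rest = [k for k in group_keys if k != "organ"]
    out = out.sort_values(["_rank", "organ"] + rest, kind="mergesort").drop(columns="_rank")
    return out.reset_index(drop=True)


def load_reference_dose_table() -> pd.DataFrame:
    """Packaged cohort dosimetry reference table (Gy/MBq, mean +/- SD).

    Per-organ, per-radioligand self-dose results of the pretargeted Lu-177
    mouse study the defaults emulate; useful for therapy-activity scaling
    and as a regression anchor.
    """
    from importlib import resources

    with resources.files("mirdose.data").joinpath("reference_doses_gy_per_mbq.csv").open() as fh:
        return pd.read_csv(fh)


class MIRDDoseModel:
    """Self-irradiation MIRD dose model for a biodistribution cohort.

    Parameters
    ----------
    biodist : DataFrame
        Quantified biodistribution records with columns
        ``mouse_id, organ, time_h, pct_ia_per_g, pct_ia`` and optionally a
        ``tracer`` grouping column (output of :func:`mirdose.quantify`).
    s_table : DataFrame, optional
        S-factor table (``organ, s_gy_per_bq_s, mass_g``); defaults to the
        packaged Lu-177 mouse table.
    nuclide : NuclideProperties
        Defaults to Lu-177.
    decay_corrected : bool
        Whether the %IA values are decay-corrected to injection time (the
        quantification default); physical decay is restored before
        integration.
    strict : bool
        If true, organs absent from the S-factor table raise; otherwise they
        are dropped with a warning.
    """

    def __init__(
        self,
        biodist: pd.DataFrame,
        s_table: pd.DataFrame | None = None,
        nuclide: NuclideProperties = LU177,
        decay_corrected: bool = True,
        strict: bool = False,
    ) -> None:
        missing = [c for c in BIODIST_COLUMNS if c not in biodist.columns]
        if missing:
            raise ValueError(f"biodist table missing column(s) {missing}")
        self.s_table = load_s_table() if s_table is None else s_table
        self.s_entries = s_entries_from_table(self.s_table)
        self.nuclide = nuclide
        self.decay_corrected = decay_corrected

        organs = set(biodist["organ"])
        unmatched = sorted(organs - set(self.s_entries))
        if unmatched:
            msg = f"organs with no S-value entry: {unmatched}"
            if strict:
                raise ValueError(msg)
            logger.warning("%s -- dropped from dosimetry", msg)
        self.unmatched_organs = unmatched
        self.biodist = biodist[biodist["organ"].isin(self.s_entries)].copy()
        if self.biodist.empty:
            raise ValueError("no biodistribution records match the S-value table")
        if "tracer" not in self.biodist.columns:
            self.biodist["tracer"] = ""

    @classmethod
    def from_counting(
        cls,
        counting: pd.DataFrame,
        nuclide: NuclideProperties = LU177,
        decay_correct: bool = True,
        efficiency: float = 1.0,
        **kwargs,
    ) -> "MIRDDoseModel":
        """Build directly from a raw counting table (quantifies %IA/g first)."""
        from .biodist import quantify

        bd = quantify(counting, nuclide, decay_correct=decay_correct, efficiency=efficiency)
        return cls(bd, nuclide=nuclide, decay_corrected=decay_correct, **kwargs)

    def fit(
        self,
        scheme: str = "trapezoid_tail",
        tail_window: int = 2,
        per_mouse: bool = True,
    ) -> "MIRDDoseResults":
        """Integrate time-activity curves and assemble absorbed doses.

        ``per_mouse=True`` (default) integrates each mouse's own curve and
        averages the doses; ``per_mouse=False`` integrates the cohort-mean
        curve per organ, yielding a single dose per organ x tracer with no
        dispersion estimate.
        """
        if scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
        rows = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rising tails are handled by the floor
            for tracer, tdf in self.biodist.groupby("tracer", sort=False):
                for organ in tdf["organ"].unique():
                    s = self.s_entries[organ]
                    if per_mouse:
                        for mouse, _ in tdf[tdf["organ"] == organ].groupby("mouse_id", sort=False):
                            curve = tac_from_biodist(
                                tdf, organ, self.nuclide, self.decay_corrected, mouse_id=mouse
                            )
                            at = cumulated_activity(curve, self.nuclide, scheme, tail_window)
                            rows.append(
                                {
                                    "tracer": tracer,
                                    "mouse_id": mouse,
                                    "organ": organ,
                                    "a_tilde_s_per_MBq": at.a_tilde_s_per_MBq,
                                    "lambda_eff_per_h": at.lambda_eff_per_h,
                                    "dose_gy_per_MBq": absorbed_dose(at, s).dose_gy_per_MBq,
                                }
                            )
                    else:
                        curve = tac_from_biodist(tdf, organ, self.nuclide, self.decay_corrected)
                        at = cumulated_activity(curve, self.nuclide, scheme, tail_window)
                        rows.append(
                            {
                                "tracer": tracer,
                                "mouse_id": "<mean curve>",
                                "organ": organ,
                                "a_tilde_s_per_MBq": at.a_tilde_s_per_MBq,
                                "lambda_eff_per_h": at.lambda_eff_per_h,
                                "dose_gy_per_MBq": absorbed_dose(at, s).dose_gy_per_MBq,
                            }
                        )
        per_mouse_df = pd.DataFrame(rows)
        # deterministic ordering regardless of input row order
        rank = {o: i for i, o in enumerate(self.s_table["organ"])}
        per_mouse_df = per_mouse_df.sort_values(
            ["organ", "tracer", "mouse_id"],
            key=lambda col: col.map(rank) if col.name == "organ" else col,
            kind="mergesort",
        ).reset_index(drop=True)
        return MIRDDoseResults(self, per_mouse_df, scheme=scheme, per_mouse=per_mouse)


class MIRDDoseResults:
    """Fitted cohort dosimetry: per-mouse doses and cohort summaries."""

    def __init__(self, model: MIRDDoseModel, doses: pd.DataFrame, scheme: str, per_mouse: bool):
        self.model = model
        #: per-mouse table: tracer, mouse_id, organ, a_tilde, lambda_eff, dose
        self.doses = doses
        self.scheme = scheme
        self.per_mouse = per_mouse
        #: cohort table: organ (x tracer) mean dose, sample SD, n
        self.dose_table = cohort_dose_table(
            doses, ["organ", "tracer"], organ_order=list(model.s_table["organ"])
        )
        if not per_mouse:
            self.dose_table["sd_gy_per_MBq"] = np.nan

    def scale_to(self, administered_MBq: float) -> pd.DataFrame:
        """Cohort dose table scaled to an administered activity (Gy)."""
        if not administered_MBq > 0:
            raise ValueError("administered_MBq must be > 0")
        out = self.dose_table.copy()
        out["dose_gy"] = out["dose_gy_per_MBq"] * administered_MBq
        out["sd_gy"] = out["sd_gy_per_MBq"] * administered_MBq
        out["administered_MBq"] = administered_MBq
        return out.drop(columns=["dose_gy_per_MBq", "sd_gy_per_MBq"])

    def summary(self, administered_MBq: float | None = None) -> str:
        """Human-readable cohort dosimetry report."""
        lines = [
            "MIRD self-dose cohort summary",
            f"  nuclide: {self.model.nuclide.name} (T1/2 = {self.model.nuclide.half_life_days} d)",
            f"  integration scheme: {self.scheme}"
            + ("" if self.per_mouse else " (cohort-mean curve)"),
        ]
        if self.model.unmatched_organs:
            lines.append(f"  organs without S-value (excluded): {', '.join(self.model.unmatched_organs)}")
        tbl = self.dose_table.copy()
        if administered_MBq:
            tbl["dose_gy"] = tbl["dose_gy_per_MBq"] * administered_MBq
            tbl["sd_gy"] = tbl["sd_gy_per_MBq"] * administered_MBq
        with pd.option_context("display.float_format", "{:.3e}".format):
            lines.append(tbl.to_string(index=False))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Bar chart of cohort mean doses with SD error bars (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tbl = self.dose_table
        labels = tbl["organ"] + np.where(tbl["tracer"].ne(""), " / " + tbl["tracer"].astype(str), "")
        ax.bar(labels, tbl["dose_gy_per_MBq"], yerr=tbl["sd_gy_per_MBq"].fillna(0.0), capsize=3)
        ax.set_ylabel("absorbed dose (Gy/MBq)")
        ax.tick_params(axis="x", rotation=60)
        return ax
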