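"""Radionuclide physical constants and decay arithmetic.

All decay bookkeeping in the package goes through :func:`decay_factor` so
that the convention is fixed in one place: a *positive* ``delta_t_h``
multiplies the activity up (decay-correct a measurement backwards to an
earlier reference time), a *negative* one decays it forward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

LN2 = math.log(2.0)

#: keV -> joule
KEV_TO_J = 1.602176634e-16


@dataclass(frozen=True)
class NuclideProperties:
    """Physical constants of a beta-emitting radionuclide.

    Parameters
    ----------
    name : str
        Display label, e.g. ``"Lu-177"``.
    half_life_days : float
        Physical half-life in days.
    mean_beta_energy_keV, max_beta_energy_keV : float
        Mean and endpoint energy of the beta spectrum (keV).
    mean_range_soft_tissue_mm : float
        Mean CSDA range of the emitted electrons in soft tissue (mm).
    """

    name: str
    half_life_days: float
    mean_beta_energy_keV: float
    max_beta_energy_keV: float
    mean_range_soft_tissue_mm: float

    def __post_init__(self) -> None:
        if not self.half_life_days > 0:
            raise ValueError(f"half_life_days must be > 0, got {self.half_life_days}")
        if not 0 < self.mean_beta_energy_keV < self.max_beta_energy_keV:
            raise ValueError(
                "need 0 < mean_beta_energy_keV < max_beta_energy_keV, got "
                f"{self.mean_beta_energy_keV} / {self.max_beta_energy_keV}"
            )
        if not self.mean_range_soft_tissue_mm > 0:
            raise ValueError("mean_range_soft_tissue_mm must be > 0")

    @property
    def half_life_h(self) -> float:
        """Physical half-life in hours."""
        return self.half_life_days * 24.0

    @property
    def lambda_phys_per_h(self) -> float:
        """Physical decay constant, per hour (ln 2 / T1/2)."""
        return LN2 / self.half_life_h


def decay_factor(nuclide: NuclideProperties, delta_t_h: float) -> float:
    """Multiplicative physical-decay factor exp(lambda * delta_t).

    ``delta_t_h > 0`` corrects an activity *backwards* in time (the factor is
    > 1: the activity was larger ``delta_t_h`` hours earlier); ``delta_t_h < 0``
    decays it forward. ``delta_t_h = 0`` returns exactly 1.

    Raises
    ------
    ValueError
        If ``delta_t_h`` is not finite.
    """
    if not math.isfinite(delta_t_h):
        raise ValueError(f"delta_t_h must be finite, got {delta_t_h}")
    return math.exp(nuclide.lambda_phys_per_h * delta_t_h)


def _nuclide_table() -> pd.DataFrame:
    with resources.files("mirdose.data").joinpath("nuclides.csv").open() as fh:
        return pd.read_csv(fh)


def get_nuclide(name: str) -> NuclideProperties:
    """Look up a nuclide from the packaged constants table by name."""
    table = _nuclide_table()
    row = table[table["name"] == name]
    if row.empty:
        known = ", ".join(table["name"])
        raise KeyError(f"unknown nuclide {name!r}; known: {known}")
    r = row.iloc[0]
    return NuclideProperties(
        name=str(r["name"]),
        half_life_days=float(r["half_life_days"]),
        mean_beta_energy_keV=float(r["mean_beta_energy_keV"]),
        max_beta_energy_keV=float(r["max_beta_energy_keV"]),
        mean_range_soft_tissue_mm=float(r["mean_range_soft_tissue_mm"]),
    )


#: Lutetium-177: T1/2 = 6.65 d, mean beta energy 133.3 keV, endpoint 498.3 keV,
#: mean range in soft tissue 0.2 mm.
LU177 = NuclideProperties(
    name="Lu-177",
    half_life_days=6.65,
    mean_beta_energy_keV=133.3,
    max_beta_energy_keV=498.3,
    mean_range_soft_tissue_mm=0.2,
)
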