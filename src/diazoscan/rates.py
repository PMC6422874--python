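"""Nitrogen-fixation rate calculations.

Two independent field assays are supported and made comparable on a
gram-nitrogen basis:

* **Acetylene reduction (ARA)** — nitrogenase reduces acetylene to
  ethylene; activity is the difference in ethylene production rate with
  and without acetylene, in nmol C2H4 plant^-1 h^-1.  Conversion to fixed
  nitrogen assumes 4 mol C2H4 per mol N2 (the theoretical electron-pair
  stoichiometry; 3 is a common empirical alternative) and 28 g/mol N2:
  ``nmol N2 day^-1 = ARA * 24 / 4`` and ``ug N day^-1 = nmol N2 day^-1 *
  28 / 1000`` (equivalently ARA * 0.168).

* **15N2 feeding** — roots incubated under 15N2; fixed N is computed from
  the 15N atom% excess ``a`` over an unlabelled control, root dry biomass
  ``b`` (g) and N content ``c`` (% of dry weight):
  ``ug N day^-1 = b * (c/100) * (a/100) * 1e6 * (24 / incubation_hours)``.
  delta-15N (permil vs air N2, standard ratio 0.0036765) converts to atom%
  via ``R = (delta/1000 + 1) * R_std``, ``atom% = 100 * R / (1 + R)``.

Rates are computed per replicate first and averaged afterwards; negative
ARA differences and negative atom% excesses are reported, not clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

#: 15N/14N ratio of atmospheric N2
R_STANDARD_AIR = 0.0036765


@dataclass(frozen=True)
class ConversionConstants:
    """Stoichiometric constants for the ARA -> fixed-N conversion."""

    c2h2_to_n2_ratio: float = 4.0  # mol C2H4 per mol N2
    n2_molar_mass: float = 28.0  # g/mol
    hours_per_day: float = 24.0

    def __post_init__(self) -> None:
        if min(self.c2h2_to_n2_ratio, self.n2_molar_mass, self.hours_per_day) <= 0:
            raise ValueError("conversion constants must be positive")


DEFAULT_CONSTANTS = ConversionConstants()


@dataclass(frozen=True)
class AraMeasurement:
    ethylene_with_acetylene: float  # nmol C2H4 produced over the incubation
    ethylene_without_acetylene: float
    incubation_hours: float
    plants: int = 1

    def __post_init__(self) -> None:
        if self.incubation_hours <= 0:
            raise ValueError("incubation_hours must be positive")
        if self.plants < 1:
            raise ValueError("plants must be >= 1")


@dataclass(frozen=True)
class IsotopeMeasurement:
    delta15N_permil: float
    control_delta15N_permil: float
    root_dry_weight_g: float
    n_content_percent: float
    incubation_hours: float = 23.0
    r_standard: float = R_STANDARD_AIR

    def __post_init__(self) -> None:
        if min(self.root_dry_weight_g, self.n_content_percent,
               self.incubation_hours) <= 0:
            raise ValueError("weights, contents and hours must be positive")


def ara_rate(m: AraMeasurement) -> float:
    """Acetylene-reducing activity in nmol C2H4 plant^-1 h^-1.

    The difference in ethylene production with vs without acetylene,
    normalized by incubation time and plant count; may be negative and is
    returned unchanged.
    """
    return (
        (m.ethylene_with_acetylene - m.ethylene_without_acetylene)
        / m.incubation_hours
        / m.plants
    )


def ara_to_n2_fixation(
    ara: float, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> tuple[float, float]:
    """Convert ARA to (nmol N2 plant^-1 day^-1, ug N plant^-1 day^-1)."""
    nmol_n2_day = ara * constants.hours_per_day / constants.c2h2_to_n2_ratio
    ug_n_day = nmol_n2_day * constants.n2_molar_mass / 1000.0
    return nmol_n2_day, ug_n_day


def delta_to_atom_percent(delta_permil: float, r_standard: float = R_STANDARD_AIR) -> float:
    """delta-15N (permil vs air) -> atom% 15N; strictly increasing in delta."""
    if delta_permil <= -1000.0:
        raise ValueError("delta-15N must exceed -1000 permil")
    r = (delta_permil / 1000.0 + 1.0) * r_standard
    return 100.0 * r / (1.0 + r)


def atom_percent_to_delta(atom_percent: float, r_standard: float = R_STANDARD_AIR) -> float:
    """Inverse of :func:`delta_to_atom_percent`."""
    if not 0 < atom_percent < 100:
        raise ValueError("atom_percent must be in (0, 100)")
    r = atom_percent / (100.0 - atom_percent)
    return (r / r_standard - 1.0) * 1000.0


def isotope_fixation_rate(
    m: IsotopeMeasurement, gas_atom_percent: float | None = None
) -> float:
    """15N2-feeding fixation rate in ug N plant^-1 day^-1.

    atom% excess = atom%(sample) - atom%(control); fixed N = biomass x
    N-content x excess, scaled to a day.  A negative excess produces a
    non-positive rate with a warning.  ``gas_atom_percent`` optionally
    corrects for an incompletely labelled gas phase (divides by the gas
    phase's atom% excess fraction).
    """
    a = delta_to_atom_percent(m.delta15N_permil, m.r_standard) - delta_to_atom_percent(
        m.control_delta15N_permil, m.r_standard
    )
    if a < -1e-12:  # tolerate round-trip rounding at exactly zero excess
        warnings.warn("negative atom% excess: sample below control enrichment")
    rate = (
        m.root_dry_weight_g
        * (m.n_content_percent / 100.0)
        * (a / 100.0)
        * 1e6
        * (24.0 / m.incubation_hours)
    )
    if gas_atom_percent is not None:
        ctrl = delta_to_atom_percent(m.control_delta15N_permil, m.r_standard)
        rate /= (gas_atom_percent - ctrl) / 100.0
    return rate


def isotope_to_ara_ratio(isotope_rate: float, ara_rate_ugN: float) -> float:
    """Ratio of the 15N2-feeding rate to the ARA-derived rate (both ug N
    plant^-1 day^-1)."""
    if ara_rate_ugN == 0:
        raise ZeroDivisionError("ARA-derived rate is zero; ratio undefined")
    return isotope_rate / ara_rate_ugN


# ---------------------------------------------------------------------------
# table-level helpers


def compute_assay_table(
    df: pd.DataFrame, constants: ConversionConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Derive per-plant fixation rates from a raw measurement table.

    Expects the columns written by the assay simulator (or equivalently
    shaped field data): ethylene_with_nmol, ethylene_without_nmol,
    ara_incubation_hours, plants, delta15n_permil, control_delta15n_permil,
    root_dry_weight_g, n_content_percent, isotope_incubation_hours.
    """
    out = df.copy()
    rates, n2, ug, atom, excess, iso = [], [], [], [], [], []
    for row in df.itertuples(index=False):
        r = ara_rate(
            AraMeasurement(
                row.ethylene_with_nmol,
                row.ethylene_without_nmol,
                row.ara_incubation_hours,
                int(row.plants),
            )
        )
        nn, uu = ara_to_n2_fixation(r, constants)
        m = IsotopeMeasurement(
            row.delta15n_permil,
            row.control_delta15n_permil,
            row.root_dry_weight_g,
            row.n_content_percent,
            row.isotope_incubation_hours,
        )
        rates.append(r)
        n2.append(nn)
        ug.append(uu)
        atom.append(delta_to_atom_percent(row.delta15n_permil))
        excess.append(
            delta_to_atom_percent(row.delta15n_permil)
            - delta_to_atom_percent(row.control_delta15n_permil)
        )
        iso.append(isotope_fixation_rate(m))
    out["ara_nmol_c2h4_plant_h"] = rates
    out["n2_nmol_plant_day"] = n2
    out["ara_ug_n_plant_day"] = ug
    out["atom_percent_15n"] = atom
    out["atom_percent_excess"] = excess
    out["isotope_ug_n_plant_day"] = iso
    out["isotope_to_ara_ratio"] = [
        i / u if u != 0 else float("nan") for i, u in zip(iso, ug)
    ]
    return out


def summarize_lines(derived: pd.DataFrame) -> pd.DataFrame:
    """Per-line means and standard errors of the derived rates (replicates
    first, then averaging)."""
    cols = [
        "ara_nmol_c2h4_plant_h",
        "n2_nmol_plant_day",
        "ara_ug_n_plant_day",
        "isotope_ug_n_plant_day",
        "isotope_to_ara_ratio",
    ]
    g = derived.groupby("line")[cols]
    mean = g.mean().add_suffix("_mean")
    sem = g.sem().add_suffix("_sem")
    return mean.join(sem).reset_index()
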