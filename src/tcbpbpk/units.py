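"""Unit handling for scenario inputs.

Canonical internal units are nmol (amount), nM (concentration), mL (volume)
and h (time).  Mass doses are converted to molar amounts through the
molecule's molecular weight (default 150 kDa for an IgG-format bispecific);
per-kilogram quantities are resolved through the animal's body weight.
"""

from __future__ import annotations

DEFAULT_MW_KDA = 150.0

#: units accepted by :func:`resolve_units`, mapped to their canonical dimension
ACCEPTED_UNITS = {
    "mg": "amount",
    "ug": "amount",
    "µg": "amount",
    "nmol": "amount",
    "mg/kg": "amount_per_kg",
    "ug/kg": "amount_per_kg",
    "µg/kg": "amount_per_kg",
    "nM": "concentration",
    "mL": "volume",
    "ml": "volume",
    "mL/kg": "volume_per_kg",
    "ml/kg": "volume_per_kg",
    "h": "time",
    "cells": "cells",
}


class UnitError(ValueError):
    """Raised for unknown units or missing context (body weight, MW)."""


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise UnitError(message)


def mass_mg_to_nmol(mass_mg: float, mw_kda: float = DEFAULT_MW_KDA) -> float:
    """Convert a mass in mg to nmol given the molecular weight in kDa.

    1 mg of a 150 kDa protein is 1/150000 mmol = 6.667e-3 µmol = 6.667 nmol.
    """
    _require(mw_kda > 0, "molecular weight must be positive")
    return mass_mg / (mw_kda * 1000.0) * 1.0e6


def nmol_to_mass_mg(amount_nmol: float, mw_kda: float = DEFAULT_MW_KDA) -> float:
    """Inverse of :func:`mass_mg_to_nmol` (exact to floating point)."""
    _require(mw_kda > 0, "molecular weight must be positive")
    return amount_nmol * (mw_kda * 1000.0) / 1.0e6


def resolve_units(
    value: float,
    unit: str,
    *,
    mw_kda: float = DEFAULT_MW_KDA,
    body_weight_kg: float | None = None,
) -> tuple[float, str]:
    """Resolve ``value`` expressed in ``unit`` to a canonical (value, unit) pair.

    Amounts become nmol, volumes mL, times h.  ``mg/kg`` and ``mL/kg``
    require ``body_weight_kg``.  Unknown units raise :class:`UnitError`
    listing the accepted set.

    Examples
    --------
    >>> resolve_units(0.5, "mg/kg", body_weight_kg=0.02, mw_kda=150.0)
    (0.06666666666666667, 'nmol')
    >>> resolve_units(4.04, "mL/kg", body_weight_kg=0.02)
    (0.0808, 'mL')
    """
    if unit not in ACCEPTED_UNITS:
        raise UnitError(
            f"unknown unit {unit!r}; accepted units: {sorted(set(ACCEPTED_UNITS))}"
        )
    kind = ACCEPTED_UNITS[unit]
    if kind in ("amount_per_kg", "volume_per_kg"):
        _require(
            body_weight_kg is not None and body_weight_kg > 0,
            f"unit {unit!r} requires a positive body weight",
        )
    if kind == "amount":
        if unit == "nmol":
            return value, "nmol"
        mass_mg = value if unit == "mg" else value * 1e-3
        return mass_mg_to_nmol(mass_mg, mw_kda), "nmol"
    if kind == "amount_per_kg":
        mass = value * body_weight_kg  # mg or ug total
        mass_mg = mass if unit == "mg/kg" else mass * 1e-3
        return mass_mg_to_nmol(mass_mg, mw_kda), "nmol"
    if kind == "concentration":
        return value, "nM"
    if kind == "volume":
        return value, "mL"
    if kind == "volume_per_kg":
        return value * body_weight_kg, "mL"
    if kind == "time":
        return value, "h"
    return value, unit  # cells


def amount_to_conc_nM(amount_nmol: float, volume_mL: float) -> float:
    """nmol in a mL volume expressed as nmol/L (= nM)."""
    return amount_nmol / (volume_mL * 1e-3)


def conc_nM_to_amount(conc_nM: float, volume_mL: float) -> float:
    """Inverse of :func:`amount_to_conc_nM`."""
    return conc_nM * volume_mL * 1e-3


#: Avogadro's number (1/mol)
N_AVOGADRO = 6.02214076e23


def receptors_to_nmol(n_receptors: float) -> float:
    """Convert a receptor copy number to nmol."""
    return n_receptors / N_AVOGADRO * 1e9


def cells_receptors_to_nmol(n_cells: float, receptors_per_cell: float) -> float:
    """Total receptor amount (nmol) carried by ``n_cells`` cells."""
    return receptors_to_nmol(n_cells * receptors_per_cell)
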