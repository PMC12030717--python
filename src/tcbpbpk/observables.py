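"""Map simulated states to measurable biodistribution quantities.

Dual-radiolabel observable model: a non-residualizing label (e.g. 125I)
effluxes from cells after antibody catabolism, so its tissue signal is the
sum of intact antibody-containing species; a residualizing label (e.g.
111In) stays trapped, so its signal additionally includes the organ's
cumulative catabolized pool.  Sampled tissues carry residual blood, modeled
additively on a per-gram basis: C_obs = C_tissue + rbf * C_blood.  Signals
are reported as percent of injected dose per gram (%ID/g) assuming tissue
density 1 g/mL.

The synthetic-data generator emulates the study design those observables
were measured under: a 0.5 mg/kg IV bolus, organs sampled at sparse time
points (72 h as the principal point), three replicate animals per point and
multiplicative log-normal measurement noise (default CV 20%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import INTACT_TCB_SPECIES, SimulationResult, simulate
from .physiology import BLOOD_COMPARTMENTS, ScenarioConfig
from .tcells import TCellParams, simulate_adoptive_transfer

LABEL_TYPES = ("residualizing", "non_residualizing")


@dataclass
class ObservableSpec:
    """One measurable series: an organ sampled over time with one label."""

    organ: str
    label_type: str = "non_residualizing"
    times: tuple = (72.0,)
    quantity: str = "percent_id_per_g"  # or "nM"
    apply_residual_blood: bool = True

    def __post_init__(self):
        if self.label_type not in LABEL_TYPES:
            raise ValueError(f"label_type must be one of {LABEL_TYPES}")


def _organ_signal_amount(result: SimulationResult, organ: str, label_type: str) -> np.ndarray:
    """Label signal (nmol equivalent) in one organ over the result grid."""
    if organ == "blood":
        total = np.zeros(len(result.t))
        for b in BLOOD_COMPARTMENTS:
            total += result.organ_amount(
                b, include_catabolized=(label_type == "residualizing")
            )
        return total
    return result.organ_amount(
        organ, include_catabolized=(label_type == "residualizing")
    )


def _organ_mass_g(scenario: ScenarioConfig, organ: str) -> float:
    if organ == "blood":
        return sum(scenario.organ(b).total_volume for b in BLOOD_COMPARTMENTS)
    return scenario.organ(organ).mass_g


def observe_tissue(
    result: SimulationResult, spec: ObservableSpec, dose_nmol: float | None = None
) -> np.ndarray:
    """Observable series at the requested times.

    %ID/g: ``100 * amount / dose / mass``, corrected for residual blood as
    ``C_obs = C_tissue + rbf * C_blood`` (both per gram).  Times beyond the
    simulated horizon raise an error.
    """
    dose = result.dose_nmol if dose_nmol is None else dose_nmol
    times = np.asarray(spec.times, dtype=float)
    if times.max() > result.t[-1] + 1e-9:
        raise ValueError(
            f"requested time {times.max()} h beyond simulated horizon {result.t[-1]} h"
        )
    scenario = result.system.scenario
    amount = _organ_signal_amount(result, spec.organ, spec.label_type)
    mass = _organ_mass_g(scenario, spec.organ)
    if spec.quantity == "nM":
        series = amount / mass * 1000.0  # nmol/mL at density 1 g/mL
    elif spec.quantity == "percent_id_per_g":
        if dose <= 0:
            raise ValueError("dose must be positive for %ID/g")
        series = 100.0 * amount / dose / mass
    else:
        raise ValueError(f"unknown quantity {spec.quantity!r}")
    if spec.apply_residual_blood and spec.organ != "blood":
        blood_amount = _organ_signal_amount(result, "blood", spec.label_type)
        blood_mass = _organ_mass_g(scenario, "blood")
        if spec.quantity == "nM":
            blood_series = blood_amount / blood_mass * 1000.0
        else:
            blood_series = 100.0 * blood_amount / dose / blood_mass
        rbf = scenario.organ(spec.organ).residual_blood_fraction
        series = series + rbf * blood_series
    return np.interp(times, result.t, series)


def percent_id_bookkeeping(result: SimulationResult) -> pd.DataFrame:
    """Whole-body %ID ledger per label at each output time.

    For the residualizing label nothing leaves the body, so organs + blood
    sum to 100%; for the non-residualizing label the catabolized fraction
    has effluxed and is booked as excreted, closing the balance at 100%.
    """
    scenario = result.system.scenario
    organs = [o.name for o in scenario.organs if o.name not in BLOOD_COMPARTMENTS]
    rows = []
    dose = result.dose_nmol
    for label in LABEL_TYPES:
        total = _organ_signal_amount(result, "blood", label).copy()
        for organ in organs:
            total += _organ_signal_amount(result, organ, label)
        excreted = np.zeros(len(result.t))
        if label == "non_residualizing":
            for key, i in result.layout.index.items():
                if key[-1] == "catabolized":
                    excreted += result.y[:, i]
        for t, tot, exc in zip(result.t, total, excreted):
            rows.append(
                {
                    "time_h": t,
                    "label_type": label,
                    "percent_id_in_body": 100.0 * tot / dose,
                    "percent_id_excreted": 100.0 * exc / dose,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------

DEFAULT_BIODISTRIBUTION_ORGANS = (
    "blood",
    "lung",
    "heart",
    "spleen",
    "lymph_node",
    "liver",
    "kidney",
    "muscle",
    "skin",
    "tumor",
)


@dataclass
class SyntheticDataset:
    """Reproducible noisy dataset plus the record of what generated it."""

    data: pd.DataFrame
    true_params: dict
    design: dict
    seed: int
    cv: float
    n_replicates: int


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with coefficient of
    variation ``cv`` (CV = 0 returns exact ones)."""
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def generate_synthetic_biodistribution(
    scenario: ScenarioConfig,
    molecules=("gD", "gD-CD3H", "HER2-CD3L"),
    organs=DEFAULT_BIODISTRIBUTION_ORGANS,
    times=(24.0, 72.0),
    label_types=LABEL_TYPES,
    dose_mg_per_kg: float = 0.5,
    cv: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    rtol: float = 1e-6,
) -> SyntheticDataset:
    """Simulate the biodistribution study and apply measurement noise.

    Deterministic given ``seed``; CV = 0 reproduces the noise-free
    observables exactly.
    """
    rng = np.random.default_rng(seed)
    t_eval = np.unique(np.concatenate([[0.0], np.geomspace(1e-3, max(times) * 1.05, 120)]))
    rows = []
    from .units import mass_mg_to_nmol

    for mol_name in molecules:
        mol = scenario.molecule(mol_name)
        dose_nmol = mass_mg_to_nmol(dose_mg_per_kg * scenario.body_weight_kg, mol.mw_kda)
        res = simulate(scenario, mol_name, t_eval=t_eval, rtol=rtol, dose_nmol=dose_nmol)
        for organ in organs:
            for label in label_types:
                spec = ObservableSpec(organ=organ, label_type=label, times=tuple(times))
                clean = observe_tissue(res, spec)
                noise = _lognormal_factors(rng, cv, (len(times), n_replicates))
                for i, t in enumerate(times):
                    for r in range(n_replicates):
                        rows.append(
                            {
                                "molecule": mol_name,
                                "organ": organ,
                                "label_type": label,
                                "time_h": t,
                                "replicate": r,
                                "value": clean[i] * noise[i, r],
                                "unit": "percent_id_per_g",
                            }
                        )
    data = pd.DataFrame(rows)
    return SyntheticDataset(
        data=data,
        true_params=_snapshot_params(scenario),
        design={
            "molecules": tuple(molecules),
            "organs": tuple(organs),
            "times": tuple(times),
            "label_types": tuple(label_types),
            "dose_mg_per_kg": dose_mg_per_kg,
        },
        seed=seed,
        cv=cv,
        n_replicates=n_replicates,
    )


def generate_synthetic_tcell_kinetics(
    scenario: ScenarioConfig,
    tcell_params: TCellParams | None = None,
    n_cells: float = 1.0e7,
    organs=("blood", "lung", "spleen", "liver", "kidney"),
    times=(1.0, 4.0, 24.0, 48.0, 96.0, 168.0),
    cv: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
) -> SyntheticDataset:
    """Adoptive-transfer time courses of activated T-cells with noise.

    Organ values are total cell content (vascular + interstitial); the blood
    row is the central pool.
    """
    params = tcell_params or (scenario.tcells or TCellParams())
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(times, dtype=float)
    counts, layout = simulate_adoptive_transfer(
        scenario.organs, params, n_cells, t_grid, phenotype="activated"
    )
    rows = []
    for organ in organs:
        if organ == "blood":
            clean = counts[:, 0]
        else:
            clean = counts[:, layout.vascular(organ)] + counts[:, layout.interstitial(organ)]
        noise = _lognormal_factors(rng, cv, (len(times), n_replicates))
        for i, t in enumerate(times):
            for r in range(n_replicates):
                rows.append(
                    {
                        "molecule": "tcells",
                        "organ": organ,
                        "label_type": "cells",
                        "time_h": t,
                        "replicate": r,
                        "value": clean[i] * noise[i, r],
                        "unit": "cells",
                    }
                )
    return SyntheticDataset(
        data=pd.DataFrame(rows),
        true_params={
            "tcells.spleen.k_transmigration": params.k_transmigration["spleen"],
            "tcells.spleen.retention_factor": params.retention_factor["spleen"],
            "tcells.k_elim_lung": params.k_elim_lung,
        },
        design={"organs": tuple(organs), "times": tuple(times), "n_cells": n_cells},
        seed=seed,
        cv=cv,
        n_replicates=n_replicates,
    )


def _snapshot_params(scenario: ScenarioConfig) -> dict:
    from .synapse import ReceptorParams

    receptors = scenario.receptors or ReceptorParams()
    tcells = scenario.tcells or TCellParams()
    snap = {
        "fcrn.kd": scenario.molecules[0].kd_FcRn,
        "receptors.k_int_dimer": receptors.k_int_dimer,
        "receptors.k_deg_HER2": receptors.k_deg_HER2,
        "tcells.spleen.k_transmigration": tcells.k_transmigration["spleen"],
        "tcells.spleen.retention_factor": tcells.retention_factor["spleen"],
        "tcells.k_elim_lung": tcells.k_elim_lung,
    }
    for m in scenario.molecules:
        if m.has_CD3_arm:
            snap[f"molecule.{m.name}.koff_CD3"] = m.koff_CD3
        if m.has_target_arm:
            snap[f"molecule.{m.name}.koff_HER2"] = m.koff_HER2
    return snap
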