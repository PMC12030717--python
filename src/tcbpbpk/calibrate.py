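"""Staged parameter calibration against (synthetic) biodistribution data.

The study's calibration proceeds in three stages, each freezing the
estimates of the stages before it:

1. ``tcell`` — organ T-cell transmigration and retention (plus lung
   elimination) against adoptive-transfer kinetics of activated T-cells;
   the lymph node is tied to the spleen (its own data are not informative
   for a lumped node).
2. ``gd_and_gdcd3`` — systemic disposition (FcRn affinity) and CD3-arm
   parameters against the gD control antibody and a CD3 one-armed variant,
   using both radiolabels.
3. ``her2cd3`` — HER2-arm parameters against a HER2-targeting bispecific,
   with all earlier estimates frozen.

Objectives are unweighted least squares on log observables (signals span
decades).  Optimization is a Levenberg-Marquardt local search in
log-parameter space with seeded multi-start, mirroring a manual-plus-
gradient workflow in an automated, reproducible form.  Parameters whose
profile changes the objective by less than 10% over a 10-fold range are
flagged non-identifiable rather than reported as estimates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from .engine import simulate
from .observables import ObservableSpec, SyntheticDataset, observe_tissue
from .physiology import ScenarioConfig
from .synapse import ReceptorParams
from .tcells import TCellParams, simulate_adoptive_transfer
from .units import mass_mg_to_nmol

STAGE_ORDER = ("tcell", "gd_and_gdcd3", "her2cd3")

_LOG_FLOOR = 1e-9

_PARAM_UNITS = {
    "kd": "nM",
    "koff_CD3": "1/h",
    "koff_HER2": "1/h",
    "retention_factor": "dimensionless",
    "k_transmigration": "1/h",
    "k_elim_lung": "1/h",
    "k_int_dimer": "1/h",
    "k_deg_HER2": "1/h",
}


# ---------------------------------------------------------------------------
# Parameter addressing
# ---------------------------------------------------------------------------


def _ensure_params(scenario: ScenarioConfig) -> ScenarioConfig:
    if scenario.receptors is None:
        scenario.receptors = ReceptorParams()
    if scenario.tcells is None:
        scenario.tcells = TCellParams()
    return scenario


def get_param(scenario: ScenarioConfig, name: str) -> float:
    _ensure_params(scenario)
    parts = name.split(".")
    if parts[0] == "fcrn" and parts[1] == "kd":
        return scenario.molecules[0].kd_FcRn
    if parts[0] == "receptors":
        if not hasattr(scenario.receptors, parts[1]):
            raise KeyError(f"unknown parameter {name!r}")
        return getattr(scenario.receptors, parts[1])
    if parts[0] == "tcells":
        if len(parts) == 2:
            return getattr(scenario.tcells, parts[1])
        organ, fname = parts[1], parts[2]
        return getattr(scenario.tcells, fname)[organ]
    if parts[0] == "molecule":
        return getattr(scenario.molecule(parts[1]), parts[2])
    raise KeyError(f"unknown parameter {name!r}")


def set_param(scenario: ScenarioConfig, name: str, value: float) -> None:
    _ensure_params(scenario)
    parts = name.split(".")
    if parts[0] == "fcrn" and parts[1] == "kd":
        for m in scenario.molecules:
            m.kd_FcRn = value
        return
    if parts[0] == "receptors":
        setattr(scenario.receptors, parts[1], value)
        return
    if parts[0] == "tcells":
        if len(parts) == 2:
            setattr(scenario.tcells, parts[1], value)
            return
        organ, fname = parts[1], parts[2]
        getattr(scenario.tcells, fname)[organ] = value
        # lymph-node trafficking is tied to the spleen (lumped-node choice)
        if organ == "spleen":
            getattr(scenario.tcells, fname)["lymph_node"] = value
        return
    if parts[0] == "molecule":
        setattr(scenario.molecule(parts[1]), parts[2], value)
        return
    raise KeyError(f"unknown parameter {name!r}")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


@dataclass
class CalibrationStage:
    """One calibration stage: free parameters (log-transformed, bounded),
    the molecules whose data it uses, and its objective settings."""

    stage_id: str
    free_params: list
    molecules: tuple
    bounds: dict = field(default_factory=dict)  # name -> (lo, hi), linear scale
    rtol: float = 1e-6

    def __post_init__(self):
        if self.stage_id not in STAGE_ORDER:
            raise ValueError(f"unknown stage {self.stage_id!r}; order is {STAGE_ORDER}")


def make_default_stages() -> list[CalibrationStage]:
    return [
        CalibrationStage(
            stage_id="tcell",
            free_params=[
                "tcells.spleen.k_transmigration",
                "tcells.spleen.retention_factor",
                "tcells.k_elim_lung",
            ],
            molecules=("tcells",),
            bounds={
                "tcells.spleen.k_transmigration": (0.1, 200.0),
                "tcells.spleen.retention_factor": (1.0, 500.0),
                "tcells.k_elim_lung": (1e-4, 1.0),
            },
        ),
        CalibrationStage(
            stage_id="gd_and_gdcd3",
            free_params=["fcrn.kd", "receptors.k_int_dimer", "molecule.gD-CD3H.koff_CD3"],
            molecules=("gD", "gD-CD3H"),
            bounds={
                "fcrn.kd": (10.0, 1e5),
                "receptors.k_int_dimer": (1e-4, 1.0),
                "molecule.gD-CD3H.koff_CD3": (1e-4, 100.0),
            },
        ),
        CalibrationStage(
            stage_id="her2cd3",
            free_params=["receptors.k_deg_HER2", "molecule.HER2-CD3L.koff_HER2"],
            molecules=("HER2-CD3L",),
            bounds={
                "receptors.k_deg_HER2": (1e-4, 1.0),
                "molecule.HER2-CD3L.koff_HER2": (1e-2, 1000.0),
            },
        ),
    ]


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def _predict_rows(scenario: ScenarioConfig, stage: CalibrationStage, design_rows: pd.DataFrame):
    """Predicted observable for each dataset row (grouped per molecule to
    share one simulation)."""
    pred = np.empty(len(design_rows))
    if stage.stage_id == "tcell":
        times = np.sort(design_rows["time_h"].unique())
        n_cells = design_rows.attrs.get("n_cells", 1.0e7)
        counts, layout = simulate_adoptive_transfer(
            scenario.organs, scenario.tcells, n_cells, times, phenotype="activated"
        )
        lookup = {}
        for organ in design_rows["organ"].unique():
            if organ == "blood":
                series = counts[:, 0]
            else:
                series = counts[:, layout.vascular(organ)] + counts[:, layout.interstitial(organ)]
            lookup[organ] = dict(zip(times, series))
        for k, (_, row) in enumerate(design_rows.iterrows()):
            pred[k] = lookup[row["organ"]][row["time_h"]]
        return pred

    dose_mg_per_kg = design_rows.attrs.get("dose_mg_per_kg", 0.5)
    t_max = design_rows["time_h"].max()
    t_eval = np.unique(np.concatenate([[0.0], np.geomspace(1e-3, t_max * 1.05, 100)]))
    for mol_name, grp in design_rows.groupby("molecule"):
        mol = scenario.molecule(mol_name)
        dose_nmol = mass_mg_to_nmol(dose_mg_per_kg * scenario.body_weight_kg, mol.mw_kda)
        res = simulate(
            scenario, mol_name, t_eval=t_eval, rtol=stage.rtol, dose_nmol=dose_nmol
        )
        for (organ, label), sub in grp.groupby(["organ", "label_type"]):
            times = tuple(sub["time_h"].to_numpy())
            values = observe_tissue(res, ObservableSpec(organ=organ, label_type=label, times=times))
            pred[np.asarray(sub.index_pos, dtype=int)] = values
    return pred


@dataclass
class FitResult:
    stage_id: str
    estimates: dict
    standard_errors: dict  # approximate relative SEs from the Jacobian
    cost: float
    converged: bool
    n_starts: int
    non_identifiable: list = field(default_factory=list)
    flags: list = field(default_factory=list)
    residual_rms: float = 0.0


def _stage_design(stage: CalibrationStage, dataset: SyntheticDataset) -> pd.DataFrame:
    rows = dataset.data[dataset.data["molecule"].isin(stage.molecules)].reset_index(drop=True)
    if rows.empty:
        raise ValueError(f"dataset contains no rows for stage {stage.stage_id!r}")
    rows["index_pos"] = np.arange(len(rows))
    rows.attrs["dose_mg_per_kg"] = dataset.design.get("dose_mg_per_kg", 0.5)
    rows.attrs["n_cells"] = dataset.design.get("n_cells", 1.0e7)
    return rows


def fit_stage(
    stage: CalibrationStage,
    dataset: SyntheticDataset,
    scenario: ScenarioConfig,
    n_starts: int = 8,
    seed: int = 0,
    max_nfev: int = 40,
    perturb_start: float = 3.0,
) -> FitResult:
    """Weighted least squares on log observables, Levenberg-Marquardt in
    log-parameter space with seeded multi-start.

    The first start is the scenario's current parameter values; the
    remaining starts perturb each parameter log-uniformly within a factor
    ``perturb_start``.  Non-convergence in every start is reported with the
    best incumbent and a flag rather than raised.
    """
    scenario = _ensure_params(copy.deepcopy(scenario))
    design = _stage_design(stage, dataset)
    obs_log = np.log(design["value"].to_numpy() + _LOG_FLOOR)
    names = list(stage.free_params)
    x_current = np.log([get_param(scenario, n) for n in names])
    lo = np.log([stage.bounds.get(n, (1e-12, 1e12))[0] for n in names])
    hi = np.log([stage.bounds.get(n, (1e-12, 1e12))[1] for n in names])

    def residuals(x):
        xc = np.clip(x, lo, hi)
        for n, v in zip(names, np.exp(xc)):
            set_param(scenario, n, v)
        pred = _predict_rows(scenario, stage, design)
        r = np.log(np.maximum(pred, 0.0) + _LOG_FLOOR) - obs_log
        # soft penalty keeps LM (which has no bound support) inside bounds
        return np.concatenate([r, 10.0 * (x - xc)])

    rng = np.random.default_rng(seed)
    starts = [x_current]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.clip(
                x_current + rng.uniform(-np.log(perturb_start), np.log(perturb_start), len(names)),
                lo,
                hi,
            )
        )

    best = None
    n_converged = 0
    for x0 in starts:
        try:
            sol = scipy.optimize.least_squares(
                residuals, x0, method="lm", max_nfev=max_nfev * (len(names) + 1)
            )
        except Exception:  # pragma: no cover - solver edge failures
            continue
        if sol.success:
            n_converged += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"stage {stage.stage_id}: all optimizer starts failed")

    x_hat = np.clip(best.x, lo, hi)
    estimates = {n: float(v) for n, v in zip(names, np.exp(x_hat))}
    dof = max(len(obs_log) - len(names), 1)
    s2 = 2.0 * best.cost / dof
    try:
        jtj = best.jac.T @ best.jac
        cov = np.linalg.inv(jtj) * s2
        se = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    except np.linalg.LinAlgError:
        se = {n: float("nan") for n in names}

    flags = [] if n_converged else ["no-start-converged"]
    non_ident = _profile_flatness(stage, design, scenario, estimates, best.cost)
    return FitResult(
        stage_id=stage.stage_id,
        estimates=estimates,
        standard_errors=se,
        cost=float(best.cost),
        converged=n_converged > 0,
        n_starts=len(starts),
        non_identifiable=non_ident,
        flags=flags,
        residual_rms=float(np.sqrt(2.0 * best.cost / len(obs_log))),
    )


def _profile_flatness(stage, design, scenario, estimates, cost_hat, threshold=0.10):
    """Parameters whose objective changes by less than ``threshold`` over a
    10-fold range around the estimate are flagged non-identifiable."""
    obs_log = np.log(design["value"].to_numpy() + _LOG_FLOOR)

    def cost_at(**overrides):
        sc = copy.deepcopy(scenario)
        for n, v in estimates.items():
            set_param(sc, n, v)
        for n, v in overrides.items():
            set_param(sc, n, v)
        pred = _predict_rows(sc, stage, design)
        r = np.log(np.maximum(pred, 0.0) + _LOG_FLOOR) - obs_log
        return 0.5 * float(r @ r)

    base = max(cost_hat, 1e-12)
    flat = []
    for name in estimates:
        changes = []
        for factor in (10.0 ** -0.5, 10.0 ** 0.5):
            c = cost_at(**{name: estimates[name] * factor})
            changes.append(abs(c - base) / base)
        if max(changes) < threshold:
            flat.append(name)
    return flat


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    stage_results: dict
    record: pd.DataFrame
    scenario: ScenarioConfig  # scenario with calibrated values applied
    completed_stages: list


def run_calibration_pipeline(
    scenario: ScenarioConfig,
    datasets: dict,
    stages: list[CalibrationStage] | None = None,
    n_starts: int = 8,
    seed: int = 0,
    perturb_start: float = 3.0,
) -> PipelineResult:
    """Run the three calibration stages in order, freezing earlier-stage
    estimates before each later stage.

    ``datasets`` maps stage id to a :class:`SyntheticDataset`.  A stage
    list given in the wrong order is rejected; a missing dataset halts the
    pipeline at that stage with a partial record.
    """
    stages = stages if stages is not None else make_default_stages()
    ids = [s.stage_id for s in stages]
    expected = [s for s in STAGE_ORDER if s in ids]
    if ids != expected:
        raise ValueError(f"stages must run in order {STAGE_ORDER}; got {ids}")

    working = _ensure_params(copy.deepcopy(scenario))
    stage_results: dict = {}
    rows = []
    completed = []
    for k, stage in enumerate(stages):
        if stage.stage_id not in datasets:
            break
        fit = fit_stage(
            stage,
            datasets[stage.stage_id],
            working,
            n_starts=n_starts,
            seed=seed + k,
            perturb_start=perturb_start,
        )
        stage_results[stage.stage_id] = fit
        for name, value in fit.estimates.items():
            set_param(working, name, value)  # freeze for later stages
            rows.append(
                {
                    "name": name,
                    "value": value,
                    "unit": _PARAM_UNITS.get(name.split(".")[-1], "1/h"),
                    "stage": stage.stage_id,
                    "provenance": "calibrated"
                    + ("; non-identifiable" if name in fit.non_identifiable else ""),
                    "lower_bound": stage.bounds.get(name, (np.nan, np.nan))[0],
                    "upper_bound": stage.bounds.get(name, (np.nan, np.nan))[1],
                    "rel_se_log": fit.standard_errors.get(name, np.nan),
                }
            )
        completed.append(stage.stage_id)
    return PipelineResult(
        stage_results=stage_results,
        record=pd.DataFrame(rows),
        scenario=working,
        completed_stages=completed,
    )
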