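"""Kinetic multi-state whole-body T-cell distribution.

Each tissue organ holds a vascular and an interstitial T-cell pool.  The
vascular pool exchanges with a central blood pool by plasma-flow-proportional
convection; cells transmigrate into the interstitium at an organ-specific
first-order rate and egress back at a global base rate divided by an
organ-specific retention factor.  Egress is routed through the lumped lymph
node (physiological lymphatic return) before re-entering blood; the lymph
node's own interstitial pool egresses directly to blood.  Elimination of
exogenously administered activated cells occurs in the lung interstitial
space only.  No proliferation terms are included (short time scales).

Activated cells transmigrate tenfold faster than naive cells with identical
retention factors; resting (endogenous) cells use a migration rate ten times
lower than the activated (calibrated) value.  The whole system is linear in
the cell counts, which the steady-state and oracle checks exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .physiology import BLOOD_COMPARTMENTS, TISSUE_ORGANS

#: activated vs naive transmigration multiplier (exact)
ACTIVATION_MULTIPLIER = 10.0
#: resting vs activated (calibrated) transmigration multiplier
RESTING_MULTIPLIER = 0.1

# (k_transmigration 1/h for activated cells, retention factor >= 1);
# spleen values calibrated against exogenous activated T-cell kinetics,
# lymph node tied to spleen, remaining organs literature-informed defaults
DEFAULT_TCELL_TABLE: dict[str, tuple[float, float]] = {
    "lung": (2.0, 3.0),
    "heart": (0.3, 2.0),
    "spleen": (15.0, 20.0),
    "lymph_node": (15.0, 20.0),
    "liver": (1.0, 3.0),
    "kidney": (0.5, 2.0),
    "gut": (1.0, 5.0),
    "muscle": (0.2, 2.0),
    "skin": (0.3, 3.0),
    "bone": (1.0, 5.0),
    "tumor": (1.5, 10.0),
    "rest_of_body": (0.3, 2.0),
}


@dataclass
class TCellParams:
    """Trafficking rates: two organ-specific parameters (transmigration and
    retention), a global egress base rate, and lung-interstitial elimination.
    """

    k_transmigration: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_TCELL_TABLE.items()}
    )
    retention_factor: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in DEFAULT_TCELL_TABLE.items()}
    )
    k_egress_base: float = 0.3  # 1/h
    k_elim_lung: float = 0.03  # 1/h, applied to lung interstitial pool only
    activation_multiplier: float = ACTIVATION_MULTIPLIER
    resting_multiplier: float = RESTING_MULTIPLIER
    total_resting_cells: float = 2.0e8  # whole-body endogenous T-cell count
    tumor_transmigration_multiplier: float = 1.0  # E-T ratio sweep knob

    def validate(self) -> None:
        for organ, k in self.k_transmigration.items():
            if k < 0:
                raise ValueError(f"{organ}: k_transmigration must be >= 0")
        for organ, rf in self.retention_factor.items():
            if rf < 1.0:
                raise ValueError(f"{organ}: retention_factor must be >= 1")
        if self.k_egress_base < 0 or self.k_elim_lung < 0:
            raise ValueError("rates must be >= 0")
        if self.activation_multiplier != ACTIVATION_MULTIPLIER:
            raise ValueError("activated:naive transmigration ratio is fixed at 10")

    def phenotype_scale(self, phenotype: str) -> float:
        if phenotype == "activated":
            return 1.0
        if phenotype == "resting":
            return self.resting_multiplier
        if phenotype == "naive":
            return 1.0 / self.activation_multiplier
        raise ValueError(f"unknown phenotype {phenotype!r}")


class TCellLayout:
    """State indexing: blood pool first, then (vascular, interstitial) per
    tissue organ in body order."""

    def __init__(self, organ_names):
        self.organs = [n for n in organ_names if n not in BLOOD_COMPARTMENTS]
        self.index = {"blood": 0}
        i = 1
        for name in self.organs:
            self.index[(name, "vascular")] = i
            self.index[(name, "interstitial")] = i + 1
            i += 2
        self.n = i

    def vascular(self, organ):
        return self.index[(organ, "vascular")]

    def interstitial(self, organ):
        return self.index[(organ, "interstitial")]


def rate_matrix(
    organs,
    params: TCellParams,
    phenotype: str = "activated",
    with_elimination: bool = True,
) -> tuple[np.ndarray, TCellLayout]:
    """Linear trafficking generator A with dN/dt = A @ N.

    Columns are source states; off-diagonal entries are transfer rates,
    diagonals their negated sums (minus lung elimination).  Without
    elimination A is a proper rate matrix (columns sum to zero), so total
    cell count is conserved.
    """
    params.validate()
    by_name = {o.name: o for o in organs}
    layout = TCellLayout([o.name for o in organs])
    blood_volume = sum(by_name[b].total_volume for b in BLOOD_COMPARTMENTS if b in by_name)
    if blood_volume <= 0:
        raise ValueError("body must include blood compartments")
    scale = params.phenotype_scale(phenotype)

    a = np.zeros((layout.n, layout.n))
    i_blood = 0
    has_ln = "lymph_node" in layout.organs

    def add(src, dst, rate):
        a[dst, src] += rate
        a[src, src] -= rate

    for name in layout.organs:
        organ = by_name[name]
        iv, ii = layout.vascular(name), layout.interstitial(name)
        v_vasc = organ.vascular_volume
        # flow exchange with the central blood pool
        add(i_blood, iv, organ.plasma_flow / blood_volume)
        add(iv, i_blood, organ.plasma_flow / max(v_vasc, 1e-12))
        # transmigration (organ-specific, phenotype-scaled)
        k_tm = params.k_transmigration.get(name, 0.0) * scale
        if name == "tumor":
            k_tm *= params.tumor_transmigration_multiplier
        add(iv, ii, k_tm)
        # egress: base rate divided by retention, routed through lymph node
        k_eg = params.k_egress_base / params.retention_factor.get(name, 1.0)
        if name != "lymph_node" and has_ln:
            add(ii, layout.interstitial("lymph_node"), k_eg)
        else:
            add(ii, i_blood, k_eg)
        if name == "lung" and with_elimination and params.k_elim_lung > 0:
            a[ii, ii] -= params.k_elim_lung
    return a, layout


def tcell_fluxes(state: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Derivative contributions dN/dt for a state vector under generator A."""
    return a @ state


def steady_state_tcell_distribution(
    organs, params: TCellParams, phenotype: str = "resting"
) -> tuple[np.ndarray, TCellLayout]:
    """Quasi-steady distribution of a fixed total cell count (elimination
    off): the null space of the trafficking generator, normalized to
    ``total_resting_cells``.  Raises if all rates are zero (no unique
    distribution)."""
    a, layout = rate_matrix(organs, params, phenotype=phenotype, with_elimination=False)
    if not np.any(a):
        raise ValueError("all trafficking rates are zero: no unique distribution")
    ns = scipy.linalg.null_space(a)
    if ns.shape[1] != 1:
        # disconnected pools: pick the stationary vector reached from blood
        # by long-time integration instead
        x0 = np.zeros(layout.n)
        x0[0] = 1.0
        x = scipy.linalg.expm(a * 1e7) @ x0
    else:
        x = ns[:, 0]
    x = np.abs(x)
    x = x / x.sum() * params.total_resting_cells
    return x, layout


def organ_fraction_table(organs, params: TCellParams, phenotype: str = "resting"):
    """Fraction of all cells per organ and sub-compartment (tidy DataFrame)."""
    import pandas as pd

    x, layout = steady_state_tcell_distribution(organs, params, phenotype)
    total = x.sum()
    rows = [{"organ": "blood", "subcompartment": "vascular", "fraction": x[0] / total}]
    for name in layout.organs:
        rows.append(
            {
                "organ": name,
                "subcompartment": "vascular",
                "fraction": x[layout.vascular(name)] / total,
            }
        )
        rows.append(
            {
                "organ": name,
                "subcompartment": "interstitial",
                "fraction": x[layout.interstitial(name)] / total,
            }
        )
    return pd.DataFrame(rows)


def simulate_adoptive_transfer(
    organs,
    params: TCellParams,
    n_cells: float,
    t_grid: np.ndarray,
    phenotype: str = "activated",
) -> tuple[np.ndarray, TCellLayout]:
    """IV bolus of ``n_cells`` into blood; returns counts (time x state).

    The system is linear time-invariant, so the solution is a matrix
    exponential propagated between output times (exact to machine precision,
    no ODE-solver tolerance involved).
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    a, layout = rate_matrix(organs, params, phenotype=phenotype, with_elimination=True)
    x = np.zeros(layout.n)
    x[0] = n_cells
    out = np.empty((len(t_grid), layout.n))
    t_prev = 0.0
    propagators: dict[float, np.ndarray] = {}
    for k, t in enumerate(t_grid):
        dt = t - t_prev
        if dt < 0:
            raise ValueError("t_grid must be non-decreasing")
        if dt > 0:
            if dt not in propagators:
                propagators[dt] = scipy.linalg.expm(a * dt)
            x = propagators[dt] @ x
        out[k] = x
        t_prev = t
    return out, layout
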