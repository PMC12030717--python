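"""Receptor turnover and the CD3/HER2 mass-action binding network.

Species per sub-compartment: free antibody, membrane and internalized CD3,
the CD3 dimer complex, and — in the tumor interstitium only — free HER2,
the HER2 dimer complex and the trimeric CD3-antibody-HER2 immune synapse.

Network (all mass action):

    TCB + CD3      <->  TCB.CD3        (kon_CD3, koff_CD3)
    TCB + HER2     <->  TCB.HER2       (kon_HER2, koff_HER2)
    TCB.CD3 + HER2 <->  Synapse        (kon_HER2, koff_HER2 * avidity)
    TCB.HER2 + CD3 <->  Synapse        (kon_CD3, koff_CD3 * avidity)

The avidity factor (0.01, i.e. 100-fold avidity) multiplies both
second-step dissociation rates, so the equilibrium constant product around
the thermodynamic cycle is path-independent and synapse dissociation is
effectively negligible at default parameters.

CD3 recycles between membrane and internal pools with k_int = 0.5 * k_rec,
pinning the membrane:internal steady state at exactly 2:1.  The local CD3
pool capacity scales linearly with the local T-cell count (synthesis
proportional to cells, first-order decay); complexes do not co-migrate with
cells between compartments.  HER2 synthesis is zero order and free and
bound HER2 degrade at identical first-order rates.  Synapse internalization
(trogocytosis: the target-cell receptor is stripped and consumed, CD3 is
recycled to the internal pool, antibody is catabolized) runs at exactly 1/3
of the dimer internalization rate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .units import cells_receptors_to_nmol

#: synapse internalization relative to dimer-complex internalization (exact)
SYNAPSE_INTERNALIZATION_RATIO = 1.0 / 3.0

#: membrane CD3 internalization relative to recycling (exact; pins the
#: membrane:internal steady state at 2:1)
CD3_INT_TO_REC_RATIO = 0.5


@dataclass
class ReceptorParams:
    """CD3 and HER2 pool sizes and turnover rates.

    Derived quantities (``k_int_CD3``, ``k_int_synapse``,
    ``k_elim_HER2complex``, ``k_syn_HER2``) are properties so the structural
    constraints hold for any parameter set by construction.
    """

    receptors_per_tcell: float = 1.0e5
    k_rec_CD3: float = 0.5  # 1/h, internal -> membrane
    k_deg_CD3: float = 0.006  # 1/h, pool turnover tracking local T-cell count
    k_int_dimer: float = 0.02  # 1/h, TCB.CD3 complex internalization
    tumor_cells: float = 2.4e7  # target-cell burden of the 240 mg tumor
    receptors_per_tumor_cell: float = 4.0e4
    k_deg_HER2: float = 0.01  # 1/h, free and bound HER2 alike

    @property
    def k_int_CD3(self) -> float:
        """Membrane CD3 internalization rate; 0.5 * k_rec_CD3 exactly."""
        return CD3_INT_TO_REC_RATIO * self.k_rec_CD3

    @property
    def k_int_synapse(self) -> float:
        """Synapse internalization; slower than dimer internalization by 1/3."""
        return self.k_int_dimer / 3.0

    @property
    def k_elim_HER2complex(self) -> float:
        """HER2 dimer elimination equals free-HER2 degradation."""
        return self.k_deg_HER2

    @property
    def her2_total_nmol(self) -> float:
        """Baseline (pre-dose) total HER2 amount in the tumor interstitium."""
        return cells_receptors_to_nmol(self.tumor_cells, self.receptors_per_tumor_cell)

    @property
    def k_syn_HER2(self) -> float:
        """Zero-order HER2 synthesis (nmol/h) balancing degradation at the
        baseline pool size."""
        return self.k_deg_HER2 * self.her2_total_nmol

    def validate(self) -> None:
        for name in (
            "receptors_per_tcell",
            "k_rec_CD3",
            "k_deg_CD3",
            "k_int_dimer",
            "tumor_cells",
            "receptors_per_tumor_cell",
            "k_deg_HER2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def cd3_pool_size(n_tcells_local: float, receptors_per_tcell: float) -> float:
    """Total CD3 amount (nmol) carried by a local T-cell population."""
    if n_tcells_local < 0 or receptors_per_tcell < 0:
        raise ValueError("counts must be >= 0")
    return cells_receptors_to_nmol(n_tcells_local, receptors_per_tcell)


def cd3_recycling_fluxes(
    cd3_mem: float, cd3_int: float, params: ReceptorParams
) -> tuple[float, float]:
    """(d_mem, d_int) from membrane/internal recycling only.

    Steady state of the closed two-pool system: mem/int = k_rec/k_int = 2.
    """
    j = params.k_rec_CD3 * cd3_int - params.k_int_CD3 * cd3_mem
    return j, -j


def binding_fluxes(
    *,
    tcb_free: float,
    cd3_mem: float,
    her2_free: float,
    tcb_cd3: float,
    tcb_her2: float,
    synapse: float,
    volume_mL: float,
    kon_CD3: float,
    koff_CD3: float,
    kon_HER2: float,
    koff_HER2: float,
    avidity_factor: float,
) -> dict[str, float]:
    """Net derivative contributions (nmol/h) of the four reversible binding
    reactions in one well-mixed sub-compartment.

    Amount-based bimolecular rates: ``kon * A * B / V`` with ``kon`` in
    mL/(nmol h) (i.e. the nM-based constant times 1000).  HER2 reactions are
    active only where HER2 exists (tumor interstitium).
    """
    if volume_mL <= 0:
        raise ValueError("volume must be positive")
    r1 = kon_CD3 * tcb_free * cd3_mem / volume_mL - koff_CD3 * tcb_cd3
    r2 = kon_HER2 * tcb_free * her2_free / volume_mL - koff_HER2 * tcb_her2
    r3 = (
        kon_HER2 * tcb_cd3 * her2_free / volume_mL
        - koff_HER2 * avidity_factor * synapse
    )
    r4 = (
        kon_CD3 * tcb_her2 * cd3_mem / volume_mL
        - koff_CD3 * avidity_factor * synapse
    )
    return {
        "tcb_free": -r1 - r2,
        "cd3_mem": -r1 - r4,
        "her2_free": -r2 - r3,
        "tcb_cd3": r1 - r3,
        "tcb_her2": r2 - r4,
        "synapse": r3 + r4,
    }


def internalization_fluxes(
    *,
    tcb_cd3: float,
    tcb_her2: float,
    synapse: float,
    params: ReceptorParams,
) -> dict[str, float]:
    """Complex elimination: dimer internalization, HER2-complex degradation,
    and trogocytotic synapse internalization.

    Routing: internalized antibody feeds the cumulative catabolized-label
    pool; the receptors carried by an eliminated complex are consumed (the
    HER2 in a synapse is stripped from the target cell; internalized CD3 is
    degraded, its pool being restored by the T-cell-count-proportional
    synthesis).  This lets receptor pools deplete under sustained
    saturation, which shapes the synapse-versus-dose relationship.
    """
    j_dimer = params.k_int_dimer * tcb_cd3
    j_her2c = params.k_elim_HER2complex * tcb_her2
    j_syn = params.k_int_synapse * synapse
    return {
        "tcb_cd3": -j_dimer,
        "tcb_her2": -j_her2c,
        "synapse": -j_syn,
        "catabolized": j_dimer + j_her2c + j_syn,
    }


def her2_turnover_fluxes(her2_free: float, params: ReceptorParams) -> float:
    """d(HER2_free)/dt from zero-order synthesis and first-order
    degradation; baseline steady state is k_syn / k_deg."""
    return params.k_syn_HER2 - params.k_deg_HER2 * her2_free
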