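"""Mouse whole-body structure, molecule specifications and scenario I/O.

The body is a set of organs with vascular / interstitial / intracellular
sub-compartments connected by plasma and lymph flows.  Two compartments
(``venous_blood``, ``arterial_blood``) are purely vascular.  A tumor module
(fixed 240 mg burden, density 1 g/mL) and a single lumped lymph node
(4.04 mL per kg body weight, sub-compartment fractions 0.017 / 0.53 / 0.453)
extend the standard organ set.

Parameter provenance is tracked per organ row: values printed in the source
study are flagged ``printed-in-paper``; everything else is a documented
``literature-default`` drawn from standard mouse PBPK tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .units import DEFAULT_MW_KDA, UnitError, resolve_units

BLOOD_COMPARTMENTS = ("venous_blood", "arterial_blood")

#: organs with both vascular and interstitial sub-compartments
TISSUE_ORGANS = (
    "lung",
    "heart",
    "spleen",
    "lymph_node",
    "liver",
    "kidney",
    "gut",
    "muscle",
    "skin",
    "bone",
    "tumor",
    "rest_of_body",
)

LYMPH_NODE_FRACTIONS = (0.017, 0.53, 0.453)  # vascular, interstitial, intracellular
LYMPH_NODE_SPECIFIC_VOLUME = 4.04  # mL per kg body weight
TUMOR_VOLUME_ML = 0.24  # 240 mg at 1 g/mL


class ValidationError(ValueError):
    """Raised when a physiology table or scenario violates an invariant."""


@dataclass
class OrganPhysiology:
    """Per-organ geometry, flows, pore parameters and sampling corrections.

    Volumes in mL, flows in mL/h, pore radii in nm.  ``f_large_pore`` is the
    fraction of trans-capillary fluid (lymph) flow carried by the large-pore
    population.  ``residual_blood_fraction`` is the blood signal carried over
    into an excised tissue sample (dimensionless, on a per-gram basis).
    ``tcell_baseline`` is filled in by the engine with the resting T-cell
    content at homeostasis; it is informational, not an input.
    """

    name: str
    total_volume: float
    f_vascular: float
    f_interstitial: float
    f_intracellular: float
    plasma_flow: float
    lymph_flow: float
    large_pore_radius: float = 22.85
    small_pore_radius: float = 4.44
    f_large_pore: float = 0.3
    residual_blood_fraction: float = 0.0
    tcell_baseline: float = 0.0
    provenance: str = "literature-default"

    @property
    def vascular_volume(self) -> float:
        return self.total_volume * self.f_vascular

    @property
    def interstitial_volume(self) -> float:
        return self.total_volume * self.f_interstitial

    @property
    def mass_g(self) -> float:
        """Organ mass assuming tissue density 1 g/mL."""
        return self.total_volume

    def validate(self) -> None:
        n = self.name
        if self.total_volume <= 0:
            raise ValidationError(f"{n}: total_volume must be positive")
        fsum = self.f_vascular + self.f_interstitial + self.f_intracellular
        if fsum > 1 + 1e-9:
            raise ValidationError(
                f"{n}: sub-compartment fractions sum to {fsum:.6f} > 1"
            )
        for fname in ("f_vascular", "f_interstitial", "f_intracellular"):
            if getattr(self, fname) < 0:
                raise ValidationError(f"{n}: {fname} must be non-negative")
        if n in BLOOD_COMPARTMENTS:
            return
        if self.plasma_flow <= 0 or self.lymph_flow <= 0:
            raise ValidationError(f"{n}: flows must be strictly positive")
        if self.lymph_flow >= self.plasma_flow:
            raise ValidationError(f"{n}: lymph_flow must be < plasma_flow")
        if self.large_pore_radius <= 0 or self.small_pore_radius <= 0:
            raise ValidationError(f"{n}: pore radii must be positive")
        if not 0 < self.f_large_pore < 1:
            raise ValidationError(f"{n}: f_large_pore must be in (0, 1)")
        if not 0 <= self.residual_blood_fraction < 1:
            raise ValidationError(f"{n}: residual_blood_fraction must be in [0, 1)")


@dataclass
class MoleculeSpec:
    """Binding arms and disposition properties of one antibody variant.

    Rate constants: ``kon_*`` in 1/(nM·h), ``koff_*`` in 1/h.  The avidity
    factor multiplies the *second* binding step's dissociation rate (0.01,
    i.e. 100-fold avidity).  ``kd_FcRn`` is the endosomal-pH FcRn affinity in
    nM, which sets the recycled (salvaged) fraction of endosomal uptake.
    """

    name: str
    kon_CD3: float = 0.0
    koff_CD3: float = 0.0
    kon_HER2: float = 0.0
    koff_HER2: float = 0.0
    avidity_factor: float = 0.01
    kd_FcRn: float = 500.0
    hydrodynamic_radius: float = 5.34
    mw_kda: float = DEFAULT_MW_KDA

    @property
    def has_CD3_arm(self) -> bool:
        return self.kon_CD3 > 0

    @property
    def has_target_arm(self) -> bool:
        return self.kon_HER2 > 0

    def validate(self) -> None:
        if not 0 < self.avidity_factor <= 1:
            raise ValidationError(f"{self.name}: avidity_factor must be in (0, 1]")
        for fname in ("kon_CD3", "koff_CD3", "kon_HER2", "koff_HER2"):
            if getattr(self, fname) < 0:
                raise ValidationError(f"{self.name}: {fname} must be >= 0")
        if self.kd_FcRn <= 0 or self.hydrodynamic_radius <= 0 or self.mw_kda <= 0:
            raise ValidationError(
                f"{self.name}: kd_FcRn, hydrodynamic_radius and mw_kda must be positive"
            )


@dataclass
class DoseEvent:
    """An IV bolus into venous blood.

    ``amount``/``unit`` are resolved against the scenario body weight and
    the molecule's molecular weight; ``amount_nmol`` is the canonical value.
    """

    molecule: str
    time: float = 0.0
    amount: float = 0.0
    unit: str = "mg"
    route: str = "iv_bolus"
    compartment: str = "venous_blood"

    def resolved_nmol(self, body_weight_kg: float, mw_kda: float) -> float:
        value, unit = resolve_units(
            self.amount, self.unit, mw_kda=mw_kda, body_weight_kg=body_weight_kg
        )
        if unit != "nmol":
            raise UnitError(f"dose unit {self.unit!r} does not resolve to an amount")
        if value <= 0:
            raise ValidationError("dose amount must be positive")
        return value


@dataclass
class ScenarioConfig:
    """Physiology + molecules + doses + solver/output settings.

    The unit of reproducibility: a scenario fully determines a simulation
    (the forward model itself is deterministic; ``seed`` only feeds synthetic
    data generation).
    """

    organs: list[OrganPhysiology]
    molecules: list[MoleculeSpec]
    doses: list[DoseEvent]
    receptors: "object" = None  # ReceptorParams; default built at assembly
    tcells: "object" = None  # TCellParams
    body_weight_kg: float = 0.02
    hematocrit: float = 0.45
    fcrn_uptake_rate: float = 0.275  # 1/h, endosomal uptake from vascular pools
    t_end: float = 5000.0
    n_output: int = 400
    rtol: float = 1e-8
    seed: int = 0

    def organ(self, name: str) -> OrganPhysiology:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    def molecule(self, name: str) -> MoleculeSpec:
        for m in self.molecules:
            if m.name == name:
                return m
        raise KeyError(name)

    def validate(self) -> None:
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ValidationError("organ names must be unique")
        for o in self.organs:
            o.validate()
        for m in self.molecules:
            m.validate()
        mol_names = {m.name for m in self.molecules}
        for d in self.doses:
            if d.molecule not in mol_names:
                raise ValidationError(f"dose references unknown molecule {d.molecule!r}")
            if d.time < 0:
                raise ValidationError("dose time must be >= 0")
            d.resolved_nmol(self.body_weight_kg, self.molecule(d.molecule).mw_kda)
        if self.body_weight_kg <= 0:
            raise ValidationError("body weight must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValidationError("hematocrit must be in (0, 1)")
        if self.t_end <= 0:
            raise ValidationError("t_end must be positive")


# ---------------------------------------------------------------------------
# Default mouse body
# ---------------------------------------------------------------------------

# (volume mL, f_vascular, f_interstitial, plasma flow mL/h, lymph/plasma flow
# ratio, residual blood fraction) for a 20 g tumor-bearing mouse.  Flows and
# volumes are literature defaults from standard mouse PBPK tables; the lymph
# node and tumor rows carry the values printed in the source study.
_CARDIAC_OUTPUT_PLASMA = 330.0  # mL/h for the 20 g reference mouse

_DEFAULT_ORGAN_TABLE = {
    # name: (V, f_v, f_i, Q, L/Q, rbf)
    "lung": (0.17, 0.26, 0.19, _CARDIAC_OUTPUT_PLASMA, 0.0004, 0.17),
    "heart": (0.13, 0.05, 0.16, 28.0, 0.004, 0.06),
    "spleen": (0.10, 0.17, 0.20, 6.3, 0.004, 0.09),
    "lymph_node": (None, 0.017, 0.53, 3.0, 0.004, 0.05),
    "liver": (1.40, 0.11, 0.16, 60.0, 0.004, 0.06),
    "kidney": (0.42, 0.11, 0.20, 52.0, 0.004, 0.05),
    "gut": (2.00, 0.03, 0.28, 55.0, 0.004, 0.02),
    "muscle": (7.80, 0.026, 0.13, 65.0, 0.004, 0.01),
    "skin": (3.40, 0.02, 0.30, 21.0, 0.004, 0.02),
    "bone": (2.00, 0.04, 0.10, 12.0, 0.004, 0.04),
    "tumor": (TUMOR_VOLUME_ML, 0.07, 0.55, 2.4, 0.012, 0.03),
    "rest_of_body": (1.50, 0.04, 0.18, None, 0.004, 0.03),
}

_REFERENCE_BW_KG = 0.02


def build_default_mouse(body_weight_kg: float = 0.02) -> list[OrganPhysiology]:
    """Default organ set for a tumor-bearing mouse.

    The lymph node volume scales with body weight (4.04 mL/kg) and keeps the
    exact sub-compartment fractions 0.017 / 0.53 / 0.453; the tumor burden is
    fixed at 240 mg regardless of body weight.  All other organ sizes and
    flows scale linearly with body weight from the 20 g reference.  The
    rest-of-body plasma flow closes the cardiac-output balance exactly.
    """
    if body_weight_kg <= 0:
        raise ValidationError("body weight must be positive")
    scale = body_weight_kg / _REFERENCE_BW_KG
    co = _CARDIAC_OUTPUT_PLASMA * scale

    organs: list[OrganPhysiology] = [
        OrganPhysiology(
            name="venous_blood",
            total_volume=0.35 * scale,
            f_vascular=1.0,
            f_interstitial=0.0,
            f_intracellular=0.0,
            plasma_flow=co,
            lymph_flow=0.0,
        ),
        OrganPhysiology(
            name="arterial_blood",
            total_volume=0.17 * scale,
            f_vascular=1.0,
            f_interstitial=0.0,
            f_intracellular=0.0,
            plasma_flow=co,
            lymph_flow=0.0,
        ),
    ]

    lung_q = co
    lung_lymph = lung_q * _DEFAULT_ORGAN_TABLE["lung"][4]
    systemic_budget = co - lung_lymph

    fixed_q = sum(
        row[3] * scale
        for name, row in _DEFAULT_ORGAN_TABLE.items()
        if name not in ("lung", "rest_of_body") and row[3] is not None
    )
    rest_q = systemic_budget - fixed_q
    if rest_q <= 0:
        raise ValidationError("organ plasma flows exceed cardiac output")

    for name, (vol, f_v, f_i, q, l_ratio, rbf) in _DEFAULT_ORGAN_TABLE.items():
        if name == "lymph_node":
            vol = LYMPH_NODE_SPECIFIC_VOLUME * body_weight_kg
            f_v, f_i = LYMPH_NODE_FRACTIONS[0], LYMPH_NODE_FRACTIONS[1]
            f_ic = LYMPH_NODE_FRACTIONS[2]
            provenance = "printed-in-paper"
        elif name == "tumor":
            vol = TUMOR_VOLUME_ML  # fixed burden, not BW-scaled
            f_ic = max(0.0, 1.0 - f_v - f_i)
            provenance = "printed-in-paper"
        else:
            vol = vol * scale
            f_ic = max(0.0, 1.0 - f_v - f_i)
            provenance = "literature-default"
        if name == "lung":
            q_val = lung_q
        elif name == "rest_of_body":
            q_val = rest_q
        else:
            q_val = q * scale
        organs.append(
            OrganPhysiology(
                name=name,
                total_volume=vol,
                f_vascular=f_v,
                f_interstitial=f_i,
                f_intracellular=f_ic,
                plasma_flow=q_val,
                lymph_flow=q_val * l_ratio,
                residual_blood_fraction=rbf,
                provenance=provenance,
            )
        )

    for o in organs:
        o.validate()
    return organs


def default_molecules() -> list[MoleculeSpec]:
    """The six antibody variants studied: a non-binding control (gD), three
    CD3 one-armed variants of increasing CD3 affinity, and two HER2-targeting
    bispecifics sharing the low/high CD3 arms.

    CD3 arm dissociation constants (120, 0.15, 0.115 nM for L/H/VH) and the
    HER2 arm (10 nM, affinity-detuned as typical for HER2 T-cell engagers)
    are calibrated defaults: the actual arm affinities are not printed in
    the source study, so these were chosen, together with the receptor
    turnover defaults, to reproduce the reported blood-clearance ordering
    of the variants and the dose-proportional antibody exposure.
    """
    kon = 0.36  # 1/(nM h) == 1e5 1/(M s)
    return [
        MoleculeSpec(name="gD"),
        MoleculeSpec(name="gD-CD3L", kon_CD3=kon, koff_CD3=kon * 120.0),
        MoleculeSpec(name="gD-CD3H", kon_CD3=kon, koff_CD3=kon * 0.15),
        MoleculeSpec(name="gD-CD3VH", kon_CD3=kon, koff_CD3=kon * 0.115),
        MoleculeSpec(
            name="HER2-CD3L",
            kon_CD3=kon,
            koff_CD3=kon * 120.0,
            kon_HER2=kon,
            koff_HER2=kon * 10.0,
        ),
        MoleculeSpec(
            name="HER2-CD3H",
            kon_CD3=kon,
            koff_CD3=kon * 0.15,
            kon_HER2=kon,
            koff_HER2=kon * 10.0,
        ),
    ]


def default_scenario(
    body_weight_kg: float = 0.02,
    dose_mg_per_kg: float = 0.5,
    molecule: str = "HER2-CD3L",
    t_end: float = 5000.0,
) -> ScenarioConfig:
    """Reference scenario: default mouse, default molecules, one IV bolus."""
    config = ScenarioConfig(
        organs=build_default_mouse(body_weight_kg),
        molecules=default_molecules(),
        doses=[DoseEvent(molecule=molecule, time=0.0, amount=dose_mg_per_kg, unit="mg/kg")],
        body_weight_kg=body_weight_kg,
        t_end=t_end,
    )
    config.validate()
    return config


# ---------------------------------------------------------------------------
# Scenario CSV round trip
# ---------------------------------------------------------------------------

_ORGAN_COLUMNS = [f.name for f in dataclasses.fields(OrganPhysiology)]
_MOL_COLUMNS = [f.name for f in dataclasses.fields(MoleculeSpec)]
_DOSE_COLUMNS = [f.name for f in dataclasses.fields(DoseEvent)]
_SETTING_KEYS = (
    "body_weight_kg",
    "hematocrit",
    "fcrn_uptake_rate",
    "t_end",
    "n_output",
    "rtol",
    "seed",
)


def save_scenario(config: ScenarioConfig, directory: str | Path) -> Path:
    """Write a scenario as one CSV per concern (organs, molecules, doses,
    settings) under ``directory``.  UTF-8, '.' decimal, header row mandatory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(o) for o in config.organs]).to_csv(
        directory / "organs.csv", index=False, float_format=lambda x: repr(float(x))
    )
    pd.DataFrame([dataclasses.asdict(m) for m in config.molecules]).to_csv(
        directory / "molecules.csv", index=False, float_format=lambda x: repr(float(x))
    )
    pd.DataFrame([dataclasses.asdict(d) for d in config.doses]).to_csv(
        directory / "doses.csv", index=False, float_format=lambda x: repr(float(x))
    )
    settings = pd.DataFrame(
        {"key": _SETTING_KEYS, "value": [getattr(config, k) for k in _SETTING_KEYS]}
    )
    settings.to_csv(directory / "settings.csv", index=False, float_format=lambda x: repr(float(x)))
    return directory


def _check_columns(df: pd.DataFrame, expected: list[str], table: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValidationError(f"{table}: missing columns {missing}")
    unknown = [c for c in df.columns if c not in expected]
    if unknown:
        raise ValidationError(f"{table}: unknown columns {unknown} rejected")


def load_scenario(directory: str | Path) -> ScenarioConfig:
    """Load and fully validate a scenario saved by :func:`save_scenario`.

    Parse errors name the offending table, row and field.
    """
    directory = Path(directory)
    for fname in ("organs.csv", "molecules.csv", "doses.csv", "settings.csv"):
        if not (directory / fname).exists():
            raise ValidationError(f"scenario is missing {fname}")

    organs_df = pd.read_csv(directory / "organs.csv", float_precision="round_trip")
    _check_columns(organs_df, _ORGAN_COLUMNS, "organs.csv")
    organs = []
    for i, row in organs_df.iterrows():
        try:
            organ = OrganPhysiology(**{c: row[c] for c in _ORGAN_COLUMNS})
            organ.validate()
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"organs.csv row {i} ({row.get('name')}): {exc}") from exc
        organs.append(organ)

    mols_df = pd.read_csv(directory / "molecules.csv", float_precision="round_trip")
    _check_columns(mols_df, _MOL_COLUMNS, "molecules.csv")
    molecules = []
    for i, row in mols_df.iterrows():
        try:
            mol = MoleculeSpec(**{c: row[c] for c in _MOL_COLUMNS})
            mol.validate()
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(
                f"molecules.csv row {i} ({row.get('name')}): {exc}"
            ) from exc
        molecules.append(mol)

    doses_df = pd.read_csv(directory / "doses.csv", float_precision="round_trip")
    _check_columns(doses_df, _DOSE_COLUMNS, "doses.csv")
    doses = [DoseEvent(**{c: row[c] for c in _DOSE_COLUMNS}) for _, row in doses_df.iterrows()]

    settings_df = pd.read_csv(directory / "settings.csv", float_precision="round_trip")
    settings = dict(zip(settings_df["key"], settings_df["value"]))
    unknown_keys = set(settings) - set(_SETTING_KEYS)
    if unknown_keys:
        raise ValidationError(f"settings.csv: unknown keys {sorted(unknown_keys)} rejected")

    config = ScenarioConfig(
        organs=organs,
        molecules=molecules,
        doses=doses,
        body_weight_kg=float(settings["body_weight_kg"]),
        hematocrit=float(settings["hematocrit"]),
        fcrn_uptake_rate=float(settings["fcrn_uptake_rate"]),
        t_end=float(settings["t_end"]),
        n_output=int(float(settings["n_output"])),
        rtol=float(settings["rtol"]),
        seed=int(float(settings["seed"])),
    )
    config.validate()
    return config
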