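"""Compound, physiology and study-design parameter defaults.

The package ships the dapaconazole parameter set used throughout: physico-chemical
properties, dog and human physiologies, the measured microsomal IC50 panel, and the
victim-substrate library for the dynamic DDI co-simulation. Everything here is plain
data; all values are overridable at call sites or through the pipeline config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CompoundParams",
    "SpeciesPhysiology",
    "TissueComposition",
    "VictimSubstrate",
    "DAPACONAZOLE_DOG",
    "DAPACONAZOLE_HUMAN",
    "DOG_PHYSIOLOGY",
    "HUMAN_PHYSIOLOGY",
    "IC50_PANEL_UM",
    "FM_BY_ROW",
    "VICTIM_SUBSTRATES",
    "DOG_QUALIFICATION_REFERENCE",
    "DEFAULT_INHIBITOR_GRID_UM",
    "DYNAMIC_SUBSTRATE_BY_ROW",
    "DOG_CL_PREDICTED_ML_MIN",
    "REFERENCE_AUCR",
    "TISSUE_COMPOSITION",
    "BLOOD_CELL_COMPOSITION",
    "FU_PLASMA_STATIC",
    "CMAX_TOTAL_UM",
    "VSS_L_KG",
    "VSAC_L_KG",
    "KIN_PER_H",
    "KOUT_PER_H",
    "KP_SCALAR_BEST_FIT",
    "CL_DOG_IN_VIVO_ML_MIN",
    "CL_HUMAN_L_H",
    "PH_PLASMA",
    "PH_INTRACELLULAR",
    "PH_BLOOD_CELL",
    "with_fu",
]


@dataclass(frozen=True)
class CompoundParams:
    """Physico-chemical and binding parameters of the perpetrator drug.

    clint_mic is the microsomal intrinsic clearance in µL/min/mg protein;
    fu_inc the unbound fraction in the incubation.
    """

    molecular_weight: float  # g/mol
    log_p: float
    pka: float  # monoprotic base
    fu_plasma: float
    blood_plasma_ratio: float
    clint_mic: float
    fu_inc: float

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be positive")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must lie in (0, 1]")
        if not 0 < self.fu_inc <= 1:
            raise ValueError("fu_inc must lie in (0, 1]")


@dataclass(frozen=True)
class TissueComposition:
    """Fractional tissue composition used by the Rodgers-Rowland Kp equations.

    f_ew/f_iw: extracellular and intracellular water fractions; f_nl/f_np:
    neutral lipid and neutral phospholipid fractions; ap_mg_g: acidic
    phospholipid content (mg/g tissue).
    """

    f_ew: float
    f_iw: float
    f_nl: float
    f_np: float
    ap_mg_g: float


@dataclass(frozen=True)
class SpeciesPhysiology:
    """System parameters for one species.

    Volumes are per kg body weight; liver weight in g; MPPGL in mg microsomal
    protein per g liver; hepatic blood flow in L/h.
    """

    body_weight: float  # kg
    liver_weight: float  # g
    mppgl: float  # mg/g liver
    hepatic_blood_flow: float  # L/h
    plasma_volume: float  # L/kg
    hematocrit: float
    tissue_volumes: dict[str, float] = field(default_factory=dict)  # L/kg BW

    def __post_init__(self) -> None:
        for name, value in (
            ("body_weight", self.body_weight),
            ("liver_weight", self.liver_weight),
            ("mppgl", self.mppgl),
            ("hepatic_blood_flow", self.hepatic_blood_flow),
            ("plasma_volume", self.plasma_volume),
        ):
            if value <= 0:
                raise ValueError(f"{name} must be positive")
        if sum(self.tissue_volumes.values()) >= 1.0:
            raise ValueError("tissue volumes exceed body volume")


@dataclass(frozen=True)
class VictimSubstrate:
    """One-compartment oral victim drug for the dynamic DDI co-simulation.

    fm is the fraction of total clearance through the inhibited CYP pathway;
    ka first-order absorption (1/h); v_over_f and cl_over_f the apparent oral
    volume (L) and clearance (L/h).
    """

    name: str
    cyp: str
    fm: float
    ka: float
    v_over_f: float
    cl_over_f: float
    dose_mg: float

    def __post_init__(self) -> None:
        if not 0 <= self.fm <= 1:
            raise ValueError("fm must lie in [0, 1]")
        if min(self.ka, self.v_over_f, self.cl_over_f, self.dose_mg) <= 0:
            raise ValueError("ka, v_over_f, cl_over_f and dose_mg must be positive")

    @property
    def half_life_h(self) -> float:
        import math

        return math.log(2.0) / (self.cl_over_f / self.v_over_f)


DAPACONAZOLE_DOG = CompoundParams(
    molecular_weight=415.2,
    log_p=5.63,
    pka=6.77,
    fu_plasma=0.037,
    blood_plasma_ratio=1.0,
    clint_mic=258.0,
    fu_inc=0.97,
)

DAPACONAZOLE_HUMAN = CompoundParams(
    molecular_weight=415.2,
    log_p=5.63,
    pka=6.77,
    fu_plasma=0.077,
    blood_plasma_ratio=6.08,
    clint_mic=118.5,
    fu_inc=0.94,
)

# Unbound plasma fraction used in the human static DDI calculation. The static
# workflow uses 0.037 for Imax,u (the value that reproduces the full R1 panel),
# while the human distribution parameter table carries 0.077; both are exposed.
FU_PLASMA_STATIC = 0.037
CMAX_TOTAL_UM = 9.5  # steady-state total Cmax of the 500 mg q8h IV regimen

# Fractional tissue volumes (L/kg body weight), literature-typical values.
_DOG_TISSUE_VOLUMES = {
    "adipose": 0.150,
    "bone": 0.080,
    "brain": 0.008,
    "gut": 0.037,
    "heart": 0.008,
    "kidney": 0.0055,
    "liver": 0.033,
    "lung": 0.008,
    "muscle": 0.457,
    "skin": 0.090,
    "spleen": 0.0026,
}

_HUMAN_TISSUE_VOLUMES = {
    "adipose": 0.210,
    "bone": 0.086,
    "brain": 0.020,
    "gut": 0.024,
    "heart": 0.0047,
    "kidney": 0.0044,
    "liver": 0.026,
    "lung": 0.0076,
    "muscle": 0.400,
    "skin": 0.037,
    "spleen": 0.0026,
}

DOG_PHYSIOLOGY = SpeciesPhysiology(
    body_weight=10.0,
    liver_weight=320.0,
    mppgl=48.0,
    hepatic_blood_flow=18.5,
    plasma_volume=0.0515,
    hematocrit=0.45,
    tissue_volumes=_DOG_TISSUE_VOLUMES,
)

HUMAN_PHYSIOLOGY = SpeciesPhysiology(
    body_weight=73.0,
    liver_weight=1800.0,
    mppgl=40.0,
    hepatic_blood_flow=90.0,
    plasma_volume=0.0436,
    hematocrit=0.45,
    tissue_volumes=_HUMAN_TISSUE_VOLUMES,
)

# Rodgers-Rowland composition table (fractions of tissue volume; AP in mg/g).
TISSUE_COMPOSITION: dict[str, TissueComposition] = {
    "adipose": TissueComposition(0.135, 0.017, 0.853, 0.0016, 0.40),
    "bone": TissueComposition(0.100, 0.346, 0.017, 0.0017, 0.67),
    "brain": TissueComposition(0.162, 0.620, 0.039, 0.0015, 0.40),
    "gut": TissueComposition(0.282, 0.475, 0.038, 0.0125, 2.41),
    "heart": TissueComposition(0.320, 0.456, 0.014, 0.0111, 2.25),
    "kidney": TissueComposition(0.273, 0.483, 0.012, 0.0242, 5.03),
    "liver": TissueComposition(0.161, 0.573, 0.014, 0.0240, 4.56),
    "lung": TissueComposition(0.336, 0.446, 0.022, 0.0128, 3.91),
    "muscle": TissueComposition(0.118, 0.630, 0.010, 0.0072, 1.53),
    "skin": TissueComposition(0.382, 0.291, 0.060, 0.0044, 1.32),
    "spleen": TissueComposition(0.207, 0.579, 0.0077, 0.0113, 3.18),
}
BLOOD_CELL_COMPOSITION = TissueComposition(0.0, 0.603, 0.0017, 0.0029, 0.50)
PH_PLASMA = 7.4
PH_INTRACELLULAR = 7.0
PH_BLOOD_CELL = 7.22

# Measured microsomal IC50 panel (µM), one row per CYP/probe-substrate pair.
IC50_PANEL_UM: dict[tuple[str, str], float] = {
    ("CYP1A2", "phenacetin"): 3.682,
    ("CYP2A6", "coumarin"): 20.7,
    ("CYP2C8", "paclitaxel"): 104.1,
    ("CYP2C9", "diclofenac"): 0.2186,
    ("CYP2C19", "S-mephenytoin"): 0.05297,
    ("CYP2D6", "bufuralol"): 0.8675,
    ("CYP3A4", "midazolam"): 0.007693,
    ("CYP3A4", "nifedipine"): 0.03032,
}

# DDI table rows: (cyp, static probe substrate) -> fm of the inhibited pathway.
FM_BY_ROW: dict[tuple[str, str], float] = {
    ("CYP1A2", "phenacetin"): 0.71,
    ("CYP2C8", "paclitaxel"): 0.50,
    ("CYP2C9", "diclofenac"): 0.87,
    ("CYP2C19", "S-mephenytoin"): 0.89,
    ("CYP2D6", "bufuralol"): 0.66,
    ("CYP3A4", "midazolam"): 0.88,
    ("CYP3A4", "nifedipine"): 0.96,
}

# Victim models for the dynamic co-simulation. PK constants are
# literature-typical one-compartment oral summaries; all editable.
VICTIM_SUBSTRATES: dict[str, VictimSubstrate] = {
    "phenacetin": VictimSubstrate("phenacetin", "CYP1A2", 0.71, 1.5, 100.0, 70.0, 150.0),
    "repaglinide": VictimSubstrate("repaglinide", "CYP2C8", 0.50, 2.0, 30.0, 33.0, 0.25),
    "tolbutamide": VictimSubstrate("tolbutamide", "CYP2C9", 0.87, 1.0, 10.0, 0.85, 500.0),
    "S-mephenytoin": VictimSubstrate("S-mephenytoin", "CYP2C19", 0.89, 1.5, 50.0, 20.0, 200.0),
    "bufuralol": VictimSubstrate("bufuralol", "CYP2D6", 0.66, 1.5, 150.0, 40.0, 20.0),
    "midazolam": VictimSubstrate("midazolam", "CYP3A4", 0.88, 3.0, 80.0, 60.0, 5.0),
    "nifedipine": VictimSubstrate("nifedipine", "CYP3A4", 0.96, 2.0, 80.0, 40.0, 5.0),
}

# Dynamic co-simulation substrate per DDI row (differs from the static probe
# for CYP2C8 and CYP2C9).
DYNAMIC_SUBSTRATE_BY_ROW: dict[tuple[str, str], str] = {
    ("CYP1A2", "phenacetin"): "phenacetin",
    ("CYP2C8", "paclitaxel"): "repaglinide",
    ("CYP2C9", "diclofenac"): "tolbutamide",
    ("CYP2C19", "S-mephenytoin"): "S-mephenytoin",
    ("CYP2D6", "bufuralol"): "bufuralol",
    ("CYP3A4", "midazolam"): "midazolam",
    ("CYP3A4", "nifedipine"): "nifedipine",
}

# Dog model-qualification reference values: per-dose predicted clearance driving
# the simulations, and the observed NCA constants from the source IV study.
DOG_CL_PREDICTED_ML_MIN = {1.0: 543.5, 2.0: 543.5, 20.0: 454.7}
DOG_QUALIFICATION_REFERENCE = {
    # dose mg/kg: {parameter: (predicted, observed)}
    1.0: {"auc_0_t": (306.7, 255.0), "cmax": (404.7, 373.2), "cl": (543.5, 700.0), "t_half": (1.9, 2.1)},
    2.0: {"auc_0_t": (613.3, 779.9), "cmax": (809.3, 1444.7), "cl": (543.5, 591.7), "t_half": (1.9, 2.5)},
    20.0: {"auc_0_t": (7331.2, 4780.1), "cmax": (8097.3, 4708.3), "cl": (454.7, 700.0), "t_half": (2.2, 2.3)},
}

# Reference static/dynamic AUC-ratio pairs for the seven DDI rows, used only as
# classification inputs and comparison constants (they originate from a
# proprietary population simulator and are not recomputed here).
REFERENCE_AUCR: dict[tuple[str, str], tuple[float, float]] = {
    ("CYP1A2", "phenacetin"): (1.86, 1.17),
    ("CYP2C8", "paclitaxel"): (3.00, 1.46),
    ("CYP2C9", "diclofenac"): (1.95, 1.38),
    ("CYP2C19", "S-mephenytoin"): (3.86, 5.36),
    ("CYP2D6", "bufuralol"): (2.31, 1.51),
    ("CYP3A4", "midazolam"): (19.45, 5.14),
    ("CYP3A4", "nifedipine"): (5.31, 4.05),
}

# Default inhibitor concentration grid of the microsomal assay (µM); the
# zero-inhibitor control is added by the plate generator.
DEFAULT_INHIBITOR_GRID_UM = (0.01, 0.1, 1.0, 10.0, 100.0)

# Minimal-PBPK + SAC distribution parameters shared by the dog and human models
# (SAC volume L/kg, exchange rate constants 1/h, Kp scalar from sensitivity
# analysis, steady-state volume L/kg).
VSS_L_KG = 6.359
VSAC_L_KG = 3.883
KIN_PER_H = 0.0262
KOUT_PER_H = 0.01582
KP_SCALAR_BEST_FIT = 0.01
CL_DOG_IN_VIVO_ML_MIN = 591.7  # observed dog IV clearance driving allometry
CL_HUMAN_L_H = 35.5


def with_fu(compound: CompoundParams, fu_plasma: float) -> CompoundParams:
    """Return a copy of ``compound`` with a different plasma unbound fraction."""
    return replace(compound, fu_plasma=fu_plasma)
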