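"""Seeded synthetic data generators.

Two generators cover the inputs the analysis consumes: microsomal incubation
plates (log-logistic inhibition with multiplicative log-normal noise on the
peak-area ratios) and dog IV plasma profiles (bi-exponential disposition with
log-normal residual error). Noise is mean-one log-normal so the expected value
at every design point equals the analytic curve, and every generator takes an
explicit seed — there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .params import DEFAULT_INHIBITOR_GRID_UM

__all__ = [
    "IncubationPlate",
    "TwoCompartmentParams",
    "SyntheticPKStudy",
    "gen_incubation_plate",
    "gen_dog_pk",
]


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative log-normal factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


@dataclass(frozen=True)
class IncubationPlate:
    """A synthetic incubation plate for one CYP isoform.

    ``data`` has columns conc_uM, replicate, area_ratio; the zero-inhibitor
    control rows carry conc_uM = 0.
    """

    isoform: str
    data: pd.DataFrame = field(repr=False)
    true_ic50: float = math.nan
    true_hill: float = math.nan

    def __post_init__(self) -> None:
        if not (self.data["conc_uM"] == 0.0).any():
            raise ValueError("plate must contain a zero-inhibitor control")
        if (self.data["area_ratio"] <= 0).any():
            raise ValueError("area ratios must be positive")

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "isoform", self.isoform)
        out.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {"isoform": self.isoform, "true_ic50_uM": self.true_ic50,
                 "true_hill": self.true_hill},
                indent=2,
            )
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "IncubationPlate":
        df = pd.read_csv(path)
        isoform = str(df["isoform"].iloc[0]) if "isoform" in df else "unknown"
        return cls(isoform=isoform, data=df[["conc_uM", "replicate", "area_ratio"]])


@dataclass(frozen=True)
class TwoCompartmentParams:
    """Bi-exponential disposition C(t) = A e^(-alpha t) + B e^(-beta t).

    Amplitudes are ng/mL per 1 mg/kg dose; rate constants 1/h.
    """

    a: float
    b: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.alpha, self.beta) <= 0:
            raise ValueError("all amplitudes and rate constants must be positive")
        if math.isclose(self.alpha, self.beta, rel_tol=1e-9):
            raise ValueError("alpha = beta is a degenerate bi-exponential")

    def conc(self, t: np.ndarray, dose_mg_per_kg: float) -> np.ndarray:
        t = np.asarray(t, float)
        return dose_mg_per_kg * (
            self.a * np.exp(-self.alpha * t) + self.b * np.exp(-self.beta * t)
        )

    @property
    def auc_inf_per_dose(self) -> float:
        """Closed-form AUC(0-inf) per 1 mg/kg dose (ng·h/mL)."""
        return self.a / self.alpha + self.b / self.beta


@dataclass(frozen=True)
class SyntheticPKStudy:
    """A simulated single-dose IV plasma study in one subject."""

    dose_mg_per_kg: float
    body_weight_kg: float
    sample_times_h: np.ndarray
    concentrations_ng_per_ml: np.ndarray
    true_params: TwoCompartmentParams

    def __post_init__(self) -> None:
        if (np.diff(self.sample_times_h) <= 0).any():
            raise ValueError("sample times must be strictly increasing")
        if (self.concentrations_ng_per_ml < 0).any():
            raise ValueError("concentrations must be >= 0")

    @property
    def dose_mg(self) -> float:
        return self.dose_mg_per_kg * self.body_weight_kg

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"time_h": self.sample_times_h, "conc_ng_ml": self.concentrations_ng_per_ml}
        ).to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "dose_mg_per_kg": self.dose_mg_per_kg,
                    "body_weight_kg": self.body_weight_kg,
                    "true_params": {
                        "a": self.true_params.a,
                        "b": self.true_params.b,
                        "alpha": self.true_params.alpha,
                        "beta": self.true_params.beta,
                    },
                },
                indent=2,
            )
        )


def gen_incubation_plate(
    ic50_true: float,
    hill_slope: float = 1.0,
    concentrations: tuple[float, ...] = DEFAULT_INHIBITOR_GRID_UM,
    replicates: int = 3,
    noise_cv: float = 0.1,
    seed: int = 0,
    isoform: str = "CYP",
    control_area_ratio: float = 0.5,
) -> IncubationPlate:
    """Generate one incubation plate with a zero-inhibitor control.

    Expected remaining activity at concentration c is 100/(1+(c/ic50)^h);
    each replicate area ratio is the noise-free value times a mean-one
    log-normal factor with CV ``noise_cv``. Identical seed, identical plate.
    """
    if ic50_true <= 0:
        raise ValueError("ic50_true must be positive")
    if hill_slope <= 0:
        raise ValueError("hill_slope must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    conc = np.asarray(concentrations, float)
    if (conc <= 0).any():
        raise ValueError("inhibitor concentrations must be positive (control added separately)")
    if replicates < 1:
        raise ValueError("need >= 1 replicate per level")

    rng = np.random.default_rng(seed)
    levels = np.concatenate([[0.0], conc])
    rows = []
    for c in levels:
        rea = 100.0 if c == 0.0 else 100.0 / (1.0 + (c / ic50_true) ** hill_slope)
        mean_ratio = control_area_ratio * rea / 100.0
        noise = _lognormal_factors(rng, noise_cv, replicates)
        for rep, factor in enumerate(noise, start=1):
            rows.append({"conc_uM": c, "replicate": rep, "area_ratio": mean_ratio * factor})
    return IncubationPlate(
        isoform=isoform,
        data=pd.DataFrame(rows),
        true_ic50=ic50_true,
        true_hill=hill_slope,
    )


def gen_dog_pk(
    two_compartment_params: TwoCompartmentParams,
    dose_mg_per_kg: float,
    body_weight_kg: float,
    sample_times_h: np.ndarray,
    noise_cv: float = 0.15,
    seed: int = 0,
) -> SyntheticPKStudy:
    """Generate a noisy bi-exponential IV plasma profile.

    The noise-free curve is the analytic bi-exponential scaled linearly with
    dose; residual error is multiplicative mean-one log-normal per sample.
    """
    if dose_mg_per_kg <= 0 or body_weight_kg <= 0:
        raise ValueError("dose and body weight must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    times = np.asarray(sample_times_h, float)
    rng = np.random.default_rng(seed)
    clean = two_compartment_params.conc(times, dose_mg_per_kg)
    noisy = clean * _lognormal_factors(rng, noise_cv, times.size)
    return SyntheticPKStudy(
        dose_mg_per_kg=dose_mg_per_kg,
        body_weight_kg=body_weight_kg,
        sample_times_h=times,
        concentrations_ng_per_ml=noisy,
        true_params=two_compartment_params,
    )
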