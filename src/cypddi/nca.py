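"""Noncompartmental analysis and model-qualification tables.

AUC by trapezoid (linear, or linear-up/log-down which log-interpolates the
declining segments), terminal slope by log-linear regression over the
best-adjusted-R² tail window, clearance from dose/AUC, and observed/predicted
qualification ratios with the conventional 2-fold acceptance window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NCAResult",
    "QualificationRow",
    "auc_trapezoid",
    "terminal_halflife",
    "cl_from_dose_auc",
    "run_nca",
    "qualification_table",
]


@dataclass(frozen=True)
class NCAResult:
    """NCA summary of one concentration-time profile (ng/mL vs h, dose in mg)."""

    auc_0_t: float  # ng·h/mL
    auc_inf: float  # ng·h/mL
    cmax: float  # ng/mL
    tmax: float  # h
    lambda_z: float  # 1/h
    t_half: float  # h
    cl: float  # mL/min
    n_lambda_points: int

    def as_dict(self) -> dict[str, float]:
        return {
            "auc_0_t": self.auc_0_t,
            "auc_inf": self.auc_inf,
            "cmax": self.cmax,
            "tmax": self.tmax,
            "lambda_z": self.lambda_z,
            "t_half": self.t_half,
            "cl": self.cl,
        }


@dataclass(frozen=True)
class QualificationRow:
    """One observed/predicted comparison with the 2-fold acceptance flag."""

    parameter: str
    predicted: float
    observed: float

    @property
    def ratio(self) -> float:
        return self.observed / self.predicted

    @property
    def within_2fold(self) -> bool:
        return 0.5 <= self.ratio <= 2.0


def auc_trapezoid(
    times: np.ndarray, concentrations: np.ndarray, method: str = "linear-up/log-down"
) -> float:
    """AUC(0-t) by the trapezoidal rule.

    With ``linear-up/log-down``, segments where the concentration declines and
    both endpoints are positive use the log-trapezoid
    (C1-C2)*dt/ln(C1/C2); all other segments are linear.
    """
    t = np.asarray(times, float)
    c = np.asarray(concentrations, float)
    if t.size < 2:
        raise ValueError("need at least two points")
    if (np.diff(t) <= 0).any():
        raise ValueError("times must be strictly increasing")
    if method not in ("linear", "linear-up/log-down"):
        raise ValueError(f"unknown AUC method {method!r}")

    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    linear = 0.5 * (c1 + c2) * dt
    if method == "linear":
        return float(linear.sum())
    down = (c2 < c1) & (c1 > 0) & (c2 > 0)
    seg = linear.copy()
    seg[down] = (c1[down] - c2[down]) * dt[down] / np.log(c1[down] / c2[down])
    return float(seg.sum())


def terminal_halflife(
    times: np.ndarray, concentrations: np.ndarray, min_points: int = 3
) -> tuple[float, float, int]:
    """Terminal slope by best-adjusted-R² log-linear regression on the tail.

    Candidate windows are the suffixes of the post-Tmax positive points
    (Tmax itself excluded) with at least ``min_points`` points; the window
    maximising adjusted R² wins. Returns (lambda_z, t_half, n_points).

    Raises ValueError when no valid window exists.
    """
    t = np.asarray(times, float)
    c = np.asarray(concentrations, float)
    i_max = int(np.argmax(c))
    tail_idx = np.where((np.arange(t.size) > i_max) & (c > 0))[0]
    if tail_idx.size < min_points:
        raise ValueError("fewer than 3 positive post-Tmax points; no terminal phase")

    tt, lc = t[tail_idx], np.log(c[tail_idx])
    best = None
    n = tt.size
    for start in range(0, n - min_points + 1):
        x, y = tt[start:], lc[start:]
        k = x.size
        slope, intercept = np.polyfit(x, y, 1)
        fitted = slope * x + intercept
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0:
            r2 = 1.0 if ss_res < 1e-300 else 0.0
        else:
            r2 = 1.0 - ss_res / ss_tot
        adj = 1.0 - (1.0 - r2) * (k - 1) / max(k - 2, 1)
        if slope >= 0:
            continue
        if best is None or adj > best[0] + 1e-12:
            best = (adj, -slope, k)
    if best is None:
        raise ValueError("no declining terminal window found")
    _, lambda_z, k = best
    return lambda_z, math.log(2.0) / lambda_z, k


def cl_from_dose_auc(dose_mg: float, auc_inf: float) -> float:
    """Clearance in mL/min from dose (mg) and AUC(0-inf) (ng·h/mL).

    dose/AUC in (mg)/(ng·h/mL) is 1e6 mL/h; divide by 60 for mL/min.
    """
    if dose_mg <= 0 or auc_inf <= 0:
        raise ValueError("dose and AUC must be positive")
    return dose_mg * 1e6 / auc_inf / 60.0


def run_nca(
    times: np.ndarray,
    concentrations: np.ndarray,
    dose_mg: float,
    method: str = "linear-up/log-down",
) -> NCAResult:
    """Full NCA of a single-dose profile: AUCs, Cmax, terminal slope, CL."""
    t = np.asarray(times, float)
    c = np.asarray(concentrations, float)
    auc_t = auc_trapezoid(t, c, method=method)
    lambda_z, t_half, n_pts = terminal_halflife(t, c)
    c_last = c[c > 0][-1]
    auc_inf = auc_t + c_last / lambda_z
    i_max = int(np.argmax(c))
    return NCAResult(
        auc_0_t=auc_t,
        auc_inf=auc_inf,
        cmax=float(c[i_max]),
        tmax=float(t[i_max]),
        lambda_z=lambda_z,
        t_half=t_half,
        cl=cl_from_dose_auc(dose_mg, auc_inf),
        n_lambda_points=n_pts,
    )


def qualification_table(
    predicted: dict[str, float] | NCAResult, observed: dict[str, float] | NCAResult
) -> list[QualificationRow]:
    """Observed/predicted ratios for every parameter present in both inputs."""
    if isinstance(predicted, NCAResult):
        predicted = predicted.as_dict()
    if isinstance(observed, NCAResult):
        observed = observed.as_dict()
    shared = [k for k in predicted if k in observed]
    if not shared:
        raise ValueError("no shared parameters to compare")
    return [QualificationRow(k, float(predicted[k]), float(observed[k])) for k in shared]


def qualification_frame(rows: list[QualificationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "predicted": [r.predicted for r in rows],
            "observed": [r.observed for r in rows],
            "ratio": [r.ratio for r in rows],
            "within_2fold": [r.within_2fold for r in rows],
        }
    )
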