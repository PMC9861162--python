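"""Reversible CYP inhibition analysis.

Turns microsomal incubation readouts (metabolite-to-internal-standard peak-area
ratios) into remaining-activity curves, fits IC50 by nonlinear regression of

    %REA(c) = 100 / (1 + (c / IC50)^h)

against log10 inhibitor concentration, and converts the fitted IC50 into the
competitive inhibition constant Ki = IC50/2 (valid when the probe substrate is
incubated at its Km) and its unbound correction Ki,u = Ki * fu,inc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ActivityPoint",
    "IC50Fit",
    "InhibitorProfile",
    "percent_remaining_activity",
    "activity_points_from_plate",
    "fit_ic50",
    "fit_ic50_from_plate",
    "ki_from_ic50",
    "unbound_ki",
    "unbound_imax",
    "classify_ic50_potency",
    "summarize_panel",
]


@dataclass(frozen=True)
class ActivityPoint:
    """One incubation observation expressed as remaining activity.

    a_i is the peak-area ratio with inhibitor present, a_0 the mean control
    (no-inhibitor) ratio; rea_percent = 100 * a_i / a_0.
    """

    concentration: float  # µM
    rea_percent: float
    a_i: float = float("nan")
    a_0: float = float("nan")

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class IC50Fit:
    """Result of the log-logistic IC50 regression."""

    ic50: float  # µM
    hill_slope: float
    standard_error: float  # µM, delta-method from log10 scale
    ci95: tuple[float, float]  # µM
    converged: bool
    residuals: np.ndarray = field(repr=False)  # % units
    message: str = ""

    def require_converged(self) -> "IC50Fit":
        if not self.converged:
            raise ValueError(f"IC50 fit did not converge: {self.message}")
        return self


@dataclass(frozen=True)
class InhibitorProfile:
    """Inhibition constants and exposure terms of the perpetrator drug."""

    ki: float  # µM
    ki_u: float  # µM
    fu_inc: float
    fu_plasma: float
    rb: float
    cmax_total: float  # µM
    imax_u: float  # µM

    def __post_init__(self) -> None:
        if not 0 < self.fu_inc <= 1:
            raise ValueError("fu_inc must lie in (0, 1]")
        if not 0 < self.fu_plasma <= 1:
            raise ValueError("fu_plasma must lie in (0, 1]")
        if self.ki_u > self.ki * (1 + 1e-12):
            raise ValueError("ki_u cannot exceed ki")
        if self.imax_u > self.cmax_total * (1 + 1e-12):
            raise ValueError("imax_u cannot exceed cmax_total")

    @classmethod
    def from_ic50(
        cls,
        ic50: float,
        *,
        fu_inc: float,
        fu_plasma: float,
        cmax_total: float,
        rb: float = 1.0,
        use_rb_in_imax: bool = False,
    ) -> "InhibitorProfile":
        """Build the full profile from a fitted IC50.

        By default Imax,u = Cmax * fu (the convention that reproduces the
        reference R1 panel); set ``use_rb_in_imax`` to additionally multiply by
        the blood-to-plasma ratio.
        """
        ki = ki_from_ic50(ic50)
        return cls(
            ki=ki,
            ki_u=unbound_ki(ki, fu_inc),
            fu_inc=fu_inc,
            fu_plasma=fu_plasma,
            rb=rb,
            cmax_total=cmax_total,
            imax_u=unbound_imax(cmax_total, fu_plasma, rb=rb if use_rb_in_imax else None),
        )


def percent_remaining_activity(a_i: float, a_0: float) -> float:
    """Remaining enzymatic activity, %REA = 100 * a_i / a_0."""
    if a_0 <= 0:
        raise ValueError("control area ratio a_0 must be positive")
    if a_i < 0:
        raise ValueError("area ratio a_i must be >= 0")
    return 100.0 * a_i / a_0


def activity_points_from_plate(plate: pd.DataFrame) -> list[ActivityPoint]:
    """Convert a plate table (conc_uM, area_ratio columns) to activity points.

    The zero-concentration rows define the control mean a_0 and are not
    returned as regression points.
    """
    controls = plate.loc[plate["conc_uM"] == 0.0, "area_ratio"]
    if controls.empty:
        raise ValueError("plate has no zero-inhibitor control")
    a_0 = float(controls.mean())
    out = []
    for _, row in plate.loc[plate["conc_uM"] > 0.0].iterrows():
        a_i = float(row["area_ratio"])
        out.append(
            ActivityPoint(
                concentration=float(row["conc_uM"]),
                rea_percent=percent_remaining_activity(a_i, a_0),
                a_i=a_i,
                a_0=a_0,
            )
        )
    return out


def _logistic_rea(log10_c: np.ndarray, log10_ic50: float, hill: float) -> np.ndarray:
    return 100.0 / (1.0 + 10.0 ** (hill * (log10_c - log10_ic50)))


def fit_ic50(points: list[ActivityPoint] | pd.DataFrame) -> IC50Fit:
    """Fit the two-parameter log-logistic inhibition model by least squares.

    Top and bottom are fixed at 100% and 0% (the assay normalises to control);
    free parameters are log10(IC50) and the Hill slope. Zero-concentration
    points are excluded (they only define the normalisation).
    """
    if isinstance(points, pd.DataFrame):
        conc = points["conc_uM"].to_numpy(float)
        rea = points["rea_percent"].to_numpy(float)
    else:
        conc = np.array([p.concentration for p in points], float)
        rea = np.array([p.rea_percent for p in points], float)
    keep = conc > 0
    conc, rea = conc[keep], rea[keep]
    if np.unique(conc).size < 4:
        raise ValueError("need >= 4 distinct positive concentrations for the IC50 fit")

    log_c = np.log10(conc)
    # start at the concentration closest to 50% activity, unit slope
    start = log_c[np.argmin(np.abs(rea - 50.0))]
    lo = (log_c.min() - 4.0, 0.05)
    hi = (log_c.max() + 4.0, 20.0)
    try:
        popt, pcov = optimize.curve_fit(
            _logistic_rea,
            log_c,
            rea,
            p0=(start, 1.0),
            bounds=(lo, hi),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological inputs
        return IC50Fit(math.nan, math.nan, math.nan, (math.nan, math.nan), False,
                       np.array([]), message=str(exc))

    log_ic50, hill = popt
    ic50 = 10.0 ** log_ic50
    resid = rea - _logistic_rea(log_c, *popt)
    dof = max(conc.size - 2, 1)
    se_log = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else math.inf
    tcrit = stats.t.ppf(0.975, dof)
    ci = (10.0 ** (log_ic50 - tcrit * se_log), 10.0 ** (log_ic50 + tcrit * se_log))
    se_um = ic50 * math.log(10.0) * se_log  # delta method

    in_range = conc.min() / 100.0 <= ic50 <= conc.max() * 100.0
    message = "" if in_range else (
        f"fitted IC50 {ic50:.4g} µM outside tested range ×100 "
        f"[{conc.min():.4g}, {conc.max():.4g}]"
    )
    return IC50Fit(
        ic50=ic50,
        hill_slope=hill,
        standard_error=se_um,
        ci95=ci,
        converged=in_range,
        residuals=resid,
        message=message,
    )


def fit_ic50_from_plate(plate: pd.DataFrame) -> IC50Fit:
    """Fit IC50 directly to the raw area ratios of a whole plate.

    Model: a(c) = A0 / (1 + (c/IC50)^h), fitted on the log scale (least
    squares on log area ratios is the maximum-likelihood estimator under the
    assay's multiplicative log-normal error). The control plateau A0 is a
    free nuisance parameter and the zero-concentration replicates are
    regression points, so uncertainty in the control level propagates into
    the IC50 confidence interval instead of biasing the curve against a
    fixed 100% top. Preferred over :func:`fit_ic50` whenever raw plate data
    are available.
    """
    conc = plate["conc_uM"].to_numpy(float)
    area = plate["area_ratio"].to_numpy(float)
    if (area <= 0).any():
        raise ValueError("area ratios must be positive")
    if not (conc == 0).any():
        raise ValueError("plate has no zero-inhibitor control")
    pos = conc[conc > 0]
    if np.unique(pos).size < 4:
        raise ValueError("need >= 4 distinct positive concentrations for the IC50 fit")
    log_a = np.log(area)

    def residuals(theta: np.ndarray) -> np.ndarray:
        log_a0, log_ic50, hill = theta
        with np.errstate(over="ignore"):
            frac = np.where(
                conc > 0, 1.0 / (1.0 + (conc / math.exp(log_ic50)) ** hill), 1.0
            )
        return log_a0 + np.log(frac) - log_a

    a0_guess = math.log(float(plate.loc[plate["conc_uM"] == 0, "area_ratio"].mean()))
    x0 = (a0_guess, math.log(float(np.median(pos))), 1.0)
    lo = (a0_guess - 5.0, math.log(pos.min()) - 9.0, 0.05)
    hi = (a0_guess + 5.0, math.log(pos.max()) + 9.0, 20.0)
    res = optimize.least_squares(residuals, x0, bounds=(lo, hi),
                                 xtol=1e-14, ftol=1e-14, gtol=1e-14)

    log_ic50, hill = res.x[1], res.x[2]
    ic50 = math.exp(log_ic50)
    dof = max(conc.size - 3, 1)
    try:
        cov = (2.0 * res.cost / dof) * np.linalg.inv(res.jac.T @ res.jac)
        se_log = math.sqrt(max(cov[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se_log = math.inf
    tcrit = stats.t.ppf(0.975, dof)
    half_width = tcrit * se_log
    if half_width > 700.0:  # CI unbounded in practice (near-singular Jacobian)
        ci = (0.0, math.inf)
    else:
        ci = (ic50 * math.exp(-half_width), ic50 * math.exp(half_width))

    in_range = pos.min() / 100.0 <= ic50 <= pos.max() * 100.0
    message = "" if (res.success and in_range) else (
        f"fit flagged: success={res.success}, IC50 {ic50:.4g} µM vs tested range "
        f"[{pos.min():.4g}, {pos.max():.4g}] ×100"
    )
    return IC50Fit(
        ic50=ic50,
        hill_slope=hill,
        standard_error=ic50 * se_log,  # delta method on the natural-log scale
        ci95=ci,
        converged=bool(res.success and in_range),
        residuals=res.fun * 100.0,
        message=message,
    )


def ki_from_ic50(ic50: float) -> float:
    """Competitive inhibition constant under the [S] = Km design: Ki = IC50/2."""
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    return ic50 / 2.0


def unbound_ki(ki: float, fu_inc: float) -> float:
    """Correct Ki to its unbound incubation value, Ki,u = Ki * fu,inc."""
    if not 0 < fu_inc <= 1:
        raise ValueError("fu_inc must lie in (0, 1]")
    if ki <= 0:
        raise ValueError("ki must be positive")
    return ki * fu_inc


def unbound_imax(cmax_total: float, fu_plasma: float, rb: float | None = None) -> float:
    """Maximal unbound plasma concentration, Imax,u = Cmax * fu.

    Passing ``rb`` additionally multiplies by the blood-to-plasma ratio
    (an alternative convention; off by default).
    """
    if cmax_total < 0:
        raise ValueError("cmax_total must be >= 0")
    if not 0 < fu_plasma <= 1:
        raise ValueError("fu_plasma must lie in (0, 1]")
    imax = cmax_total * fu_plasma
    if rb is not None:
        imax *= rb
    return imax


def classify_ic50_potency(ic50: float) -> str:
    """Band in-vitro potency: high (<1 µM), moderate (1-10 µM), low (>10 µM).

    Boundary values 1 and 10 fall in the moderate band.
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be positive")
    if ic50 < 1.0:
        return "high"
    if ic50 <= 10.0:
        return "moderate"
    return "low"


def summarize_panel(
    fits: dict[tuple[str, str], IC50Fit], fu_inc: float
) -> pd.DataFrame:
    """Tabulate IC50/Ki/Ki,u and potency band per (CYP, substrate) pair."""
    rows = []
    for (cyp, substrate), fit in fits.items():
        ki = ki_from_ic50(fit.ic50)
        rows.append(
            {
                "cyp": cyp,
                "substrate": substrate,
                "ic50_uM": fit.ic50,
                "se_uM": fit.standard_error,
                "hill_slope": fit.hill_slope,
                "ki_uM": ki,
                "ki_u_uM": unbound_ki(ki, fu_inc),
                "band": classify_ic50_potency(fit.ic50),
            }
        )
    return pd.DataFrame(rows)
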