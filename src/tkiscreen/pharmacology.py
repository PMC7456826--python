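"""Quantitative pharmacology: 4PL dose-response fits and assay summaries.

The dose-response model is the four-parameter logistic

    v(d) = bottom + (top - bottom) / (1 + (d / IC50)^hill)

fit by bounded least squares with multi-start over log-spaced IC50
guesses. IC50 generalizes to ICx, the dose at fraction affected x
(normalized between top and bottom), which feeds the Chou-Talalay
combination index CI = d1/Dx1 + d2/Dx2 for two-drug synergy calls
(CI < 1 synergy, = 1 additive, > 1 antagonism). Apoptosis fractions from
flow-cytometry quadrant counts and wound-healing migration inhibition
are plain arithmetic on the assays' numeric outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from tkiscreen.simulate import four_pl

_CI_ATOL = 1e-9


@dataclass
class FourPLFit:
    """Fitted four-parameter logistic curve."""

    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    converged: bool

    def predict(self, dose):
        return four_pl(dose, self.bottom, self.top, self.ic50, self.hill)


def fit_4pl(doses, viability, bottom_max_frac: float = 0.5) -> FourPLFit:
    """Least-squares 4PL fit to (dose, viability) observations.

    ``doses`` and ``viability`` are flat, replicate observations repeated
    per dose. Initialization: top = max per-dose mean, bottom = min
    per-dose mean, hill = 1, IC50 = the dose whose mean is nearest the
    midpoint; three additional starts space IC50 log-uniformly across the
    dose range and the best residual sum of squares wins. ``bottom`` is
    bounded to [0, bottom_max_frac * top-estimate] — doubling-dilution
    designs rarely pin the lower asymptote. Non-convergence of all starts
    is flagged, never silent.
    """
    doses = np.asarray(doses, dtype=float)
    viability = np.asarray(viability, dtype=float)
    if doses.shape != viability.shape:
        raise ValueError("doses and viability must have matching shapes")
    if (doses <= 0).any():
        raise ValueError("doses must be strictly positive")
    uniq = np.unique(doses)
    if uniq.size < 4:
        raise ValueError("need >= 4 distinct doses to identify a 4PL")
    means = np.array([viability[doses == d].mean() for d in uniq])
    if np.ptp(viability) == 0:
        raise ValueError("all viabilities equal: curve unidentifiable")

    top0 = float(means.max())
    bottom0 = float(means.min())
    mid = 0.5 * (top0 + bottom0)
    ic50_init = float(uniq[np.argmin(np.abs(means - mid))])

    lo = np.array([0.0, bottom0, np.log(uniq.min() / 100.0), 0.05])
    hi = np.array(
        [max(bottom_max_frac * top0, 1e-12), top0 * 2.0 + 1e-6,
         np.log(uniq.max() * 100.0), 20.0]
    )

    def residuals(theta):
        b, t, log_ic50, h = theta
        return four_pl(doses, b, t, np.exp(log_ic50), h) - viability

    starts = [ic50_init] + list(np.geomspace(uniq.min(), uniq.max(), 3))
    best = None
    converged = False
    for ic50_guess in starts:
        x0 = np.clip(
            np.array([bottom0, top0, np.log(ic50_guess), 1.0]),
            lo + 1e-12, hi - 1e-12,
        )
        res = least_squares(
            residuals, x0, bounds=(lo, hi), xtol=1e-10, ftol=1e-10, gtol=1e-10
        )
        rss = float(2.0 * res.cost)
        if best is None or rss < best[0]:
            best = (rss, res.x)
            converged = res.status > 0
    rss, (b, t, log_ic50, h) = best
    return FourPLFit(
        bottom=float(b), top=float(t), ic50=float(np.exp(log_ic50)),
        hill=float(h), rss=rss, converged=converged,
    )


def fit_dose_response_table(table: pd.DataFrame) -> FourPLFit:
    """Fit a long-format (dose, replicate, viability) table."""
    return fit_4pl(table["dose"].to_numpy(), table["viability"].to_numpy())


def fold_resistance(
    ic50_resistant: float,
    ic50_parental: float,
    unit_resistant: str | None = None,
    unit_parental: str | None = None,
) -> float:
    """Fold change in IC50 of the resistant line over the parental line."""
    if unit_resistant is not None and unit_parental is not None:
        if unit_resistant != unit_parental:
            raise ValueError(
                f"IC50 unit mismatch: {unit_resistant!r} vs {unit_parental!r}"
            )
    if ic50_resistant <= 0 or ic50_parental <= 0:
        raise ValueError("IC50 values must be positive")
    return ic50_resistant / ic50_parental


def icx(fit: FourPLFit, x: float) -> float:
    """Dose achieving fraction affected x, normalized between top and bottom.

    Closed-form inversion of the 4PL: d = IC50 * (x / (1 - x))^(1/hill).
    icx(fit, 0.5) equals the fitted IC50 exactly.
    """
    if not 0.0 < x < 1.0:
        raise ValueError("fraction affected x must lie strictly in (0, 1)")
    return float(fit.ic50 * (x / (1.0 - x)) ** (1.0 / fit.hill))


def combination_index(
    d1: float,
    d2: float,
    fit1: FourPLFit,
    fit2: FourPLFit,
    effect_level: float,
) -> tuple[float, str]:
    """Chou-Talalay combination index at the effect level the combination achieved.

    CI = d1/Dx1 + d2/Dx2 with Dx_i the single-agent dose producing the
    same fraction affected. Returns (CI, classification) with synergy
    CI < 1, additive CI = 1, antagonism CI > 1.
    """
    if d1 < 0 or d2 < 0:
        raise ValueError("combination doses must be non-negative")
    for label, fit in (("agent 1", fit1), ("agent 2", fit2)):
        if not fit.converged:
            raise ValueError(f"single-agent fit for {label} did not converge")
    try:
        dx1 = icx(fit1, effect_level)
    except ValueError as exc:
        raise ValueError(f"effect level unattainable for agent 1: {exc}") from exc
    try:
        dx2 = icx(fit2, effect_level)
    except ValueError as exc:
        raise ValueError(f"effect level unattainable for agent 2: {exc}") from exc
    ci = d1 / dx1 + d2 / dx2
    if abs(ci - 1.0) <= _CI_ATOL:
        label = "additive"
    elif ci < 1.0:
        label = "synergy"
    else:
        label = "antagonism"
    return float(ci), label


def apoptosis_fraction(q1: int, q2: int, q3: int, q4: int) -> tuple[float, dict[str, float]]:
    """Apoptotic fraction from annexin V / PI quadrant counts.

    Quadrants are Q1 dead-cell fragments, Q2 late apoptosis, Q3 early
    apoptosis, Q4 normal cells; the apoptotic fraction is
    (Q2 + Q3) / total. Also returns per-quadrant percentages (sum 100).
    """
    qs = np.array([q1, q2, q3, q4], dtype=float)
    if (qs < 0).any():
        raise ValueError("quadrant counts must be non-negative")
    total = qs.sum()
    if total == 0:
        raise ValueError("zero total events")
    pct = 100.0 * qs / total
    fraction = float((q2 + q3) / total)
    return fraction, {"Q1": pct[0], "Q2": pct[1], "Q3": pct[2], "Q4": pct[3]}


def migration_inhibition(
    width_0_treated: float,
    width_48_treated: float,
    width_0_control: float,
    width_48_control: float,
) -> float:
    """Wound-healing migration inhibition of treated relative to control wells.

    Closure = (w0 - w48)/w0 per well, floored at 0 (cells may detach and
    the wound widen); inhibition = 1 - closure_treated/closure_control.
    """
    for name, w in (
        ("width_0_treated", width_0_treated),
        ("width_48_treated", width_48_treated),
        ("width_0_control", width_0_control),
        ("width_48_control", width_48_control),
    ):
        if w <= 0:
            raise ValueError(f"{name} must be positive")
    closure_t = max(0.0, (width_0_treated - width_48_treated) / width_0_treated)
    closure_c = max(0.0, (width_0_control - width_48_control) / width_0_control)
    if closure_c == 0:
        raise ValueError("control closure is zero: migration rate undefined")
    return 1.0 - closure_t / closure_c
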