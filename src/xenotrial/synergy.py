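"""Dose-response fitting and Loewe-additivity synergy scoring.

Single-agent viability curves are fit with a four-parameter Hill model; IC50s
beyond the tested range are censored and propagated as bounds.  Combination
9x9 dose matrices are scored with the Loewe combination index
CI = d1/D_x1 + d2/D_x2 at a common effect level x (default 50% inhibition),
with CI < 0.75 called synergistic and CI > 1.5 antagonistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SYNERGY_MAX_CI",
    "ANTAGONISM_MIN_CI",
    "DoseResponseFit",
    "CIResult",
    "fit_hill",
    "hill_inhibition",
    "invert_hill",
    "loewe_ci",
    "classify_ci",
    "matrix_ci",
]

SYNERGY_MAX_CI = 0.75
ANTAGONISM_MIN_CI = 1.5


def hill_inhibition(d, fmax, ec50, h):
    """Fractional inhibition at dose d for a Hill curve anchored at 0."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    pos = d > 0
    out[pos] = fmax / (1.0 + (ec50 / d[pos]) ** h)
    return out


@dataclass
class DoseResponseFit:
    agent: str
    e0: float                    # response at zero dose (input units)
    fmax: float                  # maximal fractional inhibition
    ec50: Optional[float]        # dose at half the *achievable* effect
    hill: Optional[float]
    rss: float
    max_dose: float
    censored: bool               # IC50 (absolute 50% inhibition) beyond range
    ic50: Optional[float]        # None when censored or never reached
    ic50_bound: Optional[float]  # lower bound (= max tested dose) when censored
    flat: bool = False

    def inhibition_at(self, dose: float) -> float:
        if self.flat:
            return 0.0
        return float(hill_inhibition(np.array([dose]), self.fmax, self.ec50, self.hill)[0])

    def dose_at(self, inhibition: float) -> tuple[float, bool]:
        """Dose producing an absolute inhibition level; (bound, True) when the
        level is beyond the fitted curve's reach within the tested range."""
        if self.flat or self.fmax <= inhibition:
            return self.max_dose, True
        d = invert_hill(inhibition, self.fmax, self.ec50, self.hill)
        if d > self.max_dose:
            return self.max_dose, True
        return d, False


def invert_hill(x: float, fmax: float, ec50: float, h: float) -> float:
    """Dose at which a Hill curve reaches absolute inhibition x (< fmax)."""
    if not (0.0 < x < fmax):
        raise ValueError("effect level must lie in (0, fmax)")
    return ec50 * (x / (fmax - x)) ** (1.0 / h)


def _to_inhibition(doses: np.ndarray, responses: np.ndarray,
                   response_type: str) -> tuple[np.ndarray, float]:
    """Normalize responses to fractional inhibition with E0 from zero-dose wells."""
    zero = doses == 0
    if response_type == "viability":
        e0 = float(responses[zero].mean()) if zero.any() else float(responses.max())
        if e0 <= 0:
            raise ValueError("zero-dose viability must be positive")
        return 1.0 - responses / e0, e0
    if response_type == "inhibition":
        e0 = float(responses[zero].mean()) if zero.any() else 0.0
        scale = 100.0 if np.nanmax(np.abs(responses)) > 1.5 else 1.0
        return (responses - e0) / scale, e0
    raise ValueError(f"unknown response_type {response_type!r}")


def fit_hill(doses: Sequence[float], responses: Sequence[float],
             agent: str = "", response_type: str = "viability") -> DoseResponseFit:
    """Least-squares Hill fit with multi-start initialization.

    Requires >= 4 distinct positive doses; zero-dose wells anchor E0.  The fit
    is done on the fractional-inhibition scale with parameters (fmax, EC50, h).
    The IC50 is the dose of 50% absolute inhibition; when the curve does not
    reach 50% within the tested range the fit is censored and the maximum
    tested dose is reported as a lower bound.
    """
    d = np.asarray(doses, dtype=float)
    r = np.asarray(responses, dtype=float)
    if d.shape != r.shape:
        raise ValueError("doses and responses must have equal length")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    pos_doses = np.unique(d[d > 0])
    if pos_doses.size < 4:
        raise ValueError("need at least 4 distinct positive doses")
    inh, e0 = _to_inhibition(d, r, response_type)
    dp, yp = d[d > 0], inh[d > 0]
    max_dose = float(dp.max())

    span = float(yp.max() - yp.min())
    if span < 0.02:  # flat curve: no dose effect to fit
        return DoseResponseFit(agent=agent, e0=e0, fmax=float(max(yp.mean(), 0.0)),
                               ec50=None, hill=None, rss=float(np.sum((yp - yp.mean()) ** 2)),
                               max_dose=max_dose, censored=yp.mean() < 0.5,
                               ic50=None,
                               ic50_bound=max_dose if yp.mean() < 0.5 else None,
                               flat=True)

    def residuals(theta):
        fmax, log_ec50, h = theta
        return hill_inhibition(dp, fmax, math.exp(log_ec50), h) - yp

    lo = [0.0, math.log(pos_doses.min()) - 6.0, 0.05]
    hi = [1.2, math.log(max_dose) + 6.0, 10.0]
    best = None
    fmax0 = float(np.clip(yp.max(), 0.1, 1.0))
    for log_ec in np.linspace(math.log(pos_doses.min()), math.log(max_dose), 7):
        for h0 in (0.5, 1.0, 2.0):
            try:
                sol = optimize.least_squares(residuals, [fmax0, log_ec, h0],
                                             bounds=(lo, hi))
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError(f"Hill fit failed to converge for agent {agent!r}")
    fmax, log_ec50, h = best.x
    ec50 = math.exp(log_ec50)
    rss = float(2.0 * best.cost)

    if fmax <= 0.5:
        ic50, bound, censored = None, max_dose, True
    else:
        ic50 = invert_hill(0.5, fmax, ec50, h)
        if ic50 > max_dose:
            ic50, bound, censored = None, max_dose, True
        else:
            bound, censored = None, False
    return DoseResponseFit(agent=agent, e0=e0, fmax=float(fmax), ec50=float(ec50),
                           hill=float(h), rss=rss, max_dose=max_dose,
                           censored=censored, ic50=ic50, ic50_bound=bound)


def loewe_ci(d1: float, d2: float, D1: float, D2: float,
             d1_censored: bool = False, d2_censored: bool = False,
             ) -> tuple[float, bool]:
    """Loewe combination index d1/D1 + d2/D2 at a common effect level.

    D1/D2 are the single-agent doses producing that effect.  When either is a
    censored lower bound the returned CI is an upper bound (flagged True).
    """
    for name, val in (("d1", d1), ("d2", d2), ("D1", D1), ("D2", D2)):
        if val <= 0:
            raise ValueError(f"{name} must be positive, got {val}")
    return d1 / D1 + d2 / D2, bool(d1_censored or d2_censored)


def classify_ci(ci: float) -> str:
    """Synergy call from a combination index; boundary values are additive."""
    if ci <= 0:
        raise ValueError("CI must be positive")
    if ci < SYNERGY_MAX_CI:
        return "synergistic"
    if ci > ANTAGONISM_MIN_CI:
        return "antagonistic"
    return "additive"


@dataclass
class CIResult:
    effect_level: float
    d1: float
    d2: float
    D1: float
    D2: float
    ci: float
    call: str
    is_upper_bound: bool
    grid_cell: tuple[int, int] = (0, 0)


def _diagonal_interpolate(doses1, doses2, inh, i, j, level):
    """Dose pair at which the diagonal through cell (i, j) crosses ``level``.

    The diagonal steps to (i-1, j-1); with serial-dilution axes this holds the
    dose ratio fixed.  The cell reports a crossing only when it brackets the
    level against its weaker diagonal neighbour (so each crossing is reported
    once).  Interpolation is log-linear in dose, falling back to linear when
    the weaker cell sits on a zero-dose margin.  Returns None otherwise.
    """
    e_hi = inh[i, j]
    e_lo = inh[i - 1, j - 1]
    if not (e_hi >= level > e_lo):
        return None
    w = (level - e_lo) / (e_hi - e_lo) if e_hi > e_lo else 1.0
    a1, a2 = doses1[i - 1], doses2[j - 1]
    b1, b2 = doses1[i], doses2[j]
    if a1 <= 0 or a2 <= 0:
        return (a1 + w * (b1 - a1), a2 + w * (b2 - a2))
    return (a1 ** (1 - w) * b1 ** w, a2 ** (1 - w) * b2 ** w)


def matrix_ci(grid: pd.DataFrame, effect_levels: Sequence[float] = (0.5,),
              response_type: str = "viability",
              agents: tuple[str, str] = ("agent1", "agent2")) -> dict:
    """Loewe CI over a dose-matrix (rows: agent-1 doses, columns: agent-2 doses).

    The zero-dose row and column provide the single-agent marginals, which are
    Hill-fit; each interior combination whose interpolated effect reaches a
    requested level contributes one CI there.  Returns the marginal fits, all
    CI results, and the minimum-CI (best synergy) summary per level.
    """
    doses1 = np.asarray(grid.index, dtype=float)
    doses2 = np.asarray(grid.columns, dtype=float)
    if doses1[0] != 0 or doses2[0] != 0:
        raise ValueError("grid must include zero-dose margins as first row/column")
    if np.any(np.diff(doses1) <= 0) or np.any(np.diff(doses2) <= 0):
        raise ValueError("dose axes must be strictly increasing")
    vals = grid.to_numpy(float)
    if response_type == "viability":
        e00 = vals[0, 0]
        if e00 <= 0:
            raise ValueError("zero-dose well must have positive viability")
        inh = 1.0 - vals / e00
    else:
        inh = vals / (100.0 if np.nanmax(np.abs(vals)) > 1.5 else 1.0)

    fit1 = fit_hill(doses1, vals[:, 0], agent=agents[0], response_type=response_type)
    fit2 = fit_hill(doses2, vals[0, :], agent=agents[1], response_type=response_type)

    results: list[CIResult] = []
    notes: list[str] = []
    for level in effect_levels:
        D1, c1 = fit1.dose_at(level)
        D2, c2 = fit2.dose_at(level)
        any_hit = False
        for i in range(1, len(doses1)):
            for j in range(1, len(doses2)):
                pair = _diagonal_interpolate(doses1, doses2, inh, i, j, level)
                if pair is None:
                    continue
                d1, d2 = pair
                if d1 <= 0 or d2 <= 0:
                    continue
                any_hit = True
                ci, ub = loewe_ci(d1, d2, D1, D2, d1_censored=c1, d2_censored=c2)
                results.append(CIResult(effect_level=level, d1=d1, d2=d2,
                                        D1=D1, D2=D2, ci=ci,
                                        call=classify_ci(ci),
                                        is_upper_bound=ub, grid_cell=(i, j)))
        if not any_hit:
            notes.append(f"no combination reaches effect level {level:g}")
    best = {}
    for level in effect_levels:
        at = [r for r in results if r.effect_level == level]
        if at:
            best[level] = min(at, key=lambda r: r.ci)
    return {"fits": (fit1, fit2), "results": results, "best": best, "notes": notes}
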