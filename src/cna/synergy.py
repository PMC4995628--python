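"""Dose-response fitting and Chou–Talalay combination-index scoring.

Single-drug and fixed-ratio combination viability series are fitted with the
two-parameter median-effect (Hill) model

    f_u(x) = 1 / (1 + (x / D50)^m)

by damped Newton-type least squares in (log D50, log m) space. The drug
combination index at fraction-affected level fa is

    CI(fa) = D_1 / D_1^single(fa) + D_2 / D_2^single(fa)

where (D_1, D_2) are the constituent doses of the combination achieving fa
and D_i^single(fa) the single-drug doses achieving the same effect; CI <= 0.85
is called synergism, CI >= 1.20 antagonism, anything between additive.
The combination is fitted on the drug1-equivalent dose axis of a fixed-ratio
design (ratio = units of drug 2 per unit of drug 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseResponse",
    "HillFit",
    "DCIProfile",
    "hill",
    "fit_hill",
    "effect_dose",
    "dci",
    "classify",
    "SYNERGY_THRESHOLD",
    "ANTAGONISM_THRESHOLD",
]

SYNERGY_THRESHOLD = 0.85
ANTAGONISM_THRESHOLD = 1.20

DEFAULT_LEVELS = np.round(np.arange(0.10, 0.9001, 0.05), 2)


@dataclass
class DoseResponse:
    """A dose–viability series (responses are fraction unaffected)."""

    doses: np.ndarray
    responses: np.ndarray
    label: str = ""
    ratio: float | None = None  # drug2 units per drug1 unit, for combinations

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses differ in length")
        if (self.doses <= 0).any():
            raise ValueError("doses must be strictly positive")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if (self.responses < 0).any() or (self.responses > 1.2).any():
            raise ValueError("responses must lie in [0, 1.2]")


@dataclass
class HillFit:
    d50: float
    m: float
    sse: float
    converged: bool
    iterations: int
    label: str = ""

    def predict(self, dose) -> np.ndarray:
        return hill(np.asarray(dose, dtype=float), self.d50, self.m)


@dataclass
class DCIProfile:
    levels: np.ndarray
    ci: np.ndarray
    headline_ci: float
    call: str
    label: str = ""

    def as_dict(self) -> dict[float, float]:
        return dict(zip(self.levels.tolist(), self.ci.tolist()))


def hill(x: np.ndarray, d50: float, m: float) -> np.ndarray:
    """Fraction unaffected at dose x: 1 / (1 + (x/d50)^m)."""
    return 1.0 / (1.0 + np.power(x / d50, m))


def _sse(x, y, ld, lm):
    return float(np.sum((y - hill(x, np.exp(ld), np.exp(lm))) ** 2))


def fit_hill(
    dr: DoseResponse,
    init: tuple[float, float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> HillFit:
    """Least-squares fit of (D50, m) by damped Gauss–Newton in log space.

    Initialization: D50 at the dose whose response is nearest 0.5, m = 1
    (overridable via ``init``). Steps that increase the SSE are halved up to
    20 times; on failure to descend, a log-grid search plus polish takes
    over and the ``converged`` flag reports the truth. Responses above 1
    (plate noise) are clipped to 1 with a warning.

    Requires >= 4 dose points and a broadly decreasing response profile.
    """
    x = dr.doses.copy()
    y = dr.responses.copy()
    if len(x) < 4:
        raise ValueError("need >=4 dose points to fit")
    if (y > 1).any():
        warnings.warn("responses > 1 clipped to 1 for fitting")
        y = np.minimum(y, 1.0)
    if np.ptp(y) == 0:
        raise ValueError("all responses identical; nothing to fit")
    slope = np.polyfit(np.log(x), y, 1)[0]
    if slope >= 0:
        raise ValueError("response does not decrease with dose; no descent to fit")

    if init is not None:
        ld, lm = np.log(init[0]), np.log(init[1])
    else:
        ld = np.log(x[np.argmin(np.abs(y - 0.5))])
        lm = 0.0

    lx = np.log(x)
    sse = _sse(x, y, ld, lm)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d50, m = np.exp(ld), np.exp(lm)
        u = np.power(x / d50, m)
        f = 1.0 / (1.0 + u)
        g = u / (1.0 + u) ** 2  # common factor of both partials
        # df/d(log D50) = m*g ; df/d(log m) = -m*log(x/D50)*g
        J = np.column_stack([m * g, -m * (lx - ld) * g])
        r = y - f
        try:
            step = np.linalg.solve(J.T @ J, J.T @ r)
        except np.linalg.LinAlgError:
            break
        # damping: halve the step while the SSE does not improve
        scale = 1.0
        for _ in range(20):
            nld, nlm = ld + scale * step[0], lm + scale * step[1]
            new_sse = _sse(x, y, nld, nlm)
            if new_sse <= sse:
                break
            scale /= 2.0
        else:
            break
        improvement = sse - new_sse
        ld, lm, sse = nld, nlm, new_sse
        if np.abs(scale * step).max() < tol or improvement < tol * max(sse, 1.0):
            converged = True
            break

    if not converged:
        ld, lm, sse, polished = _grid_fallback(x, y, ld, lm, sse, tol, max_iter)
        converged = polished
    return HillFit(float(np.exp(ld)), float(np.exp(lm)), sse, converged, it, dr.label)


def _grid_fallback(x, y, ld0, lm0, sse0, tol, max_iter):
    """Coarse log-grid search over (D50, m), then one polishing descent."""
    lds = np.linspace(np.log(x.min()) - 2, np.log(x.max()) + 2, 41)
    lms = np.linspace(np.log(0.1), np.log(10.0), 25)
    best = (ld0, lm0, sse0)
    for ld in lds:
        for lm in lms:
            s = _sse(x, y, ld, lm)
            if s < best[2]:
                best = (ld, lm, s)
    ld, lm, sse = best
    # simple coordinate polish
    step = 0.1
    for _ in range(max_iter):
        moved = False
        for delta in ((step, 0), (-step, 0), (0, step), (0, -step)):
            s = _sse(x, y, ld + delta[0], lm + delta[1])
            if s < sse:
                ld, lm, sse = ld + delta[0], lm + delta[1], s
                moved = True
        if not moved:
            step /= 2.0
            if step < tol:
                return ld, lm, sse, True
    return ld, lm, sse, False


def effect_dose(fit: HillFit, fa: float) -> float:
    """Dose producing fraction-affected ``fa``: D50 * (fa/(1-fa))^(1/m)."""
    if not 0.0 < fa < 1.0:
        raise ValueError("fraction affected must lie in (0, 1)")
    return float(fit.d50 * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def dci(
    fit1: HillFit,
    fit2: HillFit,
    fit_combo: HillFit,
    ratio: float,
    levels=DEFAULT_LEVELS,
) -> DCIProfile:
    """Combination-index profile across fraction-affected levels.

    ``fit_combo`` must come from a fixed-ratio series on the drug1-equivalent
    dose axis; ``ratio`` is drug2 dose per unit drug1 dose. At each level the
    combination dose splits into D_1 = D_combo and D_2 = ratio * D_combo and
    CI = D_1/D_1^single + D_2/D_2^single. The headline call uses the 50 %
    effect level.
    """
    for f in (fit1, fit2, fit_combo):
        if not f.converged:
            raise ValueError(f"unconverged fit: {f.label or '(unnamed)'}")
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    levels = np.asarray(levels, dtype=float)
    ci = np.empty_like(levels)
    for i, fa in enumerate(levels):
        d_combo = effect_dose(fit_combo, fa)
        ci[i] = (d_combo / effect_dose(fit1, fa)
                 + ratio * d_combo / effect_dose(fit2, fa))
    headline = (d50_ci := _ci_at(fit1, fit2, fit_combo, ratio, 0.5))
    return DCIProfile(levels, ci, headline, classify(d50_ci), fit_combo.label)


def _ci_at(fit1, fit2, fit_combo, ratio, fa):
    d_combo = effect_dose(fit_combo, fa)
    return float(d_combo / effect_dose(fit1, fa)
                 + ratio * d_combo / effect_dose(fit2, fa))


def classify(ci: float) -> str:
    """Call a combination index: synergism <= 0.85 < additive < 1.20 <= antagonism."""
    if not np.isfinite(ci) or ci <= 0:
        raise ValueError("combination index must be a positive number")
    if ci <= SYNERGY_THRESHOLD:
        return "synergism"
    if ci >= ANTAGONISM_THRESHOLD:
        return "antagonism"
    return "additive"
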