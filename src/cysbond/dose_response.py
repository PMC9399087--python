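"""Four-parameter logistic (4PL) dose-response fitting.

Fits Y = bottom + (top - bottom) / (1 + (ec50/X)^h) to IL-2 coculture
readouts over graded peptide concentrations.  Internally the curve is
parameterized on log-dose for optimizer stability; results are reported on
the linear scale.  Confidence intervals come from a seeded parametric
bootstrap rather than asymptotic formulas.  When the data never reach an
upper plateau the fitted EC50 is only a lower bound on the true value and
is flagged as a minimum estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class FitConvergenceError(RuntimeError):
    """The 4PL optimizer failed to converge; diagnostics in the message."""


@dataclass
class DoseResponseCurve:
    """Dose-response observations; zero-dose control wells kept separate."""

    doses: np.ndarray
    responses: np.ndarray
    replicate_ids: np.ndarray | None = None
    dose_unit: str = "nM"
    zero_dose_responses: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        zero = self.doses <= 0
        if zero.any():
            self.zero_dose_responses = self.responses[zero]
            self.doses = self.doses[~zero]
            self.responses = self.responses[~zero]
            if self.replicate_ids is not None:
                self.replicate_ids = np.asarray(self.replicate_ids)[~zero]
        if np.unique(self.doses).size < 4:
            raise ValueError("4PL fitting needs >= 4 distinct positive doses")


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters with bootstrap 95% confidence intervals."""

    ec50: float
    h: float
    top: float
    bottom: float
    ec50_ci: tuple[float, float]
    h_ci: tuple[float, float]
    top_ci: tuple[float, float]
    plateau_reached: bool
    ec50_is_minimum_estimate: bool
    dose_unit: str = "nM"
    residual_sd: float = 0.0
    status: str = "ok"  # "ok" | "sign_warning"

    def predict(self, doses) -> np.ndarray:
        return four_pl(np.asarray(doses, dtype=float),
                       self.bottom, self.top, self.ec50, self.h)

    def to_dict(self) -> dict:
        return {
            "ec50": self.ec50, "h": self.h, "top": self.top,
            "bottom": self.bottom, "ec50_ci": list(self.ec50_ci),
            "h_ci": list(self.h_ci), "top_ci": list(self.top_ci),
            "plateau_reached": self.plateau_reached,
            "ec50_is_minimum_estimate": self.ec50_is_minimum_estimate,
            "dose_unit": self.dose_unit, "status": self.status,
        }


def four_pl(x: np.ndarray, bottom: float, top: float, ec50: float, h: float):
    """4PL response at dose x: bottom + (top-bottom)/(1 + (ec50/x)^h)."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + np.exp(h * (np.log(ec50) - np.log(x))))


def _fit_core(logx: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares 4PL on log-dose; returns (bottom, top, log_ec50, h)."""

    def model(lx, bottom, top, log_ec50, h):
        return bottom + (top - bottom) / (1.0 + np.exp(h * (log_ec50 - lx)))

    span = float(y.max() - y.min())
    p0 = (float(y.min()), float(y.max()), float(np.median(logx)), 1.0)
    lo = [y.min() - 2 * span - 1.0, y.min() - 2 * span - 1.0, logx.min() - 15.0, -20.0]
    hi = [y.max() + 2 * span + 1.0, y.max() + 10 * span + 1.0, logx.max() + 15.0, 20.0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            popt, _ = curve_fit(model, logx, y, p0=p0, bounds=(lo, hi), maxfev=40000)
        except RuntimeError as exc:
            raise FitConvergenceError(f"4PL fit did not converge: {exc}") from exc
    return popt


def fit_4pl(
    curve: DoseResponseCurve,
    n_bootstrap: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> FourPLFit:
    """Fit the 4PL and attach parametric-bootstrap confidence intervals.

    The bootstrap error model is heteroscedastic: immunoassay readouts
    scale with the signal, so per-point noise is taken proportional to the
    fitted response (with a floor at 5% of the curve maximum so baseline
    points keep a nonzero scale), with the relative scale estimated from
    the degrees-of-freedom-corrected residuals.

    The plateau criterion declares the upper plateau reached when the
    bootstrap CI of ``top`` is narrower than half the fitted ``top`` and
    the mean response at the highest dose is at least 90% of the fitted
    ``top``; otherwise the EC50 is reported as a minimum estimate.
    Monotone-decreasing data (fitted h < 0) yield a ``sign_warning``.
    """
    logx = np.log(curve.doses)
    y = curve.responses
    bottom, top, log_ec50, h = _fit_core(logx, y)
    fitted = four_pl(curve.doses, bottom, top, np.exp(log_ec50), h)
    resid = y - fitted
    dof = max(y.size - 4, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    scale = np.maximum(np.abs(fitted), 0.05 * float(np.abs(fitted).max()) + 1e-12)
    rel_sd = float(np.sqrt(np.sum((resid / scale) ** 2) / dof))

    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        y_sim = fitted + rng.normal(0.0, rel_sd * scale)
        try:
            boots.append(_fit_core(logx, y_sim))
        except FitConvergenceError:
            continue
    alpha = 1.0 - ci_level
    if boots:
        arr = np.asarray(boots)
        qs = np.quantile(arr, [alpha / 2, 1 - alpha / 2], axis=0)
        ec50_ci = (float(np.exp(qs[0, 2])), float(np.exp(qs[1, 2])))
        h_ci = (float(qs[0, 3]), float(qs[1, 3]))
        top_ci = (float(qs[0, 1]), float(qs[1, 1]))
    else:
        ec50_ci = h_ci = top_ci = (float("nan"), float("nan"))

    top_ci_width = top_ci[1] - top_ci[0]
    max_dose = curve.doses.max()
    max_dose_resp = float(np.mean(y[curve.doses == max_dose]))
    plateau = (
        np.isfinite(top_ci_width)
        and top_ci_width < 0.5 * abs(top)
        and max_dose_resp >= 0.9 * top
    )
    return FourPLFit(
        ec50=float(np.exp(log_ec50)), h=float(h), top=float(top),
        bottom=float(bottom), ec50_ci=ec50_ci, h_ci=h_ci, top_ci=top_ci,
        plateau_reached=bool(plateau),
        ec50_is_minimum_estimate=not bool(plateau),
        dose_unit=curve.dose_unit, residual_sd=resid_sd,
        status="sign_warning" if (h < 0 or top < bottom) else "ok",
    )


def simulate_dose_response(
    bottom: float,
    top: float,
    ec50: float,
    h: float,
    doses,
    noise_cv: float = 0.0,
    n_replicates: int = 1,
    seed: int = 0,
    dose_unit: str = "nM",
) -> DoseResponseCurve:
    """Simulate responses = 4PL(dose) * lognormal(mean 1, CV noise_cv)."""
    rng = np.random.default_rng(seed)
    d = np.repeat(np.asarray(doses, dtype=float), n_replicates)
    reps = np.tile(np.arange(n_replicates), len(np.asarray(doses)))
    mu = four_pl(d, bottom, top, ec50, h)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=d.shape)
        y = mu * noise
    else:
        y = mu
    return DoseResponseCurve(doses=d, responses=y, replicate_ids=reps,
                             dose_unit=dose_unit)
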