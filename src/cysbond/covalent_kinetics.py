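"""Two-phase TCR-pMHC binding kinetics and SPR-style analysis.

The model: analyte at concentration C binds immobilized receptor
reversibly, and a bound noncovalent complex can convert irreversibly into a
disulfide-linked (covalent) complex:

    dB_nc/dt = kon * C * (Rmax - B_nc - B_cov) - (koff + kcov) * B_nc
    dB_cov/dt = kcov * B_nc

with C piecewise-constant over the injection schedule (0 during
dissociation).  The noncovalent phase sets the apparent affinity
K_eq = koff/kon; the covalent phase accumulates over minutes because the
per-binding-event conversion probability kcov/(koff+kcov) is small.
Treating the system with a reducing agent (DTT) is modeled as kcov = 0, in
which case the signal returns to baseline after injection ends.

Also provided: 1:1 Langmuir steady-state fitting of equilibrium responses,
the occupancy normalization used to compare chips with different amounts of
immobilized receptor, decomposition of a dissociation trace into a fast
exponential plus a persistent plateau, and tetramer-decay curves with
rebinding blocked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class KineticParams:
    """Rate constants of the two-phase binding scheme.

    kon in 1/(M s); koff and kcov in 1/s (kcov = 0 models DTT treatment);
    rmax in RU.
    """

    kon: float
    koff: float
    kcov: float = 0.0
    rmax: float = 100.0

    def __post_init__(self) -> None:
        if min(self.kon, self.koff, self.kcov, self.rmax) < 0:
            raise ValueError("all kinetic parameters must be >= 0")

    @property
    def keq(self) -> float:
        """Equilibrium dissociation constant of the noncovalent step (M)."""
        return self.koff / self.kon


@dataclass(frozen=True)
class InjectionSchedule:
    """Piecewise-constant analyte program: (concentration M, duration s)."""

    segments: tuple[tuple[float, float], ...]
    dissociation_duration: float = 0.0

    def __post_init__(self) -> None:
        for conc, dur in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if conc < 0:
                raise ValueError("concentrations must be >= 0")
        if self.dissociation_duration < 0:
            raise ValueError("dissociation duration must be >= 0")

    @classmethod
    def single(
        cls, concentration: float, duration: float, dissociation: float = 0.0
    ) -> "InjectionSchedule":
        return cls(((concentration, duration),), dissociation)


@dataclass
class Sensorgram:
    """RU time series with (for simulations) its bound-state components."""

    time: np.ndarray
    response: np.ndarray
    bound_noncovalent: np.ndarray | None = None
    bound_covalent: np.ndarray | None = None
    injection_end: float | None = None


@dataclass(frozen=True)
class SteadyStateFit:
    """1:1 Langmuir steady-state fit of equilibrium responses."""

    keq: float
    rmax: float
    keq_stderr: float
    rmax_stderr: float
    concentrations: tuple[float, ...]
    eq_responses: tuple[float, ...]
    status: str = "ok"  # "ok" | "degenerate"


@dataclass(frozen=True)
class DissociationDecomposition:
    """Fast-exponential + persistent-plateau split of a dissociation trace."""

    fast_amplitude: float
    decay_rate: float
    persistent_plateau: float
    half_life: float
    status: str = "ok"  # "ok" | "warning"


def _rates(params: KineticParams, conc: float) -> tuple[np.ndarray, np.ndarray]:
    """Affine system x' = A x + b for constant concentration."""
    a = params.kon * conc
    A = np.array(
        [[-(a + params.koff + params.kcov), -a], [params.kcov, 0.0]]
    )
    b = np.array([a * params.rmax, 0.0])
    return A, b


def simulate_sensorgram(
    params: KineticParams,
    schedule: InjectionSchedule,
    dt: float = 0.1,
    y0: Sequence[float] = (0.0, 0.0),
) -> Sensorgram:
    """Integrate the two-state model over an injection schedule.

    State carries over between segments without reset, matching sequential
    injections at increasing concentrations.  ``dt`` sets the output grid
    spacing; integration itself is adaptive (LSODA) with tolerances far
    below the reported signal, so stiffness in any rate regime is handled
    internally rather than by the caller choosing a step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    segments = list(schedule.segments)
    if schedule.dissociation_duration > 0:
        segments.append((0.0, schedule.dissociation_duration))

    times: list[np.ndarray] = []
    ncs: list[np.ndarray] = []
    covs: list[np.ndarray] = []
    t0 = 0.0
    y = np.asarray(y0, dtype=float)
    atol = max(params.rmax, 1.0) * 1e-9
    for conc, dur in segments:
        A, b = _rates(params, conc)
        grid = np.arange(0.0, dur + 0.5 * dt, dt)
        grid[-1] = min(grid[-1], dur)
        sol = solve_ivp(
            lambda t, x: A @ x + b,
            (0.0, dur),
            y,
            method="LSODA",
            t_eval=grid,
            rtol=1e-8,
            atol=atol,
            jac=lambda t, x: A,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        times.append(sol.t + t0)
        ncs.append(sol.y[0])
        covs.append(sol.y[1])
        y = sol.y[:, -1].copy()
        t0 += dur

    time = np.concatenate(times)
    nc = np.concatenate(ncs)
    cov = np.concatenate(covs)
    inj_end = sum(d for _, d in schedule.segments)
    return Sensorgram(
        time=time,
        response=nc + cov,
        bound_noncovalent=nc,
        bound_covalent=cov,
        injection_end=inj_end,
    )


def persistent_fraction(
    params: KineticParams, injection_duration: float, concentration: float
) -> float:
    """Fraction of the end-of-injection response that never decays.

    Every noncovalent complex eventually either dissociates or converts,
    with conversion probability kcov/(koff+kcov); covalent complexes are
    permanent.  Zero exactly when kcov = 0; strictly increasing in the
    injection duration otherwise.
    """
    if params.kcov == 0.0:
        return 0.0
    sg = simulate_sensorgram(
        params, InjectionSchedule.single(concentration, injection_duration), dt=min(0.1, injection_duration / 100)
    )
    b_nc = float(sg.bound_noncovalent[-1])
    b_cov = float(sg.bound_covalent[-1])
    total = b_nc + b_cov
    if total == 0.0:
        return 0.0
    p_convert = params.kcov / (params.koff + params.kcov)
    return (b_cov + b_nc * p_convert) / total


def fit_steady_state(
    concentrations: Sequence[float], eq_responses: Sequence[float]
) -> SteadyStateFit:
    """Fit R_eq = Rmax * C / (K_eq + C) by least squares.

    Flags the fit as degenerate when Rmax is unidentifiable: all responses
    equal, or the fitted K_eq escapes far beyond the sampled concentration
    range (non-saturating data).
    """
    C = np.asarray(concentrations, dtype=float)
    R = np.asarray(eq_responses, dtype=float)
    if C.size < 3:
        raise ValueError("steady-state fit needs at least 3 concentrations")
    if np.ptp(R) < 1e-12 * max(1.0, float(np.abs(R).max())):
        return SteadyStateFit(
            keq=float("nan"), rmax=float("nan"),
            keq_stderr=float("nan"), rmax_stderr=float("nan"),
            concentrations=tuple(C), eq_responses=tuple(R), status="degenerate",
        )

    def langmuir(c, rmax, keq):
        return rmax * c / (keq + c)

    p0 = (float(R.max()) * 1.5, float(np.median(C)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, pcov = curve_fit(
            langmuir, C, R, p0=p0, bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    perr = np.sqrt(np.diag(pcov))
    status = "ok"
    if not np.all(np.isfinite(perr)) or popt[1] > 100.0 * C.max():
        status = "degenerate"
    return SteadyStateFit(
        keq=float(popt[1]), rmax=float(popt[0]),
        keq_stderr=float(perr[1]), rmax_stderr=float(perr[0]),
        concentrations=tuple(C), eq_responses=tuple(R), status=status,
    )


def normalization_factor(keq_ref: float, concentration: float) -> float:
    """Occupancy correction factor (K_eq + C) / C.

    At equilibrium a 1:1 Langmuir interaction occupies C/(K_eq + C) of the
    surface, so the RU corresponding to 100% occupancy is this factor times
    the equilibrium RU of the reference injection.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    return (keq_ref + concentration) / concentration


def normalized_ru(
    ru_control_eq: float,
    keq_ref: float,
    concentration: float,
    responses: Sequence[float] | np.ndarray | None = None,
) -> tuple[float, np.ndarray | None]:
    """Normalize responses to estimated fractional receptor occupancy.

    Returns ``(factor, normalized)`` where ``factor * ru_control_eq`` is
    the RU at full occupancy and ``normalized = responses / (factor *
    ru_control_eq)``; ``normalized`` is None when no responses are given.
    """
    factor = normalization_factor(keq_ref, concentration)
    full = factor * ru_control_eq
    if responses is None:
        return factor, None
    return factor, np.asarray(responses, dtype=float) / full


def decompose_dissociation(
    sensorgram: Sensorgram, window_start: float | None = None
) -> DissociationDecomposition:
    """Fit R(t) = A exp(-lambda (t - t0)) + P on the post-injection window.

    Reports the fast-phase half-life ln2/lambda and the persistent plateau
    P.  A post-injection signal that rises beyond noise tolerance yields a
    ``warning`` status (the model predicts monotone decay once injection
    ends).
    """
    t0 = window_start if window_start is not None else sensorgram.injection_end
    if t0 is None:
        raise ValueError("window_start required when injection_end is unknown")
    mask = sensorgram.time >= t0
    t = sensorgram.time[mask] - t0
    r = sensorgram.response[mask]
    if t.size < 4:
        raise ValueError("dissociation window too short to fit")

    status = "ok"
    scale = max(float(np.abs(r).max()), 1e-12)
    if np.any(np.diff(r) > 1e-3 * scale):
        status = "warning"

    amp0 = max(float(r[0] - r[-1]), 1e-9)
    lam0 = 1.0 / max(float(t[-1]) / 5.0, 1e-6)

    def model(tt, amp, lam, plateau):
        return amp * np.exp(-lam * tt) + plateau

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        popt, _ = curve_fit(
            model, t, r, p0=(amp0, lam0, float(r[-1])),
            bounds=([0.0, 1e-12, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    amp, lam, plateau = (float(v) for v in popt)
    return DissociationDecomposition(
        fast_amplitude=amp,
        decay_rate=lam,
        persistent_plateau=plateau,
        half_life=LN2 / lam,
        status=status,
    )


def simulate_tetramer_decay(
    params: KineticParams,
    timepoints_min: Sequence[float],
    f_cov: float = 0.0,
) -> np.ndarray:
    """Percent of tetramer staining remaining with rebinding blocked.

    With no association term, each noncovalent complex either dissociates
    or converts covalently; ``f_cov`` is the covalently bound fraction when
    the blocking antibody is added (t = 0).  With kcov = 0 and f_cov = 0
    this reduces to pure exponential decay 100*exp(-koff t).
    """
    if not 0.0 <= f_cov <= 1.0:
        raise ValueError("f_cov must lie in [0, 1]")
    t = np.asarray(timepoints_min, dtype=float) * 60.0
    k = params.koff + params.kcov
    if k == 0.0:
        return np.full(t.shape, 100.0)
    p_convert = params.kcov / k
    remaining = (
        f_cov
        + (1.0 - f_cov) * np.exp(-k * t)
        + (1.0 - f_cov) * p_convert * (1.0 - np.exp(-k * t))
    )
    return 100.0 * remaining
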