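"""Denaturant transition curves: double-Boltzmann fits and thermodynamics.

A scalar optical parameter y (a fluorescence lifetime, the molar ellipticity
at 222 nm, or the intensity ratio I320/I360) measured against urea molarity u
is described by the double-Boltzmann function

    y(u) = y0 + A * [ p / (1 + exp((c1 - u)/k1))
                    + (1 - p) / (1 + exp((c2 - u)/k2)) ]

with a shared baseline ``y0``, total signed amplitude ``A``, amplitude
fraction ``p`` of the first transition, midpoints ``c1 < c2`` (the
[Urea]_50% values) and widths ``k1``, ``k2`` in molar units.

Each transition is mapped to two-state linear-extrapolation thermodynamics:
the m-value is m_i = R*T / k_i and the unfolding free energy extrapolated to
water is dG_H2O,i = m_i * c_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .errors import DomainError
from .tcspc import SteadyStateSpectrum

__all__ = [
    "TransitionCurve",
    "DoubleBoltzmannParams",
    "TransitionFit",
    "ThermoParams",
    "double_boltzmann",
    "fit_transition",
    "thermo_from_fit",
    "intensity_ratio",
]

GAS_CONSTANT_KJ = 8.314e-3  # kJ mol^-1 K^-1
DEFAULT_TEMPERATURE_K = 298.15


@dataclass(frozen=True)
class TransitionCurve:
    """Optical parameter vs denaturant concentration."""

    denaturant: np.ndarray  # M urea, strictly increasing
    signal: np.ndarray
    signal_name: str = "signal"

    def __post_init__(self):
        u = np.asarray(self.denaturant, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if u.shape != y.shape or u.ndim != 1:
            raise DomainError("denaturant and signal must be 1D, same length")
        if np.any(u < 0):
            raise DomainError("denaturant concentrations must be non-negative")
        if np.any(np.diff(u) <= 0):
            raise DomainError("denaturant grid must be strictly increasing")
        object.__setattr__(self, "denaturant", u)
        object.__setattr__(self, "signal", y)


@dataclass(frozen=True)
class DoubleBoltzmannParams:
    y0: float  # baseline signal
    A: float  # total amplitude (signed)
    p: float  # amplitude fraction of transition 1, in [0, 1]
    c1: float  # midpoint of transition 1, M
    c2: float  # midpoint of transition 2, M
    k1: float  # width of transition 1, M
    k2: float  # width of transition 2, M

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 <= 0:
            raise DomainError("transition widths must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise DomainError("amplitude fraction p must lie in [0, 1]")

    def ordered(self) -> "DoubleBoltzmannParams":
        """Canonical form with c1 <= c2 (swapping relabels p -> 1-p)."""
        if self.c1 <= self.c2:
            return self
        return DoubleBoltzmannParams(
            self.y0, self.A, 1.0 - self.p, self.c2, self.c1, self.k2, self.k1
        )


@dataclass
class TransitionFit:
    params: DoubleBoltzmannParams
    stderr: dict[str, float] | None
    converged: bool
    chi2: float
    n_points: int
    warnings: list[str] = field(default_factory=list)
    message: str = ""


@dataclass(frozen=True)
class ThermoParams:
    """Per-transition linear-extrapolation thermodynamics."""

    m_values: tuple[float, float]  # kJ mol^-1 M^-1
    dG_H2O: tuple[float, float]  # kJ mol^-1
    fractions: tuple[float, float]  # amplitude shares, sum to 1
    temperature: float = DEFAULT_TEMPERATURE_K  # K


def double_boltzmann(
    u: np.ndarray | float, params: DoubleBoltzmannParams
) -> np.ndarray | float:
    """Evaluate the double-Boltzmann transition model at urea concentration u."""
    u_arr = np.asarray(u, dtype=float)
    s1 = expit((u_arr - params.c1) / params.k1)
    s2 = expit((u_arr - params.c2) / params.k2)
    y = params.y0 + params.A * (params.p * s1 + (1.0 - params.p) * s2)
    return y if np.ndim(u) else float(y)


def _initial_guess(u: np.ndarray, y: np.ndarray, n_transitions: int) -> np.ndarray:
    """Midpoints from the two largest steps of a smoothed derivative."""
    if y.size >= 5:
        kernel = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        kernel /= kernel.sum()
        ys = np.convolve(np.pad(y, 2, mode="edge"), kernel, mode="valid")
    else:
        ys = y
    dy = np.gradient(ys, u)
    span = float(u[-1] - u[0])
    # exclude the endpoints, where the gradient is one-sided
    interior = np.arange(1, u.size - 1)
    order = interior[np.argsort(np.abs(dy[interior]))[::-1]]
    c_a = u[order[0]]
    # second midpoint: next-largest step at a separated urea concentration
    min_gap = max(1.0, span / 8.0)
    c_b = None
    for idx in order[1:]:
        if abs(u[idx] - c_a) >= min_gap:
            c_b = u[idx]
            break
    if c_b is None:
        c_b = min(c_a + max(span / 3.0, 0.5), u[-1])
    c1, c2 = sorted((float(c_a), float(c_b)))
    y0, a_tot = float(ys[0]), float(ys[-1] - ys[0])
    if a_tot == 0.0:
        a_tot = float(np.ptp(y)) or 1.0
    if n_transitions == 1:
        return np.array([y0, a_tot, c1, 0.3])
    # amplitude split from the signal level midway between the two midpoints
    y_mid = float(np.interp(0.5 * (c1 + c2), u, ys))
    p0 = (y_mid - y0) / a_tot if a_tot != 0 else 0.5
    p0 = float(np.clip(p0, 0.1, 0.9))
    return np.array([y0, a_tot, p0, c1, c2, 0.3, 0.3])


def fit_transition(
    curve: TransitionCurve,
    n_transitions: int = 2,
    init: DoubleBoltzmannParams | None = None,
) -> TransitionFit:
    """Least-squares double-Boltzmann fit with ordered midpoints.

    Non-convergence (including effectively constant signal) is flagged on the
    result rather than raised.  A two-transition fit whose amplitude fraction
    collapses to one transition (p < 0.05 or p > 0.95) records a warning.
    """
    if n_transitions not in (1, 2):
        raise DomainError("n_transitions must be 1 or 2")
    u, y = curve.denaturant, curve.signal
    n_par = 4 if n_transitions == 1 else 7
    if u.size < n_par + 1:
        raise DomainError(
            f"{u.size} points cannot constrain {n_par} parameters"
        )
    record: list[str] = []

    scale = float(np.ptp(y))
    if scale == 0.0 or np.ptp(u) == 0.0 or scale < 1e-12 * max(abs(y).max(), 1.0):
        params = DoubleBoltzmannParams(
            float(y.mean()), 0.0, 0.5, float(u.mean()),
            float(u.mean()) + 1.0, 0.3, 0.3,
        )
        return TransitionFit(
            params, None, False, 0.0, u.size,
            warnings=["signal is constant; nothing to fit"],
            message="degenerate input",
        )

    span = float(u[-1] - u[0])
    if n_transitions == 1:
        def unpack(x):
            y0, a, c1, k1 = x
            return DoubleBoltzmannParams(y0, a, 1.0, c1, c1 + span, k1, k1)
        lb = [-np.inf, -np.inf, u[0] - span, 1e-3]
        ub = [np.inf, np.inf, u[-1] + span, 10.0 * span]
        x0 = _initial_guess(u, y, 1)
        names = ["y0", "A", "c1", "k1"]
    else:
        def unpack(x):
            y0, a, p, c1, c2, k1, k2 = x
            return DoubleBoltzmannParams(y0, a, p, c1, c2, k1, k2)
        lb = [-np.inf, -np.inf, 0.0, u[0] - span, u[0] - span, 1e-3, 1e-3]
        ub = [np.inf, np.inf, 1.0, u[-1] + span, u[-1] + span, 10 * span, 10 * span]
        if init is not None:
            x0 = np.array([init.y0, init.A, init.p, init.c1, init.c2,
                           init.k1, init.k2])
        else:
            x0 = _initial_guess(u, y, 2)
        names = ["y0", "A", "p", "c1", "c2", "k1", "k2"]

    def residuals(x):
        return double_boltzmann(u, unpack(x)) - y

    # deterministic multi-start: derivative-based guess plus evenly spaced
    # midpoints guard against local minima on noisy curves
    starts = [np.clip(x0, lb, ub)]
    if n_transitions == 2:
        y0_g, a_g = x0[0], x0[1]
        for frac1, frac2 in ((1 / 4, 2 / 3), (1 / 6, 1 / 2), (1 / 3, 3 / 4)):
            alt = np.array([y0_g, a_g, 0.5, u[0] + frac1 * span,
                            u[0] + frac2 * span, 0.3, 0.3])
            starts.append(np.clip(alt, lb, ub))

    sol = None
    for start in starts:
        trial = least_squares(residuals, start, bounds=(lb, ub), xtol=1e-14,
                              ftol=1e-14, max_nfev=5000)
        if sol is None or trial.cost < sol.cost:
            sol = trial
    params = unpack(sol.x).ordered()
    chi2 = 2.0 * sol.cost
    converged = bool(sol.status > 0)
    if not converged:
        record.append(f"optimizer did not converge: {sol.message}")

    if n_transitions == 2 and (params.p < 0.05 or params.p > 0.95):
        record.append(
            f"amplitude fraction p = {params.p:.3f}: the data may contain only "
            "a single transition"
        )

    stderr = None
    dof = max(u.size - len(sol.x), 1)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * (chi2 / dof)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        stderr = dict(zip(names, se.tolist()))
    except np.linalg.LinAlgError:
        record.append("covariance singular; standard errors unavailable")

    return TransitionFit(
        params=params, stderr=stderr, converged=converged, chi2=float(chi2),
        n_points=u.size, warnings=record, message=sol.message,
    )


def thermo_from_fit(
    params: DoubleBoltzmannParams,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> ThermoParams:
    """Two-state linear-extrapolation mapping: m_i = RT/k_i, dG = m_i * c_i."""
    if params.k1 <= 0 or params.k2 <= 0:
        raise DomainError("transition widths must be positive")
    if temperature <= 0:
        raise DomainError("temperature must be positive (kelvin)")
    rt = GAS_CONSTANT_KJ * temperature
    m1, m2 = rt / params.k1, rt / params.k2
    return ThermoParams(
        m_values=(m1, m2),
        dG_H2O=(m1 * params.c1, m2 * params.c2),
        fractions=(params.p, 1.0 - params.p),
        temperature=temperature,
    )


def intensity_ratio(
    spectrum: SteadyStateSpectrum,
    numerator_nm: float = 320.0,
    denominator_nm: float = 360.0,
) -> float:
    """Spectral-shift parameter I320/I360 by linear interpolation.

    Returns NaN when the denominator intensity is zero.
    """
    i_num = float(spectrum.at(numerator_nm)[0])
    i_den = float(spectrum.at(denominator_nm)[0])
    if i_den == 0.0:
        return float("nan")
    return i_num / i_den
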