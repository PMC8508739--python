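"""Multi-exponential TCSPC decay analysis with IRF reconvolution.

The observed photon histogram at each emission wavelength is modelled as

    I(t) = S(t) ⊗ sum_i alpha_i exp(-t / tau_i) + b

where ``S`` is the measured instrument response (area-normalised, with an
optional fractional-channel shift) and ``b`` a flat background.  A global fit
shares the lifetimes ``tau_i`` across all wavelengths while the amplitudes
``alpha_i(lambda)`` and backgrounds stay free per trace; the spectral fraction
of component ``i`` at wavelength ``lambda`` is

    f_i(lambda) = alpha_i(lambda) tau_i / sum_j alpha_j(lambda) tau_j

and the decay-associated spectra partition the steady-state emission spectrum
as ``I_i(lambda) = f_i(lambda) I_ss(lambda)``.

Fitting uses Poisson (Neyman) weights ``1/max(counts, 1)`` and variable
projection: for trial lifetimes the amplitudes/backgrounds are solved per
trace by non-negative weighted least squares, and only the lifetimes (and
optional IRF shift) are iterated by damped least squares with a seeded
multi-start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .errors import DomainError, GridError, InsufficientDataError, RangeError

__all__ = [
    "DecayTrace",
    "InstrumentResponse",
    "MultiExpModel",
    "GlobalFitResult",
    "SteadyStateSpectrum",
    "DecayAssociatedSpectra",
    "convolve_decay",
    "fit_single_decay",
    "global_fit",
    "spectral_fractions",
    "decay_associated_spectra",
]

DEFAULT_CHANNEL_WIDTH_NS = 0.027  # instrument time resolution, ns/channel


@dataclass(frozen=True)
class DecayTrace:
    """Photon-count histogram at one emission wavelength."""

    wavelength: float  # nm
    counts: np.ndarray  # photon counts per channel, >= 0
    channel_width: float = DEFAULT_CHANNEL_WIDTH_NS  # ns

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 2:
            raise DomainError("a decay trace needs at least 2 channels")
        if np.any(counts < 0):
            raise DomainError("photon counts must be non-negative")
        if not self.channel_width > 0:
            raise DomainError("channel width must be positive")
        object.__setattr__(self, "counts", counts.astype(float))

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.channel_width


@dataclass(frozen=True)
class InstrumentResponse:
    """Measured instrument response histogram on the traces' channel grid."""

    counts: np.ndarray
    channel_width: float = DEFAULT_CHANNEL_WIDTH_NS  # ns
    shift: float = 0.0  # fractional-channel shift applied before use

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 2:
            raise DomainError("IRF needs at least 2 channels")
        if np.any(counts < 0):
            raise DomainError("IRF counts must be non-negative")
        if counts.sum() <= 0:
            raise DomainError("IRF must contain counts")
        if not self.channel_width > 0:
            raise DomainError("channel width must be positive")
        object.__setattr__(self, "counts", counts)

    def normalized(self, shift: float | None = None) -> np.ndarray:
        """Area-normalised IRF, linearly interpolated by ``shift`` channels."""
        s = self.counts
        delta = self.shift if shift is None else shift
        if delta != 0.0:
            idx = np.arange(s.size, dtype=float)
            s = np.interp(idx - delta, idx, s, left=0.0, right=0.0)
        total = s.sum()
        if total <= 0:
            raise DomainError("IRF shift moved all counts out of the window")
        return s / total

    @property
    def peak_channel(self) -> int:
        return int(np.argmax(self.counts))


@dataclass(frozen=True)
class MultiExpModel:
    """Sum-of-exponentials decay model.

    ``amplitudes`` is ``(n_components,)`` for a single trace or
    ``(n_wavelengths, n_components)`` for a global model; ``background`` is a
    scalar or one value per wavelength (counts/channel).  Lifetimes are kept
    sorted descending so component 1 is always the longest-lived.
    """

    lifetimes: np.ndarray  # ns, sorted descending
    amplitudes: np.ndarray
    background: np.ndarray | float = 0.0
    wavelengths: np.ndarray | None = None  # nm, for global models

    def __post_init__(self):
        tau = np.asarray(self.lifetimes, dtype=float)
        amp = np.asarray(self.amplitudes, dtype=float)
        if np.any(tau <= 0):
            raise DomainError("all lifetimes must be positive")
        order = np.argsort(tau)[::-1]
        tau_sorted = tau[order]
        if amp.ndim == 1:
            if amp.size != tau.size:
                raise DomainError("amplitude vector length must match n_components")
            amp_sorted = amp[order]
        elif amp.ndim == 2:
            if amp.shape[1] != tau.size:
                raise DomainError("amplitude matrix must have n_components columns")
            amp_sorted = amp[:, order]
        else:
            raise DomainError("amplitudes must be 1- or 2-dimensional")
        bg = np.asarray(self.background, dtype=float)
        if np.any(bg < 0):
            raise DomainError("background must be non-negative")
        object.__setattr__(self, "lifetimes", tau_sorted)
        object.__setattr__(self, "amplitudes", amp_sorted)
        object.__setattr__(self, "background", bg if bg.ndim else float(bg))
        if self.wavelengths is not None:
            object.__setattr__(
                self, "wavelengths", np.asarray(self.wavelengths, dtype=float)
            )

    @property
    def n_components(self) -> int:
        return self.lifetimes.size


@dataclass
class GlobalFitResult:
    """Outcome of a (global) reconvolution fit."""

    model: MultiExpModel
    chi2_global: float
    chi2_reduced: float
    weighted_residuals: list[np.ndarray]
    covariance: np.ndarray | None  # of the nonlinear parameters (log-lifetimes[, shift])
    converged: bool
    n_data: int
    n_free: int
    irf_shift: float = 0.0
    lifetime_stderr: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)
    message: str = ""

    @property
    def tau3_reliable(self) -> bool:
        """Shortest lifetime flagged unreliable below 1.5x the channel width."""
        return bool(self.model.lifetimes[-1] >= 1.5 * _model_channel_width(self))


def _model_channel_width(fit: GlobalFitResult) -> float:
    return getattr(fit, "_channel_width", DEFAULT_CHANNEL_WIDTH_NS)


@dataclass(frozen=True)
class SteadyStateSpectrum:
    """Steady-state emission spectrum (arbitrary intensity units)."""

    wavelengths: np.ndarray  # nm, strictly increasing
    intensities: np.ndarray  # >= 0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        if wl.shape != inten.shape or wl.ndim != 1:
            raise DomainError("wavelengths and intensities must be 1D, same length")
        if np.any(np.diff(wl) <= 0):
            raise DomainError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise DomainError("intensities must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", inten)

    def at(self, wavelength_nm: np.ndarray | float) -> np.ndarray:
        wl = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
        if wl.min() < self.wavelengths[0] or wl.max() > self.wavelengths[-1]:
            raise RangeError(
                f"wavelength outside spectrum range "
                f"[{self.wavelengths[0]}, {self.wavelengths[-1]}] nm"
            )
        return np.interp(wl, self.wavelengths, self.intensities)


@dataclass
class DecayAssociatedSpectra:
    """Partition of the steady-state spectrum among lifetime components."""

    wavelengths: np.ndarray  # nm
    fractions: np.ndarray  # f_i(lambda), shape (n_wl, n_comp)
    component_spectra: np.ndarray  # I_i(lambda), same shape
    mean_fractions: np.ndarray  # f_i, unweighted mean over wavelengths


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def convolve_decay(
    model: MultiExpModel,
    irf: InstrumentResponse,
    n_channels: int,
    channel_width: float | None = None,
    shift: float | None = None,
) -> np.ndarray:
    """Expected counts per channel: IRF ⊗ multi-exponential plus background.

    The IRF histogram is area-normalised (after the optional fractional-channel
    shift) and discretely convolved with the exponentials sampled at channel
    centres; with channel widths small against the lifetimes this matches the
    continuous convolution to well under 0.1%.
    """
    dt = irf.channel_width if channel_width is None else channel_width
    if channel_width is not None and not np.isclose(irf.channel_width, channel_width):
        raise GridError(
            f"IRF channel width {irf.channel_width} ns does not match "
            f"trace channel width {channel_width} ns"
        )
    amp = np.atleast_1d(np.asarray(model.amplitudes, dtype=float))
    if amp.ndim != 1:
        raise DomainError("convolve_decay expects a single-trace model")
    basis = _convolved_basis(model.lifetimes, irf, n_channels, shift=shift)
    bg = float(np.atleast_1d(model.background)[0])
    return basis @ amp + bg


def _convolved_basis(
    lifetimes: np.ndarray,
    irf: InstrumentResponse,
    n_channels: int,
    shift: float | None = None,
) -> np.ndarray:
    """Columns = unit-amplitude exponentials convolved with the normalised IRF."""
    if np.any(np.asarray(lifetimes) <= 0):
        raise DomainError("all lifetimes must be positive")
    s = irf.normalized(shift=shift)
    if s.size < n_channels:
        s = np.pad(s, (0, n_channels - s.size))
    s = s[:n_channels]
    dt = irf.channel_width
    t = np.arange(n_channels) * dt
    cols = np.empty((n_channels, len(lifetimes)))
    for i, tau in enumerate(np.asarray(lifetimes, dtype=float)):
        decay = np.exp(-t / tau)
        # treat the IRF mass of each channel as uniform across the bin and
        # integrate the exponential over it analytically; the j = k bin only
        # contributes its causal half
        full_bin = (tau / dt) * 2.0 * np.sinh(dt / (2.0 * tau))
        half_bin = (tau / dt) * (1.0 - np.exp(-dt / (2.0 * tau)))
        cols[:, i] = (
            full_bin * np.convolve(s, decay)[:n_channels]
            + (half_bin - full_bin) * s
        )
    return cols


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _fit_window(
    trace: DecayTrace, irf: InstrumentResponse, window: tuple[int, int] | None
) -> tuple[int, int]:
    """Default window: IRF peak - 5 to the last channel with >= 1 count."""
    if window is not None:
        lo, hi = window
    else:
        lo = max(irf.peak_channel - 5, 0)
        nz = np.nonzero(trace.counts >= 1)[0]
        hi = int(nz[-1]) + 1 if nz.size else trace.n_channels
    if hi - lo < 4:
        raise InsufficientDataError("fit window too short")
    return lo, hi


def _solve_linear(
    basis: np.ndarray,
    counts: np.ndarray,
    weights: np.ndarray,
    fit_background: bool,
    fixed_background: float,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Weighted NNLS for amplitudes (and background); returns weighted residuals."""
    w = np.sqrt(weights)
    if fit_background:
        a_mat = np.column_stack([basis, np.ones(basis.shape[0])])
        y = counts
    else:
        a_mat = basis
        y = counts - fixed_background
    coef, _ = nnls(a_mat * w[:, None], y * w)
    if fit_background:
        amps, bg = coef[:-1], float(coef[-1])
    else:
        amps, bg = coef, fixed_background
    resid = w * (basis @ amps + bg - counts)
    return amps, bg, resid


def _multistart_lifetimes(
    n_components: int,
    t_span: float,
    channel_width: float,
    init: np.ndarray | None,
    n_starts: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    starts = []
    if init is not None:
        starts.append(np.sort(np.asarray(init, dtype=float))[::-1])
    # geometric spread across the observable range as the deterministic start
    lo, hi = 1.5 * channel_width, max(t_span / 3.0, 3.0 * channel_width)
    starts.append(np.geomspace(hi, lo, n_components))
    while len(starts) < n_starts:
        taus = np.exp(rng.uniform(np.log(lo), np.log(hi), n_components))
        starts.append(np.sort(taus)[::-1])
    return starts[:n_starts]


def global_fit(
    traces: list[DecayTrace],
    irf: InstrumentResponse,
    n_components: int = 3,
    init: MultiExpModel | None = None,
    fit_shift: bool = False,
    fit_background: bool = True,
    window: tuple[int, int] | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> GlobalFitResult:
    """Global reconvolution fit with lifetimes shared across wavelengths.

    Amplitudes and backgrounds are profiled out per trace by weighted NNLS
    (variable projection); the lifetimes (log-parameterised) and optionally an
    IRF fractional-channel shift are optimised by damped least squares from
    ``n_starts`` seeded starting points, keeping the lowest global chi^2.
    Non-convergence is reported on the result, not raised.
    """
    if not 1 <= n_components <= 4:
        raise DomainError("n_components must be in 1..4")
    if len(traces) < 1:
        raise DomainError("need at least one trace")
    for tr in traces:
        if not np.isclose(tr.channel_width, irf.channel_width):
            raise GridError(
                f"trace at {tr.wavelength} nm: channel width {tr.channel_width} "
                f"!= IRF {irf.channel_width}"
            )
        if tr.n_channels != traces[0].n_channels:
            raise GridError("all traces must share one channel grid")
    peak = max(float(tr.counts.max()) for tr in traces)
    if peak < 10:
        raise InsufficientDataError(
            f"peak count {peak:.0f} too low to fit (need >= 10; >= 100 recommended)"
        )

    n_channels = traces[0].n_channels
    dt = irf.channel_width
    windows = [_fit_window(tr, irf, window) for tr in traces]
    counts_w = [tr.counts[lo:hi] for tr, (lo, hi) in zip(traces, windows)]
    weights_w = [1.0 / np.maximum(c, 1.0) for c in counts_w]  # Neyman weights

    record: list[str] = []
    t_span = n_channels * dt
    rng = np.random.default_rng(seed)
    init_taus = init.lifetimes if init is not None else None
    starts = _multistart_lifetimes(n_components, t_span, dt, init_taus, n_starts, rng)

    # keep lifetimes in a sane positive range even when a bad start pushes
    # log-lifetimes toward +/- infinity during line search
    log_lo, log_hi = np.log(0.01 * dt), np.log(100.0 * t_span)

    def residuals(theta: np.ndarray) -> np.ndarray:
        taus = np.exp(np.clip(theta[:n_components], log_lo, log_hi))
        shift = theta[n_components] if fit_shift else 0.0
        basis_full = _convolved_basis(taus, irf, n_channels, shift=shift)
        out = []
        for (lo, hi), c, w in zip(windows, counts_w, weights_w):
            _, _, r = _solve_linear(basis_full[lo:hi], c, w, fit_background, 0.0)
            out.append(r)
        return np.concatenate(out)

    best = None
    for taus0 in starts:
        theta0 = np.log(np.clip(taus0, 0.3 * dt, None))
        if fit_shift:
            theta0 = np.append(theta0, 0.0)
        try:
            sol = least_squares(
                residuals, theta0, method="lm" if not fit_shift else "trf",
                xtol=1e-12, ftol=1e-12, max_nfev=400 * (n_components + 1),
            )
        except Exception as exc:  # pragma: no cover - optimizer edge cases
            record.append(f"start {taus0}: optimizer failure: {exc}")
            continue
        cost = 2.0 * sol.cost
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise InsufficientDataError("all optimizer starts failed")
    chi2, sol = best

    taus = np.exp(np.clip(sol.x[:n_components], log_lo, log_hi))
    shift = float(sol.x[n_components]) if fit_shift else 0.0
    basis_full = _convolved_basis(taus, irf, n_channels, shift=shift)
    amps = np.zeros((len(traces), n_components))
    bgs = np.zeros(len(traces))
    resids = []
    for k, ((lo, hi), c, w) in enumerate(zip(windows, counts_w, weights_w)):
        a, b, r = _solve_linear(basis_full[lo:hi], c, w, fit_background, 0.0)
        amps[k], bgs[k] = a, b
        resids.append(r)

    order = np.argsort(taus)[::-1]
    taus, amps = taus[order], amps[:, order]

    ratios = taus[:-1] / taus[1:]
    if np.any(ratios < 1.05):
        record.append(
            "degenerate lifetimes: adjacent estimates within 5% of each other"
        )
    if taus[-1] < 1.5 * dt:
        record.append(
            f"tau_{n_components} = {taus[-1]:.4g} ns is below 1.5x the channel "
            f"width ({1.5 * dt:.4g} ns) and should be considered unreliable"
        )

    n_data = sum(hi - lo for lo, hi in windows)
    n_free = (
        n_components
        + (1 if fit_shift else 0)
        + len(traces) * (n_components + (1 if fit_background else 0))
    )
    dof = max(n_data - n_free, 1)

    cov = None
    tau_se = None
    try:
        jtj = sol.jac.T @ sol.jac
        cov_theta = np.linalg.inv(jtj) * (chi2 / dof)
        cov = cov_theta
        # delta method: tau = exp(theta)
        tau_se_full = np.sqrt(np.diag(cov_theta)[:n_components]) * np.exp(
            sol.x[:n_components]
        )
        tau_se = tau_se_full[order]
    except np.linalg.LinAlgError:
        record.append("covariance singular; standard errors unavailable")

    converged = bool(sol.status > 0)
    if not converged:
        record.append(f"optimizer did not converge: {sol.message}")

    model = MultiExpModel(
        lifetimes=taus,
        amplitudes=amps,
        background=bgs,
        wavelengths=np.array([tr.wavelength for tr in traces]),
    )
    result = GlobalFitResult(
        model=model,
        chi2_global=float(chi2),
        chi2_reduced=float(chi2 / dof),
        weighted_residuals=resids,
        covariance=cov,
        converged=converged,
        n_data=n_data,
        n_free=n_free,
        irf_shift=shift,
        lifetime_stderr=tau_se,
        warnings=record,
        message=sol.message,
    )
    result._channel_width = dt
    for msg in record:
        warnings.warn(msg, stacklevel=2)
    return result


def fit_single_decay(
    trace: DecayTrace,
    irf: InstrumentResponse,
    n_components: int = 3,
    init: MultiExpModel | None = None,
    **kwargs,
) -> GlobalFitResult:
    """Reconvolution fit of one trace (a one-trace global fit)."""
    return global_fit([trace], irf, n_components=n_components, init=init, **kwargs)


# ---------------------------------------------------------------------------
# Decay-associated spectra
# ---------------------------------------------------------------------------

def spectral_fractions(fit: GlobalFitResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavelength fractions f_i(lambda) = alpha_i tau_i / sum_j alpha_j tau_j.

    Returns ``(f_ilambda, f_i)`` where ``f_i`` is the unweighted mean over
    wavelengths.  Wavelengths where all amplitudes vanish yield NaN rows and
    are excluded from the means.
    """
    if not fit.converged:
        raise DomainError("spectral fractions require a converged fit")
    amps = np.atleast_2d(fit.model.amplitudes)
    contrib = amps * fit.model.lifetimes[None, :]
    totals = contrib.sum(axis=1)
    frac = np.full_like(contrib, np.nan)
    ok = totals > 0
    frac[ok] = contrib[ok] / totals[ok, None]
    if not np.all(ok):
        warnings.warn(
            "all-zero amplitudes at some wavelengths; fractions reported missing",
            stacklevel=2,
        )
    mean_frac = np.nanmean(frac, axis=0)
    return frac, mean_frac


def decay_associated_spectra(
    fractions: np.ndarray,
    wavelengths: np.ndarray,
    spectrum: SteadyStateSpectrum,
) -> DecayAssociatedSpectra:
    """Partition the steady-state spectrum: I_i(lambda) = f_i(lambda) I_ss(lambda)."""
    frac = np.atleast_2d(np.asarray(fractions, dtype=float))
    wl = np.asarray(wavelengths, dtype=float)
    if frac.shape[0] != wl.size:
        raise DomainError("fractions and wavelengths disagree in length")
    iss = spectrum.at(wl)
    comp = frac * iss[:, None]
    mean_frac = np.nanmean(frac, axis=0)
    return DecayAssociatedSpectra(
        wavelengths=wl,
        fractions=frac,
        component_spectra=comp,
        mean_fractions=mean_frac,
    )
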