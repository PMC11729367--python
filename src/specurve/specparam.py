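"""Spectral parameterization of power spectra into aperiodic and periodic parts.

A power spectrum (in log10 power) is modeled as the sum of an aperiodic
Lorentzian component

    L(F) = b - log10(k + F**chi)

(offset ``b``, optional knee ``k``, exponent ``chi``) and N oscillatory peaks,
each a Gaussian in log10-power over linear frequency.  The fitting procedure
follows the iterative robust scheme of the FOOOF / specparam family:

1. robust two-pass aperiodic fit,
2. iterative extraction of Gaussian peak guesses from the flattened spectrum,
3. joint bounded least-squares refit of all Gaussians,
4. aperiodic refit on the peak-removed spectrum,
5. goodness of fit (MAE and R^2) of the full model.

The estimator :class:`SpectralFit` exposes this with a scikit-learn style
``fit`` API; the module-level functions are thin wrappers used by the
pipeline code.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike
from sklearn.base import BaseEstimator

from . import _solvers

__all__ = [
    "AperiodicParams",
    "Peak",
    "FitDiagnostics",
    "SpectralFit",
    "evaluate_aperiodic",
    "fit_aperiodic",
    "fit_spectrum",
    "goodness_of_fit",
    "exponent_for_subject",
]


@dataclass(frozen=True)
class AperiodicParams:
    """Aperiodic (Lorentzian) parameters; ``knee is None`` means fixed mode."""

    offset: float
    exponent: float
    knee: float | None = None

    def __post_init__(self) -> None:
        if self.knee is not None and self.knee < 0:
            raise ValueError(f"knee must be >= 0, got {self.knee}")

    @property
    def mode(self) -> str:
        return "fixed" if self.knee is None else "knee"


@dataclass(frozen=True)
class Peak:
    """One Gaussian peak: center (Hz), height (log10 power), width (Hz, SD)."""

    center: float
    height: float
    width: float


@dataclass(frozen=True)
class FitDiagnostics:
    mae: float
    r_squared: float


def evaluate_aperiodic(params: AperiodicParams, freqs: ArrayLike) -> np.ndarray:
    """Evaluate L(F) = b - log10(k + F**chi) at the given frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any(freqs <= 0):
        raise ValueError("frequencies must be strictly positive")
    knee = 0.0 if params.knee is None else params.knee
    return params.offset - np.log10(knee + freqs**params.exponent)


def _gaussian(freqs: np.ndarray, center: float, height: float, width: float) -> np.ndarray:
    return height * np.exp(-((freqs - center) ** 2) / (2.0 * width**2))


def _peaks_model(freqs: np.ndarray, peaks: Sequence[Peak]) -> np.ndarray:
    out = np.zeros_like(freqs, dtype=float)
    for p in peaks:
        out += _gaussian(freqs, p.center, p.height, p.width)
    return out


def goodness_of_fit(model_log10: ArrayLike, data_log10: ArrayLike) -> FitDiagnostics:
    """MAE and R^2 of a model against data, both in log10 power."""
    model = np.asarray(model_log10, dtype=float)
    data = np.asarray(data_log10, dtype=float)
    if model.shape != data.shape or data.size < 2:
        raise ValueError("model and data must have equal length >= 2")
    resid = data - model
    ss_tot = float(np.sum((data - data.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for constant data")
    mae = float(np.mean(np.abs(resid)))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return FitDiagnostics(mae=mae, r_squared=r2)


class FitError(RuntimeError):
    """Internal signal that a solver stage failed; callers map it to converged=False."""


def _fit_fixed(freqs: np.ndarray, log_power: np.ndarray) -> tuple[float, float]:
    """Exact least-squares fit of b - chi*log10(F); linear in (b, chi)."""
    logf = np.log10(freqs)
    design = np.column_stack([np.ones_like(logf), -logf])
    coef, *_ = np.linalg.lstsq(design, log_power, rcond=None)
    return float(coef[0]), float(coef[1])


_LN10 = math.log(10.0)


def _fit_knee(
    freqs: np.ndarray,
    log_power: np.ndarray,
    p0: tuple[float, float, float],
    f_hi: float,
    xtol: float,
    maxfev: int,
) -> tuple[float, float, float]:
    """Knee-mode Lorentzian fit via variable projection.

    The offset enters linearly, so for any (k, chi) the optimal offset is
    b* = mean(y + log10(k + F**chi)); the remaining 2-D problem in
    (log k, chi) is solved with Levenberg-Marquardt.  A fit whose knee runs
    beyond f_hi**3 (or that exhausts the solver budget) is reported as
    non-convergence.
    """
    y = np.ascontiguousarray(log_power, dtype=float)
    freqs = np.ascontiguousarray(freqs, dtype=float)
    yc = y - y.mean()
    logf = np.log(freqs)
    u_hi = 3.0 * math.log(f_hi)
    u0 = math.log(max(p0[1], 1e-12))

    u_lo = -30.0  # k = e^-30, numerically a zero knee
    u0 = max(min(u0, u_hi), u_lo)
    u, chi, ok = _solvers.knee_lm(
        freqs, yc, logf, u0, p0[2], u_lo, u_hi, -20.0, 20.0, xtol, maxfev
    )
    if not ok or not (np.isfinite(u) and np.isfinite(chi)):
        raise FitError("knee-mode aperiodic fit did not converge")
    # the knee model nests the kneeless one; if the first basin is worse
    # than a zero-knee straight line, restart from that nested solution
    chi_fixed = _fit_fixed(freqs, log_power)[1]

    def cost_at(uu, cc):
        r = _solvers._knee_resid(freqs, yc, uu, cc)
        return float(r @ r)

    if cost_at(u, chi) > cost_at(u_lo, chi_fixed):
        u2, chi2, ok2 = _solvers.knee_lm(
            freqs, yc, logf, u_lo, chi_fixed, u_lo, u_hi, -20.0, 20.0, xtol, maxfev
        )
        if ok2 and cost_at(u2, chi2) < cost_at(u, chi):
            u, chi = u2, chi2
    k = math.exp(u)
    if k < 1e-9:  # numerically zero knee
        k = 0.0
    b = float(np.mean(y + np.log10(k + freqs**chi)))
    return b, k, float(chi)


def _aperiodic_simple(
    freqs: np.ndarray,
    log_power: np.ndarray,
    mode: str,
    f_hi: float,
    xtol: float,
    maxfev: int,
    seed_params: AperiodicParams | None = None,
) -> AperiodicParams:
    """Single-pass least-squares aperiodic fit (fixed mode is solved exactly)."""
    if mode == "fixed":
        b, chi = _fit_fixed(freqs, log_power)
        return AperiodicParams(offset=b, exponent=chi)
    if seed_params is None or seed_params.knee is None:
        b0, chi0 = _fit_fixed(freqs, log_power)
        k0 = float(np.median(freqs)) ** chi0
    else:
        b0, chi0, k0 = seed_params.offset, seed_params.exponent, seed_params.knee
    b, k, chi = _fit_knee(freqs, log_power, (b0, k0, chi0), f_hi, xtol, maxfev)
    return AperiodicParams(offset=b, exponent=chi, knee=k)


@dataclass
class SpectralModel:
    """Result of a full spectral parameterization."""

    aperiodic: AperiodicParams | None
    peaks: list[Peak]
    fit_range: tuple[float, float]
    diagnostics: FitDiagnostics | None
    converged: bool
    freqs: np.ndarray | None = None
    model_log10: np.ndarray | None = None

    def to_dict(self) -> dict:
        ap = self.aperiodic
        return {
            "offset": None if ap is None else ap.offset,
            "knee": None if ap is None else ap.knee,
            "exponent": None if ap is None else ap.exponent,
            "peaks": [
                {"center": p.center, "height": p.height, "width": p.width} for p in self.peaks
            ],
            "mae": None if self.diagnostics is None else self.diagnostics.mae,
            "r_squared": None if self.diagnostics is None else self.diagnostics.r_squared,
            "converged": self.converged,
            "fit_range": list(self.fit_range),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


class SpectralFit(BaseEstimator):
    """Scikit-learn style estimator for spectral parameterization.

    Parameters
    ----------
    f_min, f_max : float
        Frequency range (Hz) over which the model is fit.  Defaults follow
        the common preset for low-frequency aperiodic estimation (2-40 Hz).
    aperiodic_mode : {'fixed', 'knee'}
        Whether the Lorentzian includes the knee parameter.
    peak_width_limits : (float, float)
        Allowed Gaussian SD of peaks, in Hz.  The 1 Hz lower limit equals
        twice a 0.5 Hz frequency resolution.
    peak_threshold : float
        Detection threshold in SD units of the flattened spectrum.
    min_peak_height : float
        Absolute minimum peak height in log10 power.
    max_n_peaks : int or None
        Cap on the number of extracted peaks (None = unbounded).
    robust_percentile : float
        Percentile of positive flattened residuals kept for the robust
        second-pass aperiodic fit.
    xtol : float
        Solver relative tolerance.
    maxfev : int
        Solver function-evaluation budget; exhausting it flags
        ``converged_ = False`` rather than raising.

    Attributes
    ----------
    offset_, knee_, exponent_ : float
        Fitted aperiodic parameters (``knee_`` is None in fixed mode).
    peaks_ : list of Peak
    mae_, r_squared_ : float
    converged_ : bool
    """

    def __init__(
        self,
        f_min: float = 2.0,
        f_max: float = 40.0,
        aperiodic_mode: str = "fixed",
        peak_width_limits: tuple[float, float] = (1.0, 12.0),
        peak_threshold: float = 2.0,
        min_peak_height: float = 0.0,
        max_n_peaks: int | None = None,
        robust_percentile: float = 2.5,
        xtol: float = 1e-8,
        maxfev: int = 5000,
    ) -> None:
        self.f_min = f_min
        self.f_max = f_max
        self.aperiodic_mode = aperiodic_mode
        self.peak_width_limits = peak_width_limits
        self.peak_threshold = peak_threshold
        self.min_peak_height = min_peak_height
        self.max_n_peaks = max_n_peaks
        self.robust_percentile = robust_percentile
        self.xtol = xtol
        self.maxfev = maxfev

    # ------------------------------------------------------------------ fit

    def fit(self, freqs: ArrayLike, power: ArrayLike) -> "SpectralFit":
        """Fit the model to one power spectrum (linear power units)."""
        freqs = np.asarray(freqs, dtype=float)
        power = np.asarray(power, dtype=float)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be 1-D arrays of equal length")
        if self.aperiodic_mode not in ("fixed", "knee"):
            raise ValueError(f"unknown aperiodic_mode {self.aperiodic_mode!r}")
        mask = (freqs >= self.f_min) & (freqs <= self.f_max)
        if mask.sum() < 5:
            raise ValueError("need at least 5 frequency bins inside the fit range")
        f = freqs[mask]
        if np.any(power[mask] <= 0):
            raise ValueError("power must be strictly positive inside the fit range")
        y = np.log10(power[mask])

        self.freqs_ = f
        self.data_log10_ = y
        try:
            self._fit_stages(f, y)
            self.converged_ = True
        except FitError:
            self.aperiodic_ = None
            self.peaks_ = []
            self.offset_ = self.knee_ = self.exponent_ = None
            self.mae_ = self.r_squared_ = None
            self.model_log10_ = None
            self.converged_ = False
        return self

    def _robust_aperiodic(self, f: np.ndarray, y: np.ndarray) -> AperiodicParams:
        """Two-pass robust fit: seed fit, then refit on low-residual bins."""
        seed = _aperiodic_simple(
            f, y, self.aperiodic_mode, self.f_max, self.xtol, self.maxfev
        )
        flat = y - evaluate_aperiodic(seed, f)
        flat = np.clip(flat, 0.0, None)
        thresh = np.percentile(flat, self.robust_percentile)
        keep = flat <= thresh
        if keep.sum() < 5:
            return seed
        return _aperiodic_simple(
            f[keep], y[keep], self.aperiodic_mode, self.f_max,
            self.xtol, self.maxfev, seed_params=seed,
        )

    def _extract_peaks(self, f: np.ndarray, flat: np.ndarray) -> list[Peak]:
        """Iteratively pull Gaussian guesses from the flattened spectrum.

        The detection threshold is peak_threshold * SD of the flattened
        spectrum as it stood before any peak removal: a fixed noise scale,
        so extraction terminates once the remaining maxima fall below it.
        """
        guesses: list[Peak] = []
        flat = flat.copy()
        lo_w, hi_w = self.peak_width_limits
        cap = self.max_n_peaks if self.max_n_peaks is not None else f.size
        # 1e-9 log10 units is a numerical floor against spurious peaks on
        # residuals that are zero to machine precision
        threshold = max(self.peak_threshold * float(np.std(flat)), self.min_peak_height, 1e-9)
        while len(guesses) < cap:
            i = int(np.argmax(flat))  # argmax takes the lowest index on ties
            height = float(flat[i])
            if height <= threshold:
                break
            center = float(f[i])
            half = height / 2.0
            width = self._width_from_half_max(f, flat, i, half)
            width = float(np.clip(width, lo_w, hi_w))
            guesses.append(Peak(center=center, height=height, width=width))
            flat -= _gaussian(f, center, height, width)
        return guesses

    def _width_from_half_max(
        self, f: np.ndarray, flat: np.ndarray, i: int, half: float
    ) -> float:
        left = None
        for j in range(i - 1, -1, -1):
            if flat[j] <= half:
                left = f[i] - f[j]
                break
        right = None
        for j in range(i + 1, f.size):
            if flat[j] <= half:
                right = f[j] - f[i]
                break
        if left is None and right is None:
            return 0.5 * (self.peak_width_limits[0] + self.peak_width_limits[1])
        if left is None:
            hwhm = right
        elif right is None:
            hwhm = left
        else:
            hwhm = 0.5 * (left + right)
        # FWHM -> Gaussian SD
        return float(2.0 * hwhm / 2.3548200450309493)

    def _refit_peaks(self, f: np.ndarray, flat: np.ndarray, guesses: list[Peak]) -> list[Peak]:
        if not guesses:
            return []
        lo_w, hi_w = self.peak_width_limits
        p0, lo, hi = [], [], []
        for g in guesses:
            p0 += [g.center, g.height, g.width]
            # center constrained near its guess (2 SD) so neighbouring
            # Gaussians cannot collapse onto each other during the refit
            lo += [max(self.f_min, g.center - 2.0 * g.width), 0.0, lo_w]
            hi += [min(self.f_max, g.center + 2.0 * g.width), np.inf, hi_w]
        lo = np.asarray(lo, dtype=float)
        hi = np.asarray(hi, dtype=float)
        p0 = np.clip(np.asarray(p0, dtype=float), lo, hi)
        popt, ok = _solvers.gauss_lm(
            np.ascontiguousarray(f, dtype=float),
            np.ascontiguousarray(flat, dtype=float),
            p0, lo, hi, self.xtol, self.maxfev,
        )
        if not ok or not np.all(np.isfinite(popt)):
            raise FitError("joint Gaussian refit failed")
        return [
            Peak(center=float(c), height=float(h), width=float(w))
            for c, h, w in zip(popt[0::3], popt[1::3], popt[2::3])
        ]

    def _fit_stages(self, f: np.ndarray, y: np.ndarray) -> None:
        robust = self._robust_aperiodic(f, y)
        flat = y - evaluate_aperiodic(robust, f)
        guesses = self._extract_peaks(f, flat)
        peaks = self._refit_peaks(f, flat, guesses)
        peak_model = _peaks_model(f, peaks)
        final_ap = _aperiodic_simple(
            f, y - peak_model, self.aperiodic_mode, self.f_max,
            self.xtol, self.maxfev, seed_params=robust,
        )
        model = evaluate_aperiodic(final_ap, f) + peak_model

        self.aperiodic_ = final_ap
        self.offset_ = final_ap.offset
        self.knee_ = final_ap.knee
        self.exponent_ = final_ap.exponent
        self.peaks_ = peaks
        self.model_log10_ = model
        diag = goodness_of_fit(model, y)
        self.mae_ = diag.mae
        self.r_squared_ = diag.r_squared

    # -------------------------------------------------------------- helpers

    def result_(self) -> SpectralModel:
        """Package fitted state as a :class:`SpectralModel` record."""
        if not hasattr(self, "converged_"):
            raise RuntimeError("estimator is not fitted")
        if not self.converged_:
            return SpectralModel(
                aperiodic=None, peaks=[], fit_range=(self.f_min, self.f_max),
                diagnostics=None, converged=False,
            )
        return SpectralModel(
            aperiodic=self.aperiodic_,
            peaks=list(self.peaks_),
            fit_range=(self.f_min, self.f_max),
            diagnostics=FitDiagnostics(mae=self.mae_, r_squared=self.r_squared_),
            converged=True,
            freqs=self.freqs_,
            model_log10=self.model_log10_,
        )


# ----------------------------------------------------------- function wrappers


def fit_aperiodic(
    freqs: ArrayLike,
    power: ArrayLike,
    fit_range: tuple[float, float] = (2.0, 40.0),
    mode: str = "fixed",
    **settings,
) -> AperiodicParams:
    """Robust two-pass aperiodic fit (no peak modeling)."""
    est = SpectralFit(f_min=fit_range[0], f_max=fit_range[1], aperiodic_mode=mode, **settings)
    freqs = np.asarray(freqs, dtype=float)
    power = np.asarray(power, dtype=float)
    mask = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    if mask.sum() < 5:
        raise ValueError("need at least 5 frequency bins inside the fit range")
    return est._robust_aperiodic(freqs[mask], np.log10(power[mask]))


def fit_spectrum(
    freqs: ArrayLike,
    power: ArrayLike,
    fit_range: tuple[float, float] = (2.0, 40.0),
    mode: str = "fixed",
    **settings,
) -> SpectralModel:
    """Full parameterization; solver failure yields converged=False, not an error."""
    est = SpectralFit(f_min=fit_range[0], f_max=fit_range[1], aperiodic_mode=mode, **settings)
    est.fit(freqs, power)
    return est.result_()


def exponent_for_subject(
    region_spectra: Sequence[tuple[ArrayLike, ArrayLike]],
    avg_psd: bool = True,
    fit_range: tuple[float, float] = (2.0, 40.0),
    mode: str = "fixed",
    **settings,
) -> tuple[float, bool]:
    """One exponent per subject from several region spectra.

    ``avg_psd=True`` averages the linear power spectra and fits once;
    ``avg_psd=False`` fits each location and averages the exponents.  A
    non-converging fit anywhere flags the subject (exponent = nan).
    """
    if len(region_spectra) == 0:
        raise ValueError("need at least one region spectrum")
    if avg_psd:
        from .spectral import average_region

        freqs, power = average_region(region_spectra)
        model = fit_spectrum(freqs, power, fit_range=fit_range, mode=mode, **settings)
        if not model.converged:
            return float("nan"), False
        return model.aperiodic.exponent, True
    exps = []
    for freqs, power in region_spectra:
        model = fit_spectrum(freqs, power, fit_range=fit_range, mode=mode, **settings)
        if not model.converged:
            return float("nan"), False
        exps.append(model.aperiodic.exponent)
    return float(np.mean(exps)), True
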