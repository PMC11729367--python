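"""Epoching and power-spectral-density estimation.

Continuous source-level signals are cut into overlapping epochs (2 s or 5 s,
50 % overlap) and the PSD is estimated per epoch with either a set of DPSS
(Slepian) multitapers with a configurable half-bandwidth smoothing, or a
single Hann taper; the final spectrum is the mean over tapers and epochs.

Conventions: per-epoch mean removal before tapering, one-sided spectra with
the standard 2x scaling of interior bins, linear-power units throughout.
Region summaries average LINEAR power (log transforms happen only in the
fitting stage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.typing import ArrayLike
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import dpss, hann

__all__ = [
    "EpochSet",
    "segment_epochs",
    "n_dpss_tapers",
    "compute_psd",
    "average_region",
    "bandpass_filter",
]


@dataclass
class EpochSet:
    """Equal-length overlapping windows of one signal."""

    epochs: np.ndarray  # (n_epochs, n_samples)
    epoch_length: float  # seconds
    overlap: float
    sampling_rate: float

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


def segment_epochs(
    samples: ArrayLike, sampling_rate: float, epoch_length: float, overlap: float = 0.5
) -> EpochSet:
    """Cut a continuous signal into overlapping epochs (trailing partial dropped)."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D signal")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    length = int(round(epoch_length * sampling_rate))
    if x.size < length or length < 1:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one epoch ({length} samples)"
        )
    step = int(round((1.0 - overlap) * length))
    n = (x.size - length) // step + 1
    starts = np.arange(n) * step
    epochs = np.stack([x[s : s + length] for s in starts])
    return EpochSet(
        epochs=epochs, epoch_length=epoch_length, overlap=overlap, sampling_rate=sampling_rate
    )


def n_dpss_tapers(epoch_length: float, smoothing_hz: float) -> int:
    """Number of Slepian tapers: floor(2*T*W - 1) for duration T, half-bandwidth W."""
    n = int(np.floor(2.0 * epoch_length * smoothing_hz - 1.0))
    if n < 1:
        raise ValueError(
            f"smoothing of +/-{smoothing_hz} Hz over {epoch_length} s epochs yields no taper"
        )
    return n


def compute_psd(
    epochs: EpochSet,
    taper: str = "dpss",
    smoothing_hz: float = 1.0,
    fmin: float = 1.0,
    fmax: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean one-sided PSD (density units) over epochs and tapers.

    Returns ``(freqs, power)`` restricted to [fmin, fmax].  The grid spacing
    is 1/epoch_length, so 2 s epochs give 0.5 Hz resolution and 5 s epochs
    0.2 Hz.
    """
    fs = epochs.sampling_rate
    data = epochs.epochs
    n_samp = data.shape[1]
    nyquist = fs / 2.0
    df = 1.0 / epochs.epoch_length
    if fmin < df - 1e-12:
        raise ValueError(f"fmin must be >= frequency resolution ({df} Hz)")
    if fmax > nyquist + 1e-12:
        raise ValueError(f"fmax must be <= Nyquist ({nyquist} Hz)")

    if taper == "dpss":
        k = n_dpss_tapers(epochs.epoch_length, smoothing_hz)
        nw = epochs.epoch_length * smoothing_hz
        windows = dpss(n_samp, NW=nw, Kmax=k)  # (k, n_samp)
    elif taper == "hanning":
        windows = hann(n_samp, sym=False)[np.newaxis, :]
    else:
        raise ValueError(f"unknown taper {taper!r}")

    demeaned = data - data.mean(axis=1, keepdims=True)
    # (n_epochs, n_tapers, n_samp)
    tapered = demeaned[:, np.newaxis, :] * windows[np.newaxis, :, :]
    spec = np.fft.rfft(tapered, axis=-1)
    norms = np.sum(windows**2, axis=1)  # per-taper energy
    psd = (np.abs(spec) ** 2) / (fs * norms[np.newaxis, :, np.newaxis])
    # one-sided: double interior bins (not DC; not Nyquist when n_samp even)
    psd[..., 1:] *= 2.0
    if n_samp % 2 == 0:
        psd[..., -1] /= 2.0
    psd = psd.mean(axis=(0, 1))

    freqs = np.fft.rfftfreq(n_samp, d=1.0 / fs)
    mask = (freqs >= fmin - 1e-9) & (freqs <= fmax + 1e-9)
    return freqs[mask], psd[mask]


def average_region(
    spectra: Sequence[tuple[ArrayLike, ArrayLike]],
) -> tuple[np.ndarray, np.ndarray]:
    """Arithmetic mean of linear power over spectra sharing one frequency grid."""
    if len(spectra) == 0:
        raise ValueError("no spectra to average")
    freqs0 = np.asarray(spectra[0][0], dtype=float)
    powers = []
    for freqs, power in spectra:
        freqs = np.asarray(freqs, dtype=float)
        if freqs.shape != freqs0.shape or not np.allclose(freqs, freqs0):
            raise ValueError("all spectra must share the same frequency grid")
        powers.append(np.asarray(power, dtype=float))
    return freqs0, np.mean(powers, axis=0)


def bandpass_filter(
    samples: ArrayLike, sampling_rate: float, low_hz: float = 0.5, high_hz: float = 100.5
) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass for external time series."""
    sos = butter(4, [low_hz, high_hz], btype="bandpass", fs=sampling_rate, output="sos")
    return sosfiltfilt(sos, np.asarray(samples, dtype=float))
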