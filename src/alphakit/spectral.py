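"""Epoching and spectral decomposition.

The decomposition chain mirrors a standard frequency-tagging workflow:
1-s epochs with 0.5-s overlap, conversion to scalp current densities
(spherical-spline surface Laplacian, Perrin-style, λ = 1e-4), per-epoch
linear detrend, Hann taper, zero-padded FFT onto an exact 0.5-Hz grid,
epoch-averaged power, decibel conversion (10·log10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.signal import detrend
from scipy.signal.windows import hann

from .synth_eeg import Montage, Recording

__all__ = [
    "EpochSet",
    "PowerSpectrum",
    "epoch_data",
    "scd_operator",
    "scalp_current_density",
    "power_spectrum",
    "to_log_power",
    "to_raw_power",
]

logger = logging.getLogger(__name__)

EPOCH_LEN = 1.0        # s
EPOCH_OVERLAP = 0.5    # s
WINDOW_START = 0.5     # s after stimulation onset
WINDOW_LEN = 3.0       # s analysed per trial
SCD_LAMBDA = 1e-4
SCD_ORDER = 4          # spline stiffness m
SCD_N_LEGENDRE = 20
TARGET_RESOLUTION = 0.5  # Hz


@dataclass
class EpochSet:
    """Windowed 1-s epochs: (n_epochs, n_channels, n_samples)."""

    data: np.ndarray
    fs: float
    montage: Montage
    condition: np.ndarray          # per-epoch condition label
    attended_side: np.ndarray      # per-epoch attended side ("" for peri)
    provenance: list = field(default_factory=list)  # (trial index, offset s)
    scale: str = "potential"       # potential | scd

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    def select(self, mask: np.ndarray) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(data=self.data[mask], fs=self.fs, montage=self.montage,
                        condition=self.condition[mask],
                        attended_side=self.attended_side[mask],
                        provenance=[p for p, m in zip(self.provenance, mask) if m],
                        scale=self.scale)


@dataclass
class PowerSpectrum:
    """Epoch-averaged per-channel power on a regular frequency grid."""

    freqs: np.ndarray              # Hz, strictly increasing, 0.5-Hz spacing
    values: np.ndarray             # (n_channels, n_freqs)
    scale: str                     # raw | db
    channels: list
    n_epochs: int = 0

    def mean_over(self, channel_idx) -> np.ndarray:
        """Average the spectrum across a channel subset."""
        return self.values[np.asarray(channel_idx, dtype=int)].mean(axis=0)


def epoch_data(rec: Recording, kind: str | None = None,
               exclude_event_trials: bool = True,
               window_start: float = WINDOW_START,
               window_len: float = WINDOW_LEN,
               epoch_len: float = EPOCH_LEN,
               overlap: float = EPOCH_OVERLAP) -> EpochSet:
    """Cut a recording into overlapping 1-s epochs.

    During-stimulation recordings contribute, per trial, a ``window_len``-s
    window starting ``window_start`` s after stimulation onset (dropping the
    onset-evoked transient and the final post-offset samples), segmented
    with ``overlap``-s steps; trials containing transient target/distracter
    events are excluded when ``exclude_event_trials`` is set.
    Peri-stimulation recordings are segmented whole.
    """
    kind = kind or rec.segment_kind
    n_ep = int(round(epoch_len * rec.fs))
    step = int(round((epoch_len - overlap) * rec.fs))
    epochs, conditions, sides, prov = [], [], [], []
    if kind == "peri":
        starts = range(0, rec.n_samples - n_ep + 1, step)
        for s in starts:
            epochs.append(rec.data[:, s:s + n_ep])
            conditions.append("peri")
            sides.append("")
            prov.append((-1, s / rec.fs))
    elif kind == "during":
        n_skipped_event = n_skipped_short = 0
        for j, tr in enumerate(rec.trials):
            if exclude_event_trials and tr.spec.has_event:
                n_skipped_event += 1
                continue
            w0 = tr.onset_sample + int(round(window_start * rec.fs))
            w1 = w0 + int(round(window_len * rec.fs))
            if w1 > rec.n_samples or tr.spec.duration < window_start + window_len:
                n_skipped_short += 1
                logger.info("trial %d shorter than analysis window, skipped", j)
                continue
            for s in range(w0, w1 - n_ep + 1, step):
                epochs.append(rec.data[:, s:s + n_ep])
                conditions.append(tr.spec.condition)
                sides.append(tr.spec.attended_side)
                prov.append((j, (s - tr.onset_sample) / rec.fs))
        if n_skipped_event:
            logger.info("excluded %d event trials from epoching", n_skipped_event)
    else:
        raise ValueError(f"unknown segment kind: {kind!r}")
    if not epochs:
        raise ValueError("no epochs could be extracted")
    return EpochSet(data=np.stack(epochs), fs=rec.fs, montage=rec.montage,
                    condition=np.array(conditions), attended_side=np.array(sides),
                    provenance=prov)


def _legendre_series(x: np.ndarray, m: float, n_terms: int) -> np.ndarray:
    """Σ_{k=1}^{n} (2k+1) / (k(k+1))^m · P_k(x) / (4π)."""
    k = np.arange(1, n_terms + 1, dtype=float)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * k + 1) / (k * (k + 1)) ** m
    return npleg.legval(x, coeffs) / (4 * np.pi)


def scd_operator(montage: Montage, m: int = SCD_ORDER, lam: float = SCD_LAMBDA,
                 n_legendre: int = SCD_N_LEGENDRE) -> np.ndarray:
    """Linear operator mapping scalp potentials to scalp current densities.

    Spherical-spline interpolation of the potential with smoothing ``lam``
    on the spline coefficients; the surface Laplacian drops one power of
    k(k+1) in the Legendre series.  Returns an (n_ch, n_ch) matrix applied
    per time sample.
    """
    pos = montage.pos
    n = pos.shape[0]
    if n < 8:
        raise ValueError("SCD needs at least 8 channels with valid positions")
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    offdiag = cosang[~np.eye(n, dtype=bool)]
    if np.any(offdiag > 1.0 - 1e-10):
        raise ValueError("duplicate electrode positions in montage")
    G = _legendre_series(cosang, m, n_legendre)
    H = _legendre_series(cosang, m - 1, n_legendre)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G + lam * np.eye(n)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    Ainv = np.linalg.inv(A)
    # potentials v -> spline coefficients c = Ainv[:n, :n] @ v  (rhs is [v; 0])
    return H @ Ainv[:n, :n]


def scalp_current_density(epochs: EpochSet, m: int = SCD_ORDER,
                          lam: float = SCD_LAMBDA,
                          n_legendre: int = SCD_N_LEGENDRE) -> EpochSet:
    """Convert an EpochSet to the reference-free SCD scale."""
    L = scd_operator(epochs.montage, m=m, lam=lam, n_legendre=n_legendre)
    out = np.einsum("ij,ejt->eit", L, epochs.data)
    return EpochSet(data=out, fs=epochs.fs, montage=epochs.montage,
                    condition=epochs.condition, attended_side=epochs.attended_side,
                    provenance=list(epochs.provenance), scale="scd")


def power_spectrum(epochs: EpochSet,
                   pad_to_resolution: float = TARGET_RESOLUTION) -> PowerSpectrum:
    """Epoch-averaged raw power spectra on an exact 0.5-Hz grid.

    Per epoch: remove mean and linear trend, Hann-taper, zero-pad so the
    FFT bin spacing equals ``pad_to_resolution``, take squared magnitudes;
    then average raw power across epochs.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty EpochSet")
    n = epochs.data.shape[-1]
    n_fft = int(np.ceil(epochs.fs / pad_to_resolution))
    if n_fft < n:
        raise ValueError("pad_to_resolution coarser than the epoch's own grid")
    x = detrend(epochs.data, axis=-1, type="linear")
    x = x * hann(n, sym=False)
    spec = np.fft.rfft(x, n=n_fft, axis=-1)
    power = (spec.real**2 + spec.imag**2).mean(axis=0)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / epochs.fs)
    return PowerSpectrum(freqs=freqs, values=power, scale="raw",
                         channels=list(epochs.montage.labels),
                         n_epochs=epochs.n_epochs)


def to_log_power(ps: PowerSpectrum) -> PowerSpectrum:
    """Convert a raw power spectrum to decibels (10·log10)."""
    if ps.scale != "raw":
        raise ValueError("expected a raw-scale spectrum")
    with np.errstate(divide="ignore"):
        vals = 10.0 * np.log10(ps.values)
    return PowerSpectrum(freqs=ps.freqs.copy(), values=vals, scale="db",
                         channels=list(ps.channels), n_epochs=ps.n_epochs)


def to_raw_power(ps: PowerSpectrum) -> PowerSpectrum:
    """Inverse of :func:`to_log_power` (exact round trip)."""
    if ps.scale != "db":
        raise ValueError("expected a dB-scale spectrum")
    return PowerSpectrum(freqs=ps.freqs.copy(), values=10.0 ** (ps.values / 10.0),
                         scale="raw", channels=list(ps.channels),
                         n_epochs=ps.n_epochs)
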