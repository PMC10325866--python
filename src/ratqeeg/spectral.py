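"""Spectral power estimation: Welch periodograms, 1-Hz bins, canonical bands.

Power is absolute (uV^2) throughout; log-scaling happens only in the
Box-Cox normalisation stage of the statistics module.

Binning conventions
-------------------
The native Welch resolution is 0.5 Hz (2-s Hann windows, 50% overlap).
Native bins are summed in pairs into 1-Hz bins labelled 1..40, where bin
``f`` covers [f, f+1) Hz.  Band edges shared by two adjacent bands (4, 8,
12, 25, 30 Hz) are resolved half-open, [low, high), so that band powers
add up without double counting; the topmost band is closed at 40 Hz (it
includes bin 40).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import hann

__all__ = [
    "BandScheme",
    "default_bands",
    "welch_csd",
    "power_spectrum",
    "band_power",
    "mean_power",
    "BIN_FREQS",
]

#: 1-Hz analysis bins, labelled by their lower edge.
BIN_FREQS = np.arange(1, 41)


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous frequency bands over the 1-40 Hz analysis range."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self) -> None:
        prev_high = None
        for name, low, high in self.bands:
            if high <= low:
                raise ValueError(f"band {name}: high <= low")
            if prev_high is not None and low != prev_high:
                raise ValueError(f"band {name}: bands must be contiguous")
            prev_high = high

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.bands)

    def band_of(self, bin_freq: float) -> str:
        """Band owning a 1-Hz bin under the [low, high) convention.

        The last band is closed at its upper edge, so bin 40 belongs to it.
        """
        last_name, _, last_high = self.bands[-1]
        for name, low, high in self.bands:
            if low <= bin_freq < high:
                return name
        if bin_freq == last_high:
            return last_name
        raise ValueError(f"bin {bin_freq} Hz not covered by the band scheme")

    def bins_of(self, name: str) -> np.ndarray:
        """The 1-Hz bins belonging to a band."""
        return np.array([f for f in BIN_FREQS if self.band_of(float(f)) == name])


def default_bands() -> BandScheme:
    """delta 1-4, theta 4-8, alpha 8-12, beta 12-25, high beta 25-30, gamma 30-40 Hz."""
    return BandScheme(
        bands=(
            ("delta", 1.0, 4.0),
            ("theta", 4.0, 8.0),
            ("alpha", 8.0, 12.0),
            ("beta", 12.0, 25.0),
            ("high_beta", 25.0, 30.0),
            ("gamma", 30.0, 40.0),
        )
    )


def _segment_windows(n_samples, fs, segments, nperseg, step):
    """Start indices of analysis windows, windows never crossing segment bounds."""
    starts = []
    for seg_start, seg_end in segments:
        i0 = int(round(seg_start * fs))
        i1 = min(int(round(seg_end * fs)), n_samples)
        pos = i0
        while pos + nperseg <= i1:
            starts.append(pos)
            pos += step
    return starts


def welch_csd(data, fs, segments=None, nperseg=None, overlap=0.5):
    """Welch auto-/cross-spectral matrix over a set of time segments.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in uV.
    fs : float
        Sampling rate in Hz.
    segments : list of (start_s, end_s), optional
        Analysis windows are tiled inside each segment only, so windows
        never span the splice between non-contiguous segments.  Default:
        the whole record.
    nperseg : int, optional
        Window length in samples; default 2 s.
    overlap : float
        Fractional window overlap (default 0.5).

    Returns
    -------
    freqs : ndarray, (n_freqs,)
        One-sided frequency grid.
    S : ndarray, complex, (n_channels, n_channels, n_freqs)
        One-sided cross-spectral density in uV^2/Hz; the diagonal is the
        per-channel PSD.
    n_windows : int
    """
    data = np.asarray(data, dtype=float)
    n_ch, n_samples = data.shape
    if nperseg is None:
        nperseg = int(round(2 * fs))
    if segments is None:
        segments = [(0.0, n_samples / fs)]
    step = max(1, nperseg - int(round(overlap * nperseg)))
    starts = _segment_windows(n_samples, fs, segments, nperseg, step)
    if not starts:
        raise ValueError("no segment is long enough for a single analysis window")

    win = hann(nperseg, sym=False)
    blocks = np.stack([data[:, s : s + nperseg] for s in starts])  # (n_win, n_ch, nperseg)
    blocks = blocks - blocks.mean(axis=-1, keepdims=True)
    F = np.fft.rfft(blocks * win, axis=-1)
    # one-sided PSD scaling (interior bins doubled)
    scale = 1.0 / (fs * np.sum(win**2))
    S = np.einsum("wcf,wdf->cdf", F, np.conj(F)) * (scale / len(starts))
    S[..., 1:-1] *= 2.0
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, S, len(starts)


def _native_to_bins(freqs, native_power):
    """Sum 0.5-Hz native bin powers pairwise into 1-Hz bins 1..40.

    ``native_power`` has frequency on the last axis and must be *power per
    native bin* (PSD integrated over the native resolution).
    """
    df = freqs[1] - freqs[0]
    if not np.isclose(df, 0.5):
        raise ValueError("1-Hz binning requires 0.5-Hz native resolution (2-s windows)")
    out = np.zeros(native_power.shape[:-1] + (len(BIN_FREQS),), dtype=native_power.dtype)
    for k, f in enumerate(BIN_FREQS):
        idx = np.flatnonzero(np.isclose(freqs, f) | np.isclose(freqs, f + 0.5))
        out[..., k] = native_power[..., idx].sum(axis=-1)
    return out


def power_spectrum(data, fs, segments=None):
    """Per-channel absolute power in 1-Hz bins 1..40 (uV^2 per bin).

    Welch average of Hann-windowed 2-s FFT periodograms at 50% overlap;
    0.5-Hz native bins are aggregated to 1-Hz bins.
    """
    freqs, S, _ = welch_csd(data, fs, segments=segments)
    psd = np.real(np.einsum("ccf->cf", S))
    df = freqs[1] - freqs[0]
    return _native_to_bins(freqs, psd * df)


def band_power(bin_powers, scheme: BandScheme | None = None):
    """Aggregate 1-Hz bin powers (last axis = bins 1..40) into band powers.

    Returns an array with the last axis ordered as ``scheme.names``.
    """
    if scheme is None:
        scheme = default_bands()
    bin_powers = np.asarray(bin_powers)
    if bin_powers.shape[-1] != len(BIN_FREQS):
        raise ValueError("expected 40 one-Hz bins on the last axis")
    cols = []
    for name in scheme.names:
        idx = scheme.bins_of(name) - 1
        cols.append(bin_powers[..., idx].sum(axis=-1))
    return np.stack(cols, axis=-1)


def mean_power(band_powers, n_channels_expected=12, axis=-2):
    """Electrode-averaged band power (unweighted mean across channels).

    ``band_powers`` must contain the full montage on ``axis``; a partial
    montage is refused because the electrode average is only comparable
    across subjects when every site contributes.
    """
    band_powers = np.asarray(band_powers)
    if band_powers.shape[axis] != n_channels_expected:
        raise ValueError(
            f"electrode average requires {n_channels_expected} channels, "
            f"got {band_powers.shape[axis]}"
        )
    return band_powers.mean(axis=axis)


def power_table(bin_powers, channels, subject, epoch, scheme=None):
    """Tidy per-channel power table: bins 1..40 plus band columns."""
    if scheme is None:
        scheme = default_bands()
    bp = band_power(bin_powers, scheme)
    df = pd.DataFrame(bin_powers, index=pd.Index(channels, name="channel"),
                      columns=[f"hz_{f}" for f in BIN_FREQS])
    for j, name in enumerate(scheme.names):
        df[name] = bp[:, j]
    df.insert(0, "subject", subject)
    df.insert(1, "epoch", epoch)
    return df.reset_index().set_index(["subject", "epoch", "channel"]).reset_index()
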