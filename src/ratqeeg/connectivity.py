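"""Phase-lagged coherence, global functional connectivity and KDE summaries.

Lagged coherence isolates the time-lagged part of the linear coupling
between two channels.  From the Welch cross-spectrum ``S_xy`` and
auto-spectra ``S_xx``, ``S_yy``::

    LC(f) = Im(S_xy)^2 / (S_xx * S_yy - Re(S_xy)^2)

The zero-lag (instantaneous) component — volume conduction, a shared
reference — contributes only to ``Re(S_xy)`` and is removed by
construction: identical or instantaneously mixed signals have LC = 0.

Global functional connectivity (GFC) is the per-subject mean of
baseline-relative lagged-coherence changes (log ratio, i.e. Box-Cox with
lambda = 0) across all electrode pairs and frequency bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .montage import ElectrodeLayout, electrode_pairs
from .spectral import BandScheme, default_bands, welch_csd

__all__ = [
    "lagged_coherence_matrix",
    "coherence_table",
    "coherence_change",
    "gfc",
    "GFCResult",
    "kde_distribution",
]

#: denominator guard below which LC is defined as 0
DEGENERACY_EPS = 1e-12
#: coherence floor below which log-ratio changes are masked
COHERENCE_FLOOR = 1e-3


def _band_bin_indices(freqs: np.ndarray, scheme: BandScheme) -> dict:
    """Native-bin index groups per (band, 1-Hz bin)."""
    out = {}
    for name in scheme.names:
        groups = []
        for f0 in scheme.bins_of(name):
            idx = np.flatnonzero((freqs >= f0) & (freqs < f0 + 1.0))
            groups.append(idx)
        out[name] = groups
    return out


def lagged_coherence_matrix(data, fs, segments=None, scheme: BandScheme | None = None):
    """Lagged coherence for every channel pair and band.

    Per 1-Hz bin, the cross- and auto-spectra are integrated over the
    bin's native Welch bins before forming LC; the band value is the
    power-weighted mean of bin-wise LC (weights: geometric mean of the
    two auto-powers), so bins with negligible power cannot dominate.

    Returns
    -------
    lc : ndarray, (n_channels, n_channels, n_bands)
        Symmetric, zero diagonal, values in [0, 1].
    """
    if scheme is None:
        scheme = default_bands()
    freqs, S, _ = welch_csd(data, fs, segments=segments)
    n_ch = S.shape[0]
    groups = _band_bin_indices(freqs, scheme)
    lc = np.zeros((n_ch, n_ch, len(scheme.names)))
    auto = np.real(np.einsum("ccf->cf", S))
    for bi, name in enumerate(scheme.names):
        bin_idx = groups[name]
        # integrated spectra per 1-Hz bin
        sxy = np.stack([S[:, :, idx].sum(axis=-1) for idx in bin_idx], axis=-1)
        sxx = np.stack([auto[:, idx].sum(axis=-1) for idx in bin_idx], axis=-1)
        denom = sxx[:, None, :] * sxx[None, :, :] - np.real(sxy) ** 2
        num = np.imag(sxy) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            lc_bin = np.where(denom > DEGENERACY_EPS, num / np.maximum(denom, DEGENERACY_EPS), 0.0)
        weights = np.sqrt(np.maximum(sxx[:, None, :] * sxx[None, :, :], 0.0))
        wsum = weights.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            band_lc = np.where(wsum > 0, (lc_bin * weights).sum(axis=-1) / np.maximum(wsum, DEGENERACY_EPS), 0.0)
        np.fill_diagonal(band_lc, 0.0)
        lc[:, :, bi] = np.clip(band_lc, 0.0, 1.0)
    return lc


def coherence_table(data, fs, layout: ElectrodeLayout, subject, epoch,
                    segments=None, scheme: BandScheme | None = None) -> pd.DataFrame:
    """Tidy lagged-coherence table: one row per electrode pair x band."""
    if scheme is None:
        scheme = default_bands()
    lc = lagged_coherence_matrix(data, fs, segments=segments, scheme=scheme)
    idx = {ch: i for i, ch in enumerate(layout.labels)}
    rows = []
    for a, b in electrode_pairs(layout):
        for bi, band in enumerate(scheme.names):
            rows.append({
                "subject": subject, "epoch": epoch,
                "ch_a": a, "ch_b": b, "band": band,
                "coherence": float(lc[idx[a], idx[b], bi]),
            })
    return pd.DataFrame(rows)


def coherence_change(table: pd.DataFrame, baseline: pd.DataFrame,
                     floor: float = COHERENCE_FLOOR) -> pd.DataFrame:
    """Baseline-relative change, ``log(LC_epoch / LC_baseline)`` per cell.

    Cells where either value lies below ``floor`` are masked (NaN) rather
    than producing extreme logarithms.
    """
    keys = ["ch_a", "ch_b", "band"]
    merged = table.merge(
        baseline[keys + ["coherence"]].rename(columns={"coherence": "baseline"}),
        on=keys, validate="one_to_one",
    )
    valid = (merged["coherence"] >= floor) & (merged["baseline"] >= floor)
    change = np.full(len(merged), np.nan)
    v = valid.to_numpy()
    change[v] = np.log(merged.loc[valid, "coherence"].to_numpy()
                       / merged.loc[valid, "baseline"].to_numpy())
    out = merged[["subject", "epoch"] + keys].copy()
    out["change"] = change
    return out


@dataclass
class GFCResult:
    subject_id: str
    epoch: str
    gfc: float
    change_samples: np.ndarray  # unmasked change values feeding the KDE
    n_total: int
    n_masked: int
    defined: bool = True


def gfc(changes: pd.DataFrame, min_coverage: float = 0.5) -> GFCResult:
    """Per-subject global functional connectivity for one epoch.

    The unweighted mean of all unmasked pair x band change values; flagged
    undefined when fewer than ``min_coverage`` of the cells survive the
    coherence floor.
    """
    subject = changes["subject"].iloc[0]
    epoch = changes["epoch"].iloc[0]
    vals = changes["change"].to_numpy()
    unmasked = vals[np.isfinite(vals)]
    n_total = len(vals)
    n_masked = n_total - len(unmasked)
    if n_total == 0 or len(unmasked) < min_coverage * n_total:
        return GFCResult(subject, epoch, np.nan, unmasked, n_total, n_masked, defined=False)
    return GFCResult(subject, epoch, float(unmasked.mean()), unmasked, n_total, n_masked)


def kde_distribution(samples, bandwidth: float = 0.5, grid=None, n_grid: int = 512):
    """Gaussian kernel density of pooled connectivity-change values.

    The kernel width is the standard deviation of the Gaussian kernel
    (fixed, default 0.5).  The default evaluation grid spans the observed
    range plus three bandwidths on either side.

    Returns
    -------
    grid : ndarray
    density : ndarray
        Non-negative, integrating to 1 within 1e-3 (trapezoid rule).
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("KDE requires at least one finite sample")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid is None:
        lo = x.min() - 3.0 * bandwidth
        hi = x.max() + 3.0 * bandwidth
        grid = np.linspace(lo, hi, n_grid)
    grid = np.asarray(grid, dtype=float)
    z = (grid[:, None] - x[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (x.size * bandwidth * np.sqrt(2 * np.pi))
    return grid, density


def kde_mode(samples, bandwidth: float = 0.5, **kw) -> float:
    """Location of the KDE maximum (used for distribution-shift summaries)."""
    grid, density = kde_distribution(samples, bandwidth=bandwidth, **kw)
    return float(grid[np.argmax(density)])
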