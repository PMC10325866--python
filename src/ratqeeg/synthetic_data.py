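"""Synthetic multichannel rat-EEG generator with analytically known ground truth.

The generator emulates the statistical structure of a freely-moving-rat
cortical EEG study so that every downstream stage (segment selection,
spectral power, phase-lagged coherence, statistics) can be validated by
parameter recovery:

* each channel is a sum of band-limited noise sources (white noise shaped
  by 4th-order Butterworth band filters), a 1/f background and white
  sensor noise;
* functional coupling between channels is realised as a *delayed shared
  source*: the receiving channel's band source is ``w * s(t - lag) +
  sqrt(1 - w^2) * s_own(t)``.  The pure delay makes the imaginary part of
  the cross-spectrum nonzero, so the phase-lagged coherence target is
  computable in closed form from the generative mixing weights and lags;
* drug effects are per-epoch multiplicative factors on band power and on
  coupling weights;
* behavioural activity episodes add EMG-like high-passed noise plus
  large-amplitude movement transients, exercising the inactivity filter
  and the amplitude-based segment selection.

Ground truth (band powers and lagged coherences per epoch) is derived
from the generative model's transfer functions, never measured from the
generated signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .montage import ElectrodeLayout, default_layout, electrode_pairs
from .spectral import BandScheme, default_bands

__all__ = [
    "Coupling",
    "EpochEffect",
    "SimulationConfig",
    "GroundTruth",
    "default_layout",
    "default_config",
    "psilocin_like_effect",
    "compressed_schedule",
    "default_epoch_schedule",
    "generate_recording",
    "quantize",
    "dequantize",
]


@dataclass(frozen=True)
class Coupling:
    """One delayed-shared-source link: ``receiver`` carries a delayed copy
    of ``carrier``'s band source with weight ``weight`` and delay ``lag_ms``."""

    carrier: str
    receiver: str
    band: str
    weight: float
    lag_ms: float


@dataclass(frozen=True)
class EpochEffect:
    """Multiplicative drug effect applied inside one epoch window.

    ``power_gain`` multiplies band *power* (a single float applies to all
    bands; a dict assigns per-band factors).  ``coupling_gain`` multiplies
    every coupling weight.
    """

    power_gain: "float | dict[str, float]" = 1.0
    coupling_gain: float = 1.0

    def gain_for(self, band: str) -> float:
        if isinstance(self.power_gain, dict):
            return float(self.power_gain.get(band, 1.0))
        return float(self.power_gain)


def default_epoch_schedule() -> dict[str, tuple[float, float]]:
    """10-min baseline, then 10-min windows at 20-30, 50-60 and 80-90 min
    after administration (administration at 600 s)."""
    return {
        "baseline": (0.0, 600.0),
        "E1": (1800.0, 2400.0),
        "E2": (3600.0, 4200.0),
        "E3": (4800.0, 5400.0),
    }


def compressed_schedule(epoch_s: float = 60.0) -> dict[str, tuple[float, float]]:
    """Back-to-back epochs of ``epoch_s`` seconds for fast simulation studies.

    Keeps the baseline/E1/E2/E3 structure and the per-epoch drug-effect
    semantics while shrinking the silent stretches of the recording.
    """
    return {
        "baseline": (0.0, epoch_s),
        "E1": (epoch_s, 2 * epoch_s),
        "E2": (2 * epoch_s, 3 * epoch_s),
        "E3": (3 * epoch_s, 4 * epoch_s),
    }


@dataclass
class SimulationConfig:
    sampling_rate: float = 250.0
    duration: float = 5400.0
    epoch_schedule: dict = field(default_factory=default_epoch_schedule)
    admin_time: float = 600.0
    band_amplitudes: dict = field(
        default_factory=lambda: {
            "delta": 30.0,
            "theta": 25.0,
            "alpha": 15.0,
            "beta": 10.0,
            "high_beta": 6.0,
            "gamma": 5.0,
        }
    )
    coupling_spec: list = field(default_factory=list)
    #: band -> weight of a weak common (subcortical-pacemaker-like) drive
    #: delivered to every channel with channel-specific conduction delays;
    #: gives the whole montage a realistic nonzero lagged-coherence floor
    global_coupling: dict = field(default_factory=dict)
    #: per-channel delay of the common drive, ms (cycled if shorter than 12)
    global_lags_ms: list = field(
        default_factory=lambda: [4.0 * (i % 6) for i in range(12)]
    )
    pink_noise_amplitude: float = 10.0
    white_noise_amplitude: float = 2.0
    drug_effect: dict = field(default_factory=dict)  # epoch name -> EpochEffect
    activity_schedule: list = field(default_factory=list)  # (start_s, end_s) active
    artifact_amplitude: float = 400.0
    emg_amplitude: float = 40.0
    transient_rate_per_min: float = 2.0
    seed: int = 0
    band_scheme: BandScheme = field(default_factory=default_bands)

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.duration <= 0:
            raise ValueError("sampling_rate and duration must be positive")
        last_end = max(e for _, e in self.epoch_schedule.values())
        if self.duration < last_end:
            raise ValueError(
                f"duration {self.duration} s shorter than the epoch schedule "
                f"(last epoch ends at {last_end} s)"
            )
        edges = {name: (lo, hi) for name, lo, hi in self.band_scheme.bands}
        receivers = set()
        for c in self.coupling_spec:
            if not 0.0 <= c.weight <= 1.0:
                raise ValueError(f"coupling weight {c.weight} outside [0, 1]")
            if c.weight > 0 and c.lag_ms <= 0:
                raise ValueError(
                    f"coupling {c.carrier}->{c.receiver} ({c.band}): a nonzero "
                    "lagged-coherence target requires a strictly positive lag"
                )
            lo, hi = edges[c.band]
            if c.lag_ms >= 1000.0 / hi:
                raise ValueError(
                    f"coupling {c.carrier}->{c.receiver}: lag {c.lag_ms} ms is not "
                    f"shorter than the {c.band} band's shortest period "
                    f"({1000.0 / hi:.1f} ms); the coherence target is ill-posed"
                )
            key = (c.receiver, c.band)
            if key in receivers:
                raise ValueError(f"channel {c.receiver} receives twice in band {c.band}")
            receivers.add(key)
        for c in self.coupling_spec:
            if (c.carrier, c.band) in receivers:
                raise ValueError(
                    f"channel {c.carrier} is both carrier and receiver in band "
                    f"{c.band}; coupling chains are not supported"
                )
        for band, w in self.global_coupling.items():
            if not 0.0 <= w < 1.0:
                raise ValueError(f"global coupling weight {w} outside [0, 1)")
            lo, hi = edges[band]
            if w > 0 and max(self.global_lags_ms) >= 1000.0 / hi:
                raise ValueError(
                    f"global-coupling delays reach {max(self.global_lags_ms)} ms, "
                    f"not shorter than the {band} band's shortest period"
                )
        for eff in self.drug_effect.values():
            gains = (
                list(eff.power_gain.values())
                if isinstance(eff.power_gain, dict)
                else [eff.power_gain]
            )
            if any(g < 0 for g in gains) or eff.coupling_gain < 0:
                raise ValueError("drug-effect gains must be non-negative")


def _default_couplings() -> list:
    """Homologous plus fronto-temporal delayed coupling in theta/alpha/beta.

    The frontal-left site acts as the shared carrier for its homologue and
    both temporal sites, so the fronto-temporal network {F3, F4, T3, T4}
    is mutually coherent, as in resting rodent cortex.
    """
    out = []
    plan = [
        ("theta", 10.0, 0.60, 0.50),
        ("alpha", 12.0, 0.50, 0.45),
        ("beta", 8.0, 0.40, 0.35),
    ]
    for band, lag, w_hom, w_ft in plan:
        out += [
            Coupling("F3", "F4", band, w_hom, lag),
            Coupling("F3", "T3", band, w_ft, lag + 3.0),
            Coupling("F3", "T4", band, w_ft, lag + 5.0),
            Coupling("C3", "C4", band, w_hom, lag),
            Coupling("P3", "P4", band, w_hom, lag),
            Coupling("P5", "P6", band, w_ft, lag + 2.0),
            Coupling("T5", "T6", band, w_ft, lag + 2.0),
        ]
    return out


def psilocin_like_effect(
    power_gain: float = 0.6, coupling_gain: float = 0.7
) -> dict[str, EpochEffect]:
    """Broadband desynchronization plus disconnection in E1-E2, partial
    recovery in E3 — the qualitative signature of a serotonergic psychedelic."""
    return {
        "E1": EpochEffect(power_gain=power_gain, coupling_gain=coupling_gain),
        "E2": EpochEffect(power_gain=power_gain, coupling_gain=min(1.0, coupling_gain + 0.05)),
        "E3": EpochEffect(
            power_gain=min(1.0, power_gain + 0.25),
            coupling_gain=min(1.0, coupling_gain + 0.2),
        ),
    }


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Study-default configuration: full-length recording, default montage
    coupling plus a weak common drive in every band, no drug effect, no
    behavioural activity."""
    cfg = SimulationConfig(
        seed=seed,
        coupling_spec=_default_couplings(),
        global_coupling={b: 0.55 for b, _, _ in default_bands().bands},
    )
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise TypeError(f"unknown SimulationConfig field: {key}")
        setattr(cfg, key, val)
    return cfg


# ---------------------------------------------------------------------------
# filters and analytic spectra


def _band_sos(low: float, high: float, fs: float):
    return sps.butter(4, [low, high], btype="bandpass", output="sos", fs=fs)


_FREQ_GRID_N = 4096


def _filter_psd_shape(sos, fs: float):
    """(freqs, |H|^2) on a dense uniform grid over [0, fs/2]."""
    w, h = sps.sosfreqz(sos, worN=_FREQ_GRID_N, fs=fs)
    return w, np.abs(h) ** 2


def _pink_shape(freqs: np.ndarray, corner: float = 1.0) -> np.ndarray:
    """|H|^2 of the 1/f shaping filter (flat below ``corner`` Hz)."""
    f = np.maximum(freqs, corner)
    shape = corner / f
    shape[freqs == 0] = 0.0
    return shape


def _unit_gain(shape_sq: np.ndarray) -> float:
    """Variance of unit white noise after filtering with |H|^2 = shape_sq."""
    return float(np.mean(shape_sq))


def _delay(x: np.ndarray, samples: int) -> np.ndarray:
    if samples == 0:
        return x
    out = np.zeros_like(x)
    out[samples:] = x[:-samples]
    return out


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Analytic per-epoch band powers (uV^2) and lagged coherences in [0, 1]."""

    band_power: pd.DataFrame  # columns: epoch, channel, band, power
    lagged_coherence: pd.DataFrame  # columns: epoch, ch_a, ch_b, band, coherence
    activity_schedule: list

    def power_of(self, epoch: str, channel: str, band: str) -> float:
        df = self.band_power
        m = (df.epoch == epoch) & (df.channel == channel) & (df.band == band)
        return float(df.loc[m, "power"].iloc[0])

    def coherence_of(self, epoch: str, pair: tuple[str, str], band: str) -> float:
        df = self.lagged_coherence
        a, b = sorted(pair)
        m = (df.epoch == epoch) & (df.ch_a == a) & (df.ch_b == b) & (df.band == band)
        return float(df.loc[m, "coherence"].iloc[0])


def _round_lag(lag_ms: float, fs: float) -> float:
    """Lag in seconds, rounded to the sample grid the generator uses."""
    return round(lag_ms / 1000.0 * fs) / fs


def _source_decomposition(config: SimulationConfig, labels):
    """Per (channel, band): list of (source_id, gain, lag_s) terms.

    Every channel owns one unit source per band; couplings replace the
    receiver's term with a two-term mixture.  Lags are rounded to the
    sample grid, matching the generated signal exactly.  Used both by the
    generator and by the closed-form cross-spectrum.
    """
    fs = config.sampling_rate
    decomp = {
        (ch, band): [(ch, 1.0, 0.0)]
        for ch in labels
        for band in config.band_scheme.names
    }
    for c in config.coupling_spec:
        decomp[(c.receiver, c.band)] = [
            (c.carrier, c.weight, _round_lag(c.lag_ms, fs)),
            (c.receiver, math.sqrt(max(0.0, 1.0 - c.weight**2)), 0.0),
        ]
    return decomp


GLOBAL_SOURCE = "__global__"


def _global_lag(config: SimulationConfig, channel_index: int) -> float:
    lags = config.global_lags_ms
    return _round_lag(lags[channel_index % len(lags)], config.sampling_rate)


def _effective_terms(terms, wg: float, tau_c: float, cg: float):
    """Unit-variance source mixture of one channel/band under a coupling gain.

    ``terms`` is the pairwise-level decomposition; ``wg`` the common-drive
    weight and ``tau_c`` the channel's common-drive delay.  Delayed shared
    weights scale with ``cg``; own-source residuals re-normalise so that
    the mixture keeps unit variance.
    """
    inner = [(src, _epoch_gain(g, tau, cg), tau) for (src, g, tau) in terms]
    if wg <= 0.0:
        return inner
    wge = wg * cg
    s = math.sqrt(max(0.0, 1.0 - wge**2))
    return [(GLOBAL_SOURCE, wge, tau_c)] + [(src, g * s, tau) for src, g, tau in inner]


def _analytic_ground_truth(config: SimulationConfig, layout: ElectrodeLayout):
    fs = config.sampling_rate
    scheme = config.band_scheme
    freqs = np.linspace(0.0, fs / 2.0, _FREQ_GRID_N)

    band_psd = {}  # band -> one-sided PSD (uV^2/Hz) of a unit coupling mixture
    for name, lo, hi in scheme.bands:
        sos = _band_sos(lo, hi, fs)
        _, shape_sq = _filter_psd_shape(sos, fs)
        amp = config.band_amplitudes.get(name, 0.0)
        v = _unit_gain(shape_sq)
        band_psd[name] = (amp**2 / v) * shape_sq * (2.0 / fs) if amp > 0 else np.zeros_like(shape_sq)
    pink_sq = _pink_shape(freqs)
    v_pink = _unit_gain(pink_sq)
    pink_psd = (config.pink_noise_amplitude**2 / v_pink) * pink_sq * (2.0 / fs)
    white_psd = np.full_like(freqs, config.white_noise_amplitude**2 * (2.0 / fs))

    # frequency coverage of each analysis band under the estimator's
    # 1-Hz-bin convention: bin f sums the 0.5-Hz Welch bins at f and
    # f+0.5, whose nominal coverage is [f-0.25, f+0.75); the topmost
    # band is closed at its upper edge (it includes bin 40)
    band_range = {}
    for name, lo, hi in scheme.bands:
        hi_eff = hi + 1.0 if name == scheme.names[-1] else hi
        band_range[name] = (lo - 0.25, hi_eff - 0.25)

    decomp = _source_decomposition(config, layout.labels)
    epochs = list(config.epoch_schedule)
    effects = {e: config.drug_effect.get(e, EpochEffect()) for e in epochs}

    power_rows = []
    for epoch in epochs:
        eff = effects[epoch]
        total_psd = pink_psd + white_psd
        total_psd = total_psd + sum(
            eff.gain_for(b) * band_psd[b] for b in scheme.names
        )
        for band, (lo, hi_eff) in band_range.items():
            sel = (freqs >= lo) & (freqs < hi_eff)
            p = float(np.trapezoid(total_psd[sel], freqs[sel]))
            for ch in layout.labels:
                power_rows.append({"epoch": epoch, "channel": ch, "band": band, "power": p})

    coh_rows = []
    df_grid = freqs[1] - freqs[0]
    ch_pos = {ch: i for i, ch in enumerate(layout.labels)}
    # 1-Hz bin coverage mirroring the Welch estimator's native bins
    bin_slices = {}
    for f0 in range(1, 41):
        sel = np.flatnonzero((freqs >= f0 - 0.25) & (freqs < f0 + 0.75))
        bin_slices[f0] = slice(int(sel[0]), int(sel[-1]) + 1)
    band_bins = {band: [int(f) for f in scheme.bins_of(band)] for band in scheme.names}
    phase_cache: dict[float, np.ndarray] = {}

    def _phase(dtau: float) -> np.ndarray:
        key = round(dtau, 9)
        if key not in phase_cache:
            phase_cache[key] = np.exp(-2j * np.pi * freqs * dtau)
        return phase_cache[key]

    for epoch in epochs:
        eff = effects[epoch]
        cg = eff.coupling_gain
        # per-channel total PSD (same for every channel: mixtures are unit variance)
        total_psd = pink_psd + white_psd + sum(
            eff.gain_for(b) * band_psd[b] for b in scheme.names
        )
        total_int = {f0: total_psd[sl].sum() * df_grid for f0, sl in bin_slices.items()}
        eff_terms = {
            (ch, band): _effective_terms(
                decomp[(ch, band)],
                config.global_coupling.get(band, 0.0),
                _global_lag(config, ch_pos[ch]),
                cg,
            )
            for ch in layout.labels
            for band in scheme.names
        }
        for a, b in electrode_pairs(layout):
            # cross-spectrum: sum over source bands of shared-source terms
            sxy = np.zeros_like(freqs, dtype=complex)
            empty = True
            for src_band in scheme.names:
                g_band = eff.gain_for(src_band)
                if g_band == 0.0:
                    continue
                contrib = None
                for (sa, ga, ta) in eff_terms[(a, src_band)]:
                    for (sb, gb, tb) in eff_terms[(b, src_band)]:
                        if sa != sb or ga * gb == 0.0:
                            continue
                        term = (ga * gb) * _phase(ta - tb)
                        contrib = term if contrib is None else contrib + term
                if contrib is not None:
                    sxy += contrib * (g_band * band_psd[src_band])
                    empty = False
            for band in scheme.names:
                if empty:
                    coh_rows.append(
                        {"epoch": epoch, "ch_a": min(a, b), "ch_b": max(a, b),
                         "band": band, "coherence": 0.0}
                    )
                    continue
                lc_bins, wts = [], []
                for f0 in band_bins[band]:
                    sl = bin_slices[f0]
                    sxy_i = sxy[sl].sum() * df_grid
                    sxx_i = total_int[f0]
                    denom = sxx_i * sxx_i - sxy_i.real**2
                    lc = (sxy_i.imag**2 / denom) if denom > 1e-12 else 0.0
                    lc_bins.append(lc)
                    wts.append(sxx_i)  # geometric mean of equal auto-powers
                lc_band = float(np.average(lc_bins, weights=wts))
                coh_rows.append(
                    {"epoch": epoch, "ch_a": min(a, b), "ch_b": max(a, b),
                     "band": band, "coherence": lc_band}
                )

    return (
        pd.DataFrame(power_rows),
        pd.DataFrame(coh_rows),
    )


def _epoch_gain(g: float, lag_s: float, coupling_gain: float) -> float:
    """Effective mixture weight of one source term under a coupling gain.

    Carrier terms (gain 1, lag 0) are unaffected.  Delayed shared terms
    scale by the coupling gain; the receiver's own-source term is re-set to
    keep the mixture at unit variance.
    """
    if g == 1.0 and lag_s == 0.0:
        return 1.0
    if lag_s > 0.0:
        return g * coupling_gain
    # own-source residual of a receiver: g = sqrt(1 - w^2) originally
    w2 = 1.0 - g * g
    return math.sqrt(max(0.0, 1.0 - w2 * coupling_gain**2))


# ---------------------------------------------------------------------------
# signal generation


def _gain_envelope(config: SimulationConfig, n: int, value_for_epoch) -> np.ndarray:
    """Per-sample envelope: 1 outside epochs, epoch-specific value inside."""
    fs = config.sampling_rate
    env = np.ones(n)
    for epoch, (t0, t1) in config.epoch_schedule.items():
        eff = config.drug_effect.get(epoch)
        if eff is None:
            continue
        i0, i1 = int(round(t0 * fs)), min(int(round(t1 * fs)), n)
        env[i0:i1] = value_for_epoch(eff)
    return env


def generate_recording(config: SimulationConfig, layout: ElectrodeLayout | None = None):
    """Simulate one subject's recording.

    Returns
    -------
    recording : ratqeeg.signal_io.Recording
        Multichannel signal in uV with activity/inactivity markers.
    truth : GroundTruth
        Closed-form band powers and lagged coherences per epoch.
    """
    from .signal_io import Marker, Recording  # deferred: avoid import cycle at doc build

    if layout is None:
        layout = default_layout()
    config.validate()
    fs = config.sampling_rate
    n = int(round(config.duration * fs))
    n_ch = layout.n_channels
    rng = np.random.default_rng(config.seed)
    scheme = config.band_scheme
    ch_index = {ch: i for i, ch in enumerate(layout.labels)}

    data = np.zeros((n_ch, n))

    couplings_by_band: dict[str, list] = {}
    for c in config.coupling_spec:
        couplings_by_band.setdefault(c.band, []).append(c)

    cg_env = _gain_envelope(config, n, lambda e: e.coupling_gain)
    cg_varies = not np.all(cg_env == 1.0)

    for name, lo, hi in scheme.bands:
        amp = config.band_amplitudes.get(name, 0.0)
        if amp <= 0:
            continue
        sos = _band_sos(lo, hi, fs)
        _, shape_sq = _filter_psd_shape(sos, fs)
        norm = amp / math.sqrt(_unit_gain(shape_sq))
        raw = rng.standard_normal((n_ch, n))
        mixed = raw.copy()
        for c in couplings_by_band.get(name, []):
            ia, ib = ch_index[c.carrier], ch_index[c.receiver]
            lag_samp = int(round(c.lag_ms / 1000.0 * fs))
            w = c.weight * (cg_env if cg_varies else 1.0)
            mixed[ib] = w * _delay(raw[ia], lag_samp) + np.sqrt(1.0 - w**2) * raw[ib]
        wg = config.global_coupling.get(name, 0.0)
        if wg > 0.0:
            glob = rng.standard_normal(n)
            wg_env = wg * (cg_env if cg_varies else 1.0)
            inner_scale = np.sqrt(1.0 - wg_env**2)
            for i in range(n_ch):
                lag_samp = int(round(_global_lag(config, i) * fs))
                mixed[i] = wg_env * _delay(glob, lag_samp) + inner_scale * mixed[i]
        band_sig = sps.sosfilt(sos, mixed, axis=-1) * norm
        pw_env = _gain_envelope(config, n, lambda e, b=name: e.gain_for(b))
        if not np.all(pw_env == 1.0):
            band_sig *= np.sqrt(pw_env)
        data += band_sig

    # 1/f background, independent per channel (FFT shaping)
    if config.pink_noise_amplitude > 0:
        white = rng.standard_normal((n_ch, n))
        f_r = np.fft.rfftfreq(n, 1.0 / fs)
        shape = np.sqrt(_pink_shape(f_r))
        spec = np.fft.rfft(white, axis=-1) * shape
        pink = np.fft.irfft(spec, n=n, axis=-1)
        # empirical unit-variance factor of the discrete shaping filter
        v = np.mean(_pink_shape(np.linspace(0.0, fs / 2, _FREQ_GRID_N)))
        data += pink * (config.pink_noise_amplitude / math.sqrt(v))

    if config.white_noise_amplitude > 0:
        data += config.white_noise_amplitude * rng.standard_normal((n_ch, n))

    # behavioural-activity artifacts
    active_mask = np.zeros(n, dtype=bool)
    for t0, t1 in config.activity_schedule:
        active_mask[int(round(t0 * fs)) : int(round(t1 * fs))] = True
    if active_mask.any():
        if config.emg_amplitude > 0:
            sos_hp = sps.butter(4, 40.0, btype="highpass", output="sos", fs=fs)
            _, hp_sq = _filter_psd_shape(sos_hp, fs)
            emg = sps.sosfilt(sos_hp, rng.standard_normal((n_ch, n)), axis=-1)
            emg *= config.emg_amplitude / math.sqrt(_unit_gain(hp_sq))
            data += emg * active_mask
        if config.artifact_amplitude > 0:
            pulse = sps.windows.hann(int(round(0.25 * fs)))
            for t0, t1 in config.activity_schedule:
                dur_min = (t1 - t0) / 60.0
                n_ev = rng.poisson(config.transient_rate_per_min * dur_min)
                for _ in range(n_ev):
                    t_ev = rng.uniform(t0, max(t0, t1 - 0.25))
                    i0 = int(round(t_ev * fs))
                    seg = slice(i0, min(n, i0 + len(pulse)))
                    amp_ch = config.artifact_amplitude * rng.uniform(0.6, 1.0, size=n_ch)
                    sign = rng.choice([-1.0, 1.0])
                    data[:, seg] += sign * amp_ch[:, None] * pulse[: seg.stop - seg.start]

    markers = [Marker(float(t0), float(t1), "active") for t0, t1 in config.activity_schedule]
    # complement of activity -> explicit inactivity markers
    bounds = sorted((float(t0), float(t1)) for t0, t1 in config.activity_schedule)
    cursor = 0.0
    for t0, t1 in bounds:
        if t0 > cursor:
            markers.append(Marker(cursor, t0, "inactive"))
        cursor = max(cursor, t1)
    if cursor < config.duration:
        markers.append(Marker(cursor, float(config.duration), "inactive"))
    markers.sort(key=lambda m: (m.start, m.end))

    power_df, coh_df = _analytic_ground_truth(config, layout)
    truth = GroundTruth(
        band_power=power_df,
        lagged_coherence=coh_df,
        activity_schedule=[(float(a), float(b)) for a, b in config.activity_schedule],
    )
    rec = Recording(
        data=data,
        sfreq=fs,
        layout=layout,
        markers=markers,
        subject_id="sim",
        group="",
        admin_time=float(config.admin_time),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# quantization


def quantize(signal, half_range: float = 500.0, bits: int = 16):
    """Uniform quantizer with step ``half_range / 2**bits``.

    With the acquisition system's +/-500 uV dynamic range and 16-bit depth
    this reproduces the hardware's printed 7.63 nV/bit resolution.  (The
    conventional full-range/2^bits step would be twice as large; the
    half-range convention is deliberate and documented.)  Values are
    clipped at +/-``half_range``.
    """
    if half_range <= 0:
        raise ValueError("half_range must be positive")
    if bits < 2:
        raise ValueError("bits must be >= 2")
    step = half_range / 2**bits
    counts = np.round(np.asarray(signal, dtype=float) / step)
    lim = 2**bits
    return np.clip(counts, -lim, lim).astype(np.int64)


def dequantize(counts, half_range: float = 500.0, bits: int = 16):
    """Inverse of :func:`quantize` (counts back to uV)."""
    step = half_range / 2**bits
    return np.asarray(counts, dtype=float) * step


def quantization_step(half_range: float = 500.0, bits: int = 16) -> float:
    """LSB size in uV."""
    return half_range / 2**bits
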