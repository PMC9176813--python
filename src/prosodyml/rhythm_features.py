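"""Rhythm-relevant features of the temporal envelope.

Three families of features describe the syllabic rhythm carried by the
slowly varying amplitude of speech:

* **ENV** — power spectrum of the broadband Hilbert envelope, finely binned
  over 0-16 Hz (0.25 Hz bins) so the perceptually crucial 2-8 Hz band is
  well resolved;
* **IMF** — summary statistics of the intrinsic mode functions obtained by
  empirical mode decomposition (EMD) of the envelope, capturing rhythm at
  multiple data-driven timescales;
* **TMS** — the temporal modulation spectrum: modulation power over 0-20 Hz
  within each of 16 log-spaced acoustic frequency bands (80-7600 Hz).  Each
  band's modulation spectrum is normalized to the same mass, so the TMS
  describes the *shape* of amplitude modulation per band rather than where
  spectral energy sits — the latter tracks voice pitch and spectral tilt,
  which belong to the intonation channel, not rhythm.

Per utterance the three blocks concatenate to 64 + 48 + 320 = 432 values;
over a speaker's 20 utterances this yields the fixed 8640-dimensional
rhythm vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.fft import ifft as _ifft
from scipy.fft import next_fast_len, rfft, rfftfreq

from .corpus_io import SpeakerRecord, Utterance, UTTERANCES_PER_SPEAKER

__all__ = [
    "RhythmConfig",
    "EnvelopeSignal",
    "RhythmVector",
    "FeatureError",
    "extract_envelope",
    "env_spectrum_features",
    "emd",
    "imf_features",
    "tms_features",
    "utterance_rhythm_features",
    "rhythm_vector",
]

LOG_FLOOR = 1e-12  # additive floor under all log-power values


class FeatureError(ValueError):
    """Raised for inputs violating feature-extraction contracts."""


@dataclass(frozen=True)
class RhythmConfig:
    """Parameters of the rhythm feature extractor.

    Defaults are chosen so that one utterance yields exactly
    ``env_spec_bins + n_imfs*imf_stats + tms_bands*tms_mod_bins = 432``
    features and a 20-utterance speaker 8640.  Changing any count changes
    the dimensionality contract.
    """

    env_lowpass_hz: float = 20.0
    env_rate: int = 100
    env_spec_bins: int = 64
    env_spec_range: tuple[float, float] = (0.0, 16.0)
    n_imfs: int = 6
    imf_stats: int = 8  # fixed by the statistic list in imf_features
    tms_bands: int = 16
    tms_range: tuple[float, float] = (80.0, 7600.0)
    tms_mod_bins: int = 20
    tms_mod_range: tuple[float, float] = (0.0, 20.0)
    rhythm_band: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        if self.env_rate < 2 * self.env_lowpass_hz:
            raise FeatureError("env_rate must be >= twice the envelope low-pass cutoff")
        if self.imf_stats != 8:
            raise FeatureError("imf_stats is fixed at 8 by the statistic list")
        for name in ("env_spec_bins", "n_imfs", "tms_bands", "tms_mod_bins"):
            if getattr(self, name) <= 0:
                raise FeatureError(f"{name} must be positive")

    @property
    def per_utterance_dim(self) -> int:
        return self.env_spec_bins + self.n_imfs * self.imf_stats + self.tms_bands * self.tms_mod_bins

    @property
    def speaker_dim(self) -> int:
        return UTTERANCES_PER_SPEAKER * self.per_utterance_dim


@dataclass(frozen=True)
class EnvelopeSignal:
    """Non-negative temporal envelope sampled at ``env_rate`` Hz."""

    values: np.ndarray
    env_rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise FeatureError("envelope contains non-finite values")
        if np.any(values < 0):
            raise FeatureError("envelope must be non-negative")


@dataclass(frozen=True)
class RhythmVector:
    """Fixed-layout per-speaker rhythm feature vector.

    Layout is utterance-major; within each utterance the blocks are
    ENV[env_spec_bins], IMF[n_imfs*8], TMS[tms_bands*tms_mod_bins].
    """

    speaker_id: str
    values: np.ndarray
    layout: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if not np.all(np.isfinite(values)):
            raise FeatureError(f"rhythm vector for {self.speaker_id!r} has non-finite values")


# ---------------------------------------------------------------------------
# Envelope
# ---------------------------------------------------------------------------

@lru_cache(maxsize=8)
def _lowpass_sos(cutoff_hz: float, sr: int) -> np.ndarray:
    return sps.butter(4, cutoff_hz, btype="low", fs=sr, output="sos")


def extract_envelope(utt: Utterance, cfg: RhythmConfig = RhythmConfig()) -> EnvelopeSignal:
    """Broadband temporal envelope: |analytic signal|, low-passed, resampled.

    Magnitude of the Hilbert analytic signal, zero-phase 4th-order
    Butterworth low-pass at ``env_lowpass_hz`` (zero-phase to preserve
    rhythm timing), polyphase-resampled to ``env_rate`` and clipped at 0.
    """
    x = utt.samples
    sr = utt.sample_rate
    if x.size < 4 * int(sr / cfg.env_lowpass_hz):
        raise FeatureError(
            f"utterance {utt.utterance_id!r} too short for envelope filtering"
        )
    n = x.size
    analytic = sps.hilbert(x, N=next_fast_len(n))[:n]
    mag = np.abs(analytic)
    filtered = sps.sosfiltfilt(_lowpass_sos(cfg.env_lowpass_hz, sr), mag)
    frac = Fraction(int(cfg.env_rate), int(sr))
    env = sps.resample_poly(filtered, frac.numerator, frac.denominator)
    return EnvelopeSignal(values=np.clip(env, 0.0, None), env_rate=float(cfg.env_rate))


# ---------------------------------------------------------------------------
# ENV: envelope spectrum
# ---------------------------------------------------------------------------

def _binned_power(x: np.ndarray, rate: float, n_bins: int,
                  f_range: tuple[float, float], nfft_min: int = 4096) -> np.ndarray:
    """Hann-windowed FFT power of mean-removed x, integrated into uniform bins."""
    v = x - np.mean(x)
    w = sps.windows.hann(v.size, sym=False)
    nfft = next_fast_len(max(v.size, nfft_min))
    spec = np.abs(rfft(v * w, n=nfft)) ** 2
    freqs = rfftfreq(nfft, d=1.0 / rate)
    lo, hi = f_range
    width = (hi - lo) / n_bins
    idx = np.floor((freqs - lo) / width).astype(int)
    valid = (idx >= 0) & (idx < n_bins)
    power = np.zeros(n_bins)
    np.add.at(power, idx[valid], spec[valid])
    return power


def env_spectrum_features(env: EnvelopeSignal, cfg: RhythmConfig = RhythmConfig()) -> np.ndarray:
    """Log-power of the envelope spectrum in 64 uniform bins over [0, 16) Hz."""
    if env.values.size < env.env_rate * 0.2:
        raise FeatureError("envelope too short for spectral features")
    power = _binned_power(env.values, env.env_rate, cfg.env_spec_bins,
                          cfg.env_spec_range, nfft_min=2048)
    return np.log10(power + LOG_FLOOR)


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------

_SIFT_THRESHOLD = 0.2   # Cauchy-type stopping criterion for sifting
_MAX_SIFTS = 50


def _extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of interior local maxima and minima (strict on the left)."""
    d = np.diff(x)
    rising = d > 0
    falling = d < 0
    maxima = np.flatnonzero(rising[:-1] & ~rising[1:] & (falling[1:] | (d[1:] == 0))) + 1
    minima = np.flatnonzero(falling[:-1] & ~falling[1:] & (rising[1:] | (d[1:] == 0))) + 1
    return maxima, minima


def _mirror_anchor(idx: np.ndarray, val: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror the two outermost extrema past each end (standard EMD boundary fix)."""
    left_i = -idx[1::-1] if idx.size >= 2 else -idx[:1]
    left_v = val[1::-1] if idx.size >= 2 else val[:1]
    right_i = 2 * (n - 1) - idx[-1:-3:-1] if idx.size >= 2 else 2 * (n - 1) - idx[-1:]
    right_v = val[-1:-3:-1] if idx.size >= 2 else val[-1:]
    return (np.concatenate([left_i, idx, right_i]),
            np.concatenate([left_v, val, right_v]))


def _natural_cubic(xi: np.ndarray, yi: np.ndarray, n_out: int) -> np.ndarray:
    """Natural cubic spline through (xi, yi), evaluated at 0..n_out-1.

    Small tridiagonal solve without the generic spline-class overhead;
    sifting calls this thousands of times on anchor sets of ~10-40 points.
    """
    h = np.diff(xi).astype(np.float64)
    k = xi.size
    if k == 2:
        slope = (yi[1] - yi[0]) / h[0]
        xq = np.arange(n_out, dtype=np.float64)
        return yi[0] + slope * (xq - xi[0])
    # second derivatives via the standard tridiagonal system (natural BC)
    rhs = np.zeros(k)
    rhs[1:-1] = 6.0 * ((yi[2:] - yi[1:-1]) / h[1:] - (yi[1:-1] - yi[:-2]) / h[:-1])
    ab = np.zeros((3, k))
    ab[0, 2:] = h[1:]
    ab[1, 0] = ab[1, -1] = 1.0
    ab[1, 1:-1] = 2.0 * (h[:-1] + h[1:])
    ab[2, :-2] = h[:-1]
    from scipy.linalg import solve_banded
    m2 = solve_banded((1, 1), ab, rhs)
    xq = np.arange(n_out, dtype=np.float64)
    seg = np.clip(np.searchsorted(xi, xq, side="right") - 1, 0, k - 2)
    dx = xq - xi[seg]
    hs = h[seg]
    a = (m2[seg + 1] - m2[seg]) / (6.0 * hs)
    b = m2[seg] / 2.0
    c = (yi[seg + 1] - yi[seg]) / hs - hs * (2.0 * m2[seg] + m2[seg + 1]) / 6.0
    return yi[seg] + dx * (c + dx * (b + dx * a))


def _mean_envelope(x: np.ndarray) -> Optional[np.ndarray]:
    maxima, minima = _extrema(x)
    if maxima.size < 2 or minima.size < 2:
        return None
    n = x.size
    mi, mv = _mirror_anchor(maxima, x[maxima], n)
    upper = _natural_cubic(mi.astype(np.float64), mv, n)
    ni, nv = _mirror_anchor(minima, x[minima], n)
    lower = _natural_cubic(ni.astype(np.float64), nv, n)
    return 0.5 * (upper + lower)


def emd(env: EnvelopeSignal | np.ndarray, cfg: RhythmConfig = RhythmConfig()) -> tuple[list[np.ndarray], np.ndarray]:
    """Empirical mode decomposition by sifting.

    Cubic-spline mean envelopes of maxima/minima are subtracted until the
    normalized squared difference between successive sift candidates falls
    below 0.2; decomposition stops after ``n_imfs`` IMFs or when the residual
    has fewer than 4 extrema (near-monotone).  The returned IMFs plus the
    residual reconstruct the input exactly (telescoping sum).
    """
    x = env.values if isinstance(env, EnvelopeSignal) else np.asarray(env, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise FeatureError("EMD input contains non-finite values")
    residual = x.copy()
    imfs: list[np.ndarray] = []
    for _ in range(cfg.n_imfs):
        maxima, minima = _extrema(residual)
        if maxima.size + minima.size < 4:
            break
        h = residual.copy()
        for _ in range(_MAX_SIFTS):
            mean_env = _mean_envelope(h)
            if mean_env is None:
                break
            h_new = h - mean_env
            denom = float(np.sum(h**2)) + 1e-30
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < _SIFT_THRESHOLD:
                break
        imfs.append(h)
        residual = residual - h
    return imfs, residual


# ---------------------------------------------------------------------------
# IMF summary statistics
# ---------------------------------------------------------------------------

def imf_features(imfs: Sequence[np.ndarray], residual: np.ndarray,
                 cfg: RhythmConfig = RhythmConfig()) -> np.ndarray:
    """Eight statistics per IMF, zero-padded to ``n_imfs`` modes.

    Per mode, in order: log energy; energy fraction of total (all modes +
    residual); mean and SD of instantaneous amplitude; mean and SD of
    instantaneous frequency (Hz, from the analytic phase derivative, clipped
    to [0, env_rate/2]); dominant spectral frequency (Hz); zero-crossing
    rate (/s).
    """
    rate = float(cfg.env_rate)
    energies = [float(np.sum(m**2)) for m in imfs]
    total = sum(energies) + float(np.sum(residual**2)) + 1e-30
    out = np.zeros(cfg.n_imfs * cfg.imf_stats)
    for i, m in enumerate(imfs[: cfg.n_imfs]):
        if m.size < 4 or energies[i] <= 0:
            continue
        analytic = sps.hilbert(m)
        amp = np.abs(analytic)
        phase = np.unwrap(np.angle(analytic))
        inst_f = np.clip(np.diff(phase) * rate / (2.0 * np.pi), 0.0, rate / 2.0)
        spec = np.abs(rfft(m)) ** 2
        freqs = rfftfreq(m.size, d=1.0 / rate)
        dom = float(freqs[1 + int(np.argmax(spec[1:]))]) if spec.size > 1 else 0.0
        zc = int(np.count_nonzero(np.diff(np.signbit(m)))) / (m.size / rate)
        out[i * 8: i * 8 + 8] = (
            np.log10(energies[i] + LOG_FLOOR),
            energies[i] / total,
            float(np.mean(amp)),
            float(np.std(amp)),
            float(np.mean(inst_f)),
            float(np.std(inst_f)),
            dom,
            zc,
        )
    return out


# ---------------------------------------------------------------------------
# TMS: temporal modulation spectrum
# ---------------------------------------------------------------------------

def _band_edges(lo: float, hi: float, n_bands: int) -> np.ndarray:
    """Uniform (linear-frequency) band edges.

    Linear spacing keeps every band wide enough (~470 Hz under defaults) to
    aggregate several voice harmonics, so per-band modulation content
    reflects amplitude dynamics rather than where individual harmonics sit
    on the frequency axis.
    """
    return np.linspace(lo, hi, n_bands + 1)


def tms_features(utt: Utterance, cfg: RhythmConfig = RhythmConfig()) -> np.ndarray:
    """Per-band modulation spectra over a 16-band log-spaced filterbank.

    The waveform is split into ``tms_bands`` bands equally spaced on a log
    frequency axis over ``tms_range``; each band's Hilbert envelope (computed
    at reduced rate by complex demodulation of the band spectrum) is
    resampled to ``env_rate`` and its mean-removed modulation power spectrum
    integrated into ``tms_mod_bins`` uniform bins over ``tms_mod_range``.
    Each band row is normalized to mass 1/``tms_bands`` (zero rows for silent
    bands), making the feature gain-invariant with total mass 1 for any
    input with energy in every band.
    """
    sr = utt.sample_rate
    lo, hi = cfg.tms_range
    if sr < 2 * hi:
        raise FeatureError(
            f"sample rate {sr} Hz < 2 x top band edge {hi} Hz; lower tms_range"
        )
    x = utt.samples
    n = x.size
    duration = n / sr
    nfft = next_fast_len(n)
    spectrum = rfft(x, n=nfft)
    bin_hz = sr / nfft
    edges = _band_edges(lo, hi, cfg.tms_bands)
    n_env = max(int(round(duration * cfg.env_rate)), 8)

    # with uniform band widths all bands share one demodulation length, so
    # the per-band envelopes and modulation spectra batch into single calls
    k1 = np.ceil(edges[:-1] / bin_hz).astype(int)
    k2 = np.floor(edges[1:] / bin_hz).astype(int)
    widths = np.maximum(k2 - k1 + 1, 0)
    m = next_fast_len(max(2 * int(widths.max()), n_env, 16))
    stacked = np.zeros((cfg.tms_bands, m), dtype=complex)
    for b in range(cfg.tms_bands):
        if widths[b] > 0:
            stacked[b, : widths[b]] = spectrum[k1[b]: k2[b] + 1]
    envelopes = np.abs(_ifft(stacked, axis=1)) * (2.0 * m / nfft)
    envelopes = sps.resample(envelopes, n_env, axis=1)

    v = envelopes - envelopes.mean(axis=1, keepdims=True)
    window = sps.windows.hann(n_env, sym=False)
    nfft2 = next_fast_len(max(n_env, 512))
    power = np.abs(rfft(v * window, n=nfft2, axis=1)) ** 2
    freqs = rfftfreq(nfft2, d=1.0 / cfg.env_rate)
    mlo, mhi = cfg.tms_mod_range
    bin_width = (mhi - mlo) / cfg.tms_mod_bins
    idx = np.floor((freqs - mlo) / bin_width).astype(int)
    valid = (idx >= 0) & (idx < cfg.tms_mod_bins)
    matrix = np.zeros((cfg.tms_bands, cfg.tms_mod_bins))
    np.add.at(matrix.T, idx[valid], power[:, valid].T)

    row_sums = matrix.sum(axis=1, keepdims=True)
    occupied = row_sums[:, 0] > 0
    matrix[occupied] /= row_sums[occupied] * cfg.tms_bands
    return matrix.ravel()


# ---------------------------------------------------------------------------
# Per-speaker assembly
# ---------------------------------------------------------------------------

def utterance_rhythm_features(utt: Utterance, cfg: RhythmConfig = RhythmConfig()) -> np.ndarray:
    """ENV + IMF + TMS feature block for a single utterance (length 432)."""
    env = extract_envelope(utt, cfg)
    env_block = env_spectrum_features(env, cfg)
    imfs, residual = emd(env, cfg)
    imf_block = imf_features(imfs, residual, cfg)
    tms_block = tms_features(utt, cfg)
    return np.concatenate([env_block, imf_block, tms_block])


def rhythm_vector(speaker: SpeakerRecord, cfg: RhythmConfig = RhythmConfig()) -> RhythmVector:
    """Utterance-major concatenation of per-utterance rhythm blocks (8640 dims)."""
    if len(speaker.utterances) != UTTERANCES_PER_SPEAKER:
        raise FeatureError(
            f"speaker {speaker.speaker_id!r} has {len(speaker.utterances)} "
            f"utterances; the rhythm vector requires {UTTERANCES_PER_SPEAKER}"
        )
    blocks = [utterance_rhythm_features(u, cfg) for u in speaker.utterances]
    values = np.concatenate(blocks)
    layout = {
        "per_utterance": cfg.per_utterance_dim,
        "blocks": {"ENV": cfg.env_spec_bins,
                   "IMF": cfg.n_imfs * cfg.imf_stats,
                   "TMS": cfg.tms_bands * cfg.tms_mod_bins},
        "n_utterances": UTTERANCES_PER_SPEAKER,
    }
    return RhythmVector(speaker_id=speaker.speaker_id, values=values, layout=layout)
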