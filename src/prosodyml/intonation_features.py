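"""Intonation-relevant features: f0 contours, time-normalized to 20 points.

The fundamental frequency is tracked per frame by normalized autocorrelation
(window-autocorrelation compensated, with parabolic peak interpolation and a
prefer-the-shortest-period rule against octave errors).  For each utterance
the voiced span of the track is linearly interpolated across unvoiced gaps
and resampled at 20 equidistant time points; concatenating the 20 utterances
of a speaker gives the fixed 400-dimensional intonation vector.  Contours
are kept in Hz and deliberately NOT per-speaker normalized: speaker-level
pitch differences are part of the signal the classifier is meant to model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, next_fast_len, rfft

from .corpus_io import SpeakerRecord, Utterance, UTTERANCES_PER_SPEAKER

__all__ = [
    "F0Config",
    "F0Track",
    "IntonationVector",
    "UnvoicedUtteranceError",
    "estimate_f0",
    "time_normalize",
    "intonation_vector",
]


class UnvoicedUtteranceError(ValueError):
    """Raised when an utterance has too little voicing for a contour."""

    def __init__(self, message: str, utterance_ids: Optional[list[str]] = None):
        super().__init__(message)
        self.utterance_ids = utterance_ids or []


@dataclass(frozen=True)
class F0Config:
    """Frame-based autocorrelation f0 tracker parameters."""

    frame_len: float = 0.040     # s; > 2 periods of fmin
    hop: float = 0.010           # s
    fmin: float = 60.0           # Hz
    fmax: float = 400.0          # Hz
    voicing_threshold: float = 0.45  # normalized autocorrelation peak
    rms_floor: float = 1e-4
    n_points: int = 20           # time-normalized contour length
    min_voiced_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.fmin >= self.fmax:
            raise ValueError("fmin must be < fmax")
        if self.frame_len <= 2.0 / self.fmin:
            raise ValueError("frame_len must exceed two periods of fmin")


@dataclass(frozen=True)
class F0Track:
    """Per-frame f0 estimates; unvoiced frames carry NaN."""

    times: np.ndarray     # frame centers, s
    f0: np.ndarray        # Hz, NaN where unvoiced
    voiced: np.ndarray    # bool

    @property
    def voiced_fraction(self) -> float:
        return float(np.mean(self.voiced)) if self.voiced.size else 0.0


@dataclass(frozen=True)
class IntonationVector:
    """400 f0 values: 20 time-normalized points x 20 utterances."""

    speaker_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))


def estimate_f0(utt: Utterance, cfg: F0Config = F0Config()) -> F0Track:
    """Track f0 by normalized autocorrelation of Hann-windowed frames.

    A frame is voiced iff its best normalized autocorrelation peak within
    the period range [1/fmax, 1/fmin] reaches ``voicing_threshold`` and its
    RMS reaches ``rms_floor``.  Among near-maximal peaks (>= 95% of the
    best) the shortest period wins, suppressing octave-down errors of
    strongly periodic frames; the winning lag is refined by parabolic
    interpolation.
    """
    sr = utt.sample_rate
    x = utt.samples
    flen = int(round(cfg.frame_len * sr))
    hop = int(round(cfg.hop * sr))
    if x.size < flen:
        return F0Track(times=np.empty(0), f0=np.empty(0), voiced=np.empty(0, bool))
    n_frames = 1 + (x.size - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n_frames)[:, None]
    frames = x[idx]
    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt(np.mean(frames**2, axis=1))

    window = sps.windows.hann(flen, sym=False)
    lag_min = max(int(np.floor(sr / cfg.fmax)), 2)
    lag_max = min(int(np.ceil(sr / cfg.fmin)), flen - 2)
    nfft = next_fast_len(2 * flen)

    spec = rfft(frames * window, n=nfft, axis=1)
    ac = irfft(np.abs(spec) ** 2, n=nfft, axis=1)[:, : lag_max + 2]
    ac0 = ac[:, 0:1] + 1e-30
    # compensate the taper the window imposes on the autocorrelation
    wspec = rfft(window, n=nfft)
    wac = irfft(np.abs(wspec) ** 2, n=nfft)[: lag_max + 2]
    wac = wac / (wac[0] + 1e-30)
    rho = (ac / ac0) / np.maximum(wac[None, :], 1e-3)
    rho = np.clip(rho, -1.5, 1.5)

    seg = rho[:, lag_min: lag_max + 1]
    interior = seg[:, 1:-1]
    is_peak = (interior >= seg[:, :-2]) & (interior >= seg[:, 2:])
    peak_vals = np.where(is_peak, interior, -np.inf)
    best = peak_vals.max(axis=1)
    near = peak_vals >= np.maximum(best[:, None] * 0.95, cfg.voicing_threshold)
    has_peak = near.any(axis=1)
    first = near.argmax(axis=1)  # shortest near-maximal period
    lags = (lag_min + 1 + first).astype(float)

    # parabolic refinement around the chosen integer lag
    li = lag_min + 1 + first
    y0 = rho[np.arange(n_frames), li - 1]
    y1 = rho[np.arange(n_frames), li]
    y2 = rho[np.arange(n_frames), li + 1]
    denom = y0 - 2 * y1 + y2
    shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / np.where(denom == 0, 1, denom), 0.0)
    lags = lags + np.clip(shift, -0.5, 0.5)

    voiced = has_peak & (best >= cfg.voicing_threshold) & (rms >= cfg.rms_floor)
    f0 = np.full(n_frames, np.nan)
    f0[voiced] = np.clip(sr / lags[voiced], cfg.fmin, cfg.fmax)
    times = (np.arange(n_frames) * hop + flen / 2) / sr
    return F0Track(times=times, f0=f0, voiced=voiced)


def time_normalize(track: F0Track, cfg: F0Config = F0Config(),
                   utterance_id: Optional[str] = None) -> np.ndarray:
    """Resample the voiced span of a track at ``n_points`` equidistant times.

    f0 is linearly interpolated across unvoiced gaps strictly inside the
    voiced span (first to last voiced frame).  Raises
    :class:`UnvoicedUtteranceError` when less than ``min_voiced_fraction``
    of frames are voiced.
    """
    if track.voiced_fraction < cfg.min_voiced_fraction:
        raise UnvoicedUtteranceError(
            f"utterance {utterance_id!r}: voiced fraction "
            f"{track.voiced_fraction:.3f} below {cfg.min_voiced_fraction}",
            utterance_ids=[utterance_id] if utterance_id else [],
        )
    xs = track.times[track.voiced]
    ys = track.f0[track.voiced]
    grid = np.linspace(xs[0], xs[-1], cfg.n_points)
    return np.interp(grid, xs, ys)


def intonation_vector(speaker: SpeakerRecord, cfg: F0Config = F0Config()) -> IntonationVector:
    """Utterance-major concatenation of 20-point contours (400 values)."""
    if len(speaker.utterances) != UTTERANCES_PER_SPEAKER:
        raise UnvoicedUtteranceError(
            f"speaker {speaker.speaker_id!r} has {len(speaker.utterances)} "
            f"utterances; the intonation vector requires {UTTERANCES_PER_SPEAKER}"
        )
    contours = []
    failures: list[str] = []
    for utt in speaker.utterances:
        track = estimate_f0(utt, cfg)
        try:
            contours.append(time_normalize(track, cfg, utterance_id=utt.utterance_id))
        except UnvoicedUtteranceError:
            failures.append(utt.utterance_id)
    if failures:
        raise UnvoicedUtteranceError(
            f"speaker {speaker.speaker_id!r}: utterances below the voicing "
            f"floor: {failures}",
            utterance_ids=failures,
        )
    return IntonationVector(speaker_id=speaker.speaker_id,
                            values=np.concatenate(contours))
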