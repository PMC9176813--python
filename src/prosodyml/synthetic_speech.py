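"""Synthetic two-group, two-language speech cohorts.

The generator emulates exactly the statistical structure the downstream
analysis assumes, with rhythm and intonation independently controllable:

* **Rhythm** lives in the timing and amplitude of syllable events.  Syllable
  inter-onset intervals (IOIs) are gamma distributed — strictly positive,
  with mean 1/rate and a directly controllable coefficient of variation.
  Stress-timed profiles alternate strong/weak syllables in duration and
  amplitude; syllable-timed profiles do not.
* **Intonation** lives in the f0 trajectory.  Intonation-language profiles
  use a declining utterance-level baseline (declination); tone-language
  profiles draw one of a small inventory of per-syllable pitch-target shapes,
  emulating lexical tone at syllable scale.

Each syllable is rendered as a harmonic complex (first 8 harmonics, 1/k
amplitude roll-off) plus a low-level broadband noise component (emulating the
frication/aspiration energy of real speech, and keeping every acoustic
filterbank band occupied regardless of f0), windowed by a raised-cosine
amplitude burst.  Rhythm, f0 and noise draws come from three independent
seeded streams per utterance so that a group effect injected into one channel
cannot leak into the other.

Group effects (rate shift, duration-CV shift, f0 median shift, f0 range
scale) default to null; cohort generation maps ASD -> effect, TD -> null.
"""

from __future__ import annotations

import enum
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numba
import numpy as np

from .corpus_io import (
    Gender,
    Group,
    Language,
    SpeakerRecord,
    Utterance,
    UTTERANCES_PER_SPEAKER,
)

__all__ = [
    "Timing",
    "F0Mode",
    "LanguageProfile",
    "GroupEffect",
    "SynthesisParams",
    "UtterancePlan",
    "SynthesisError",
    "synth_utterance",
    "generate_speaker",
    "generate_cohort",
    "speaker_plans",
    "EN_PROFILE",
    "YUE_PROFILE",
]


class SynthesisError(ValueError):
    """Raised for parameter combinations outside the generator's valid ranges."""


class Timing(str, enum.Enum):
    STRESS_TIMED = "stress_timed"
    SYLLABLE_TIMED = "syllable_timed"


class F0Mode(str, enum.Enum):
    INTONATION = "intonation"
    TONE = "tone"


#: Per-syllable tone target shapes, as (start, end) in units of half the
#: utterance f0 excursion (semitones).  Six shapes loosely patterned on the
#: Cantonese inventory: high level, high rising, mid level, low falling,
#: low rising, low level.
DEFAULT_TONE_INVENTORY: tuple[tuple[float, float], ...] = (
    (1.0, 1.0),
    (0.0, 1.0),
    (0.3, 0.3),
    (-0.5, -1.0),
    (-0.5, 0.3),
    (-0.5, -0.5),
)


@dataclass(frozen=True)
class LanguageProfile:
    """Rhythm-typology and f0-mode profile of one language."""

    name: Language
    timing: Timing
    f0_mode: F0Mode
    tone_inventory: tuple[tuple[float, float], ...] = DEFAULT_TONE_INVENTORY
    stress_alternation_depth: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.stress_alternation_depth < 1.0):
            raise SynthesisError("stress_alternation_depth must be in [0, 1)")

    @staticmethod
    def default(language: Language | str) -> "LanguageProfile":
        language = Language(language)
        return EN_PROFILE if language is Language.EN else YUE_PROFILE


#: English default: stress-timed, intonation language.
EN_PROFILE = LanguageProfile(
    name=Language.EN,
    timing=Timing.STRESS_TIMED,
    f0_mode=F0Mode.INTONATION,
    stress_alternation_depth=0.4,
)

#: Cantonese default: syllable-timed, tone language.
YUE_PROFILE = LanguageProfile(
    name=Language.YUE,
    timing=Timing.SYLLABLE_TIMED,
    f0_mode=F0Mode.TONE,
)


@dataclass(frozen=True)
class GroupEffect:
    """Additive/multiplicative group-level shifts; defaults are the null effect."""

    rate_shift: float = 0.0          # Hz added to mean syllable rate
    duration_cv_shift: float = 0.0   # additive change to IOI coefficient of variation
    f0_median_shift: float = 0.0     # Hz added to speaker f0 median
    f0_range_scale: float = 1.0      # multiplicative factor on f0 excursion

    @staticmethod
    def null() -> "GroupEffect":
        return GroupEffect()

    @property
    def is_null(self) -> bool:
        return (
            self.rate_shift == 0.0
            and self.duration_cv_shift == 0.0
            and self.f0_median_shift == 0.0
            and self.f0_range_scale == 1.0
        )


@dataclass(frozen=True)
class SynthesisParams:
    """Free parameters of the generator (cohort-level constants)."""

    sample_rate: int = 16000
    utterance_duration: tuple[float, float] = (1.5, 3.0)  # s, uniform range
    base_syllable_rate: float = 4.5        # Hz
    base_duration_cv: float = 0.25         # dimensionless
    base_f0_median_m: float = 120.0        # Hz, male speakers
    base_f0_median_f: float = 210.0        # Hz, female speakers
    base_f0_excursion: float = 4.0         # semitones, utterance-level range
    noise_rel: float = 0.12                # broadband component, rel. harmonic RMS
    silence_floor: float = 0.10            # min fraction of each IOI left silent
    # speaker-level lognormal jitter SDs (log scale)
    speaker_rate_sd: float = 0.03
    speaker_median_sd: float = 0.04
    speaker_excursion_sd: float = 0.10
    speaker_tilt_sd: float = 0.30  # SD of the spectral-tilt exponent
    speaker_breathiness_sd: float = 0.40  # lognormal SD of noise/harmonic ratio

    def __post_init__(self) -> None:
        lo, hi = self.utterance_duration
        if not (0.2 <= lo <= hi):
            raise SynthesisError("utterance_duration range must be >= 0.2 s and ordered")
        for name in ("sample_rate", "base_syllable_rate", "base_duration_cv",
                     "base_f0_median_m", "base_f0_median_f", "base_f0_excursion"):
            if getattr(self, name) <= 0:
                raise SynthesisError(f"{name} must be positive")

    def base_f0_median(self, gender: Gender) -> float:
        return self.base_f0_median_m if Gender(gender) is Gender.M else self.base_f0_median_f


RATE_BOUNDS = (1.0, 10.0)   # Hz, admissible syllable rates
F0_BOUNDS = (60.0, 400.0)   # Hz, admissible f0


def _validate_effect(params: SynthesisParams, effect: GroupEffect) -> None:
    rate = params.base_syllable_rate + effect.rate_shift
    if not (RATE_BOUNDS[0] <= rate <= RATE_BOUNDS[1]):
        raise SynthesisError(
            f"resulting syllable rate {rate:.2f} Hz outside {RATE_BOUNDS}"
        )
    if params.base_duration_cv + effect.duration_cv_shift <= 0:
        raise SynthesisError("resulting duration CV must be positive")
    if effect.f0_range_scale <= 0:
        raise SynthesisError("f0_range_scale must be positive")
    for med in (params.base_f0_median_m, params.base_f0_median_f):
        shifted = med + effect.f0_median_shift
        if not (F0_BOUNDS[0] <= shifted <= F0_BOUNDS[1]):
            raise SynthesisError(
                f"resulting f0 median {shifted:.1f} Hz outside {F0_BOUNDS}"
            )


@dataclass(frozen=True)
class UtterancePlan:
    """Ground-truth description of one synthetic utterance (pre-rendering)."""

    duration: float
    onsets: np.ndarray            # s
    burst_durations: np.ndarray   # s
    amplitudes: np.ndarray
    f0_start: np.ndarray          # Hz at burst start
    f0_end: np.ndarray            # Hz at burst end

    @property
    def n_syllables(self) -> int:
        return int(self.onsets.size)

    @property
    def syllable_rate(self) -> float:
        return self.n_syllables / self.duration


@dataclass(frozen=True)
class SpeakerLatents:
    """Speaker-level idiosyncrasies: prosodic jitter factors and vocal tract.

    The vocal-tract part (random spectral tilt plus a few Gaussian resonance
    bumps, fixed per speaker) emulates the large between-speaker variation in
    spectral envelope that real cohorts show; it dominates per-band energy
    differences so that voice pitch placement alone does not individuate the
    spectral profile.
    """

    rate: float
    median: float
    excursion: float
    tilt: float                 # exponent of the spectral tilt
    breathiness: float          # speaker factor on the noise-to-harmonic ratio
    resonance_freqs: np.ndarray  # Hz
    resonance_gains: np.ndarray  # linear amplitude gain of each bump
    resonance_bws: np.ndarray    # Gaussian bump SD, Hz
    noise_tilt: float = 0.0      # tilt of the aspiration-noise spectrum
    noise_res_freqs: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise_res_gains: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise_res_bws: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise_lowband: float = 1.0   # gain of the low-frequency (<~800 Hz) noise floor


def _draw_latents(params: SynthesisParams, rng: np.random.Generator) -> SpeakerLatents:
    n_res = 3
    freqs = np.exp(rng.uniform(np.log(150.0), np.log(4500.0), size=n_res))
    nfreqs = np.exp(rng.uniform(np.log(150.0), np.log(6500.0), size=n_res))
    return SpeakerLatents(
        rate=float(rng.lognormal(0.0, params.speaker_rate_sd)),
        median=float(rng.lognormal(0.0, params.speaker_median_sd)),
        excursion=float(rng.lognormal(0.0, params.speaker_excursion_sd)),
        tilt=float(rng.normal(0.0, params.speaker_tilt_sd)),
        breathiness=float(rng.lognormal(0.0, params.speaker_breathiness_sd)),
        resonance_freqs=freqs,
        resonance_gains=rng.lognormal(0.3, 0.5, size=n_res),
        resonance_bws=freqs * rng.uniform(0.15, 0.35, size=n_res),
        noise_tilt=float(rng.normal(0.0, params.speaker_tilt_sd)),
        noise_res_freqs=nfreqs,
        noise_res_gains=rng.lognormal(0.5, 0.6, size=n_res),
        noise_res_bws=nfreqs * rng.uniform(0.2, 0.5, size=n_res),
        noise_lowband=float(rng.lognormal(0.0, 1.0)),
    )


def _magnitude_response(freqs: np.ndarray, tilt: float, res_f: np.ndarray,
                        res_g: np.ndarray, res_bw: np.ndarray) -> np.ndarray:
    """Spectral tilt plus Gaussian resonance bumps on an rfft frequency grid."""
    h = ((freqs + 200.0) / 1000.0) ** tilt
    for cf, g, bw in zip(res_f, res_g, res_bw):
        h = h * (1.0 + g * np.exp(-0.5 * ((freqs - cf) / bw) ** 2))
    return h


def _vocal_tract_response(latents: SpeakerLatents, freqs: np.ndarray) -> np.ndarray:
    return _magnitude_response(freqs, latents.tilt, latents.resonance_freqs,
                               latents.resonance_gains, latents.resonance_bws)


def _noise_colour_response(latents: SpeakerLatents, freqs: np.ndarray) -> np.ndarray:
    return _magnitude_response(freqs, latents.noise_tilt, latents.noise_res_freqs,
                               latents.noise_res_gains, latents.noise_res_bws)


def _plan_utterance(
    params: SynthesisParams,
    profile: LanguageProfile,
    effect: GroupEffect,
    gender: Gender,
    latents: SpeakerLatents,
    rng_rhythm: np.random.Generator,
    rng_f0: np.random.Generator,
) -> UtterancePlan:
    duration = float(rng_rhythm.uniform(*params.utterance_duration))

    # --- syllable timing (rhythm channel) ---
    rate = params.base_syllable_rate * latents.rate + effect.rate_shift
    rate = float(np.clip(rate, *RATE_BOUNDS))
    cv = max(params.base_duration_cv + effect.duration_cv_shift, 0.02)
    mean_ioi = 1.0 / rate
    shape = 1.0 / cv**2
    n_guess = int(duration / mean_ioi * 2) + 12
    iois = rng_rhythm.gamma(shape, mean_ioi * cv**2, size=n_guess)
    amps = rng_rhythm.lognormal(0.0, 0.10, size=n_guess)
    if profile.timing is Timing.STRESS_TIMED and profile.stress_alternation_depth > 0:
        d = profile.stress_alternation_depth
        weak = np.arange(n_guess) % 2 == 1
        iois[weak] *= 1.0 - d
        amps[weak] *= 1.0 - d
        # keep base_syllable_rate the *mean* syllable rate across profiles
        iois /= 1.0 - d / 2.0

    onsets = np.concatenate(([0.0], np.cumsum(iois[:-1])))
    keep = onsets < duration - 2.0 * MIN_BURST_S
    onsets, iois, amps = onsets[keep], iois[keep], amps[keep]
    if onsets.size == 0:  # pathological ultra-slow draw; force one syllable
        onsets = np.array([0.0])
        iois = np.array([duration])
        amps = np.array([1.0])
    bursts = (1.0 - params.silence_floor) * iois
    bursts = np.minimum(bursts, duration - onsets)
    bursts = np.maximum(bursts, MIN_BURST_S)

    # --- f0 targets (intonation channel, independent RNG stream) ---
    median = params.base_f0_median(gender) * latents.median + effect.f0_median_shift
    exc_st = (
        params.base_f0_excursion
        * latents.excursion
        * effect.f0_range_scale
        * float(rng_f0.lognormal(0.0, 0.05))
    )
    # smooth utterance-level wiggle in normalized time: its roughness is
    # independent of how many syllables the rhythm channel happened to draw
    wiggle_amp = rng_f0.normal(0.0, 0.25, size=3) / np.arange(1, 4)
    wiggle_phase = rng_f0.uniform(0.0, 2.0 * np.pi, size=3)

    def wiggle(t: np.ndarray) -> np.ndarray:
        return sum(
            a * np.sin(2.0 * np.pi * (j + 1) * t + p)
            for j, (a, p) in enumerate(zip(wiggle_amp, wiggle_phase))
        )

    # normalized position within the *spoken* span: the declination and
    # wiggle cover the phrase itself, so contour shape is invariant to how
    # much trailing silence the timing channel happened to leave
    span_end = float(min(onsets[-1] + bursts[-1], duration))
    t0 = onsets / span_end
    t1 = np.minimum(onsets + bursts, span_end) / span_end
    if profile.f0_mode is F0Mode.INTONATION:
        # declination: +exc/2 semitones at utterance start, -exc/2 at the end
        st_start = exc_st * (0.5 - t0) + wiggle(t0) + rng_f0.normal(0.0, 0.1, size=t0.size)
        st_end = exc_st * (0.5 - t1) + wiggle(t1) + rng_f0.normal(0.0, 0.1, size=t1.size)
    else:
        inventory = np.asarray(profile.tone_inventory, dtype=float)
        tones = inventory[rng_f0.integers(0, len(inventory), size=t0.size)]
        trend = -0.5  # gentle downdrift in semitones over the utterance
        st_start = tones[:, 0] * exc_st / 2.0 + trend * t0 + wiggle(t0) * 0.3 + rng_f0.normal(0.0, 0.1, size=t0.size)
        st_end = tones[:, 1] * exc_st / 2.0 + trend * t1 + wiggle(t1) * 0.3 + rng_f0.normal(0.0, 0.1, size=t1.size)

    f0_start = np.clip(median * 2.0 ** (st_start / 12.0), *F0_BOUNDS)
    f0_end = np.clip(median * 2.0 ** (st_end / 12.0), *F0_BOUNDS)
    return UtterancePlan(
        duration=duration,
        onsets=onsets,
        burst_durations=bursts,
        amplitudes=amps,
        f0_start=f0_start,
        f0_end=f0_end,
    )


MIN_BURST_S = 0.04  # shortest admissible syllable burst

@numba.njit(cache=False)
def _harmonic_complex(phase: np.ndarray, k_max: int) -> np.ndarray:
    """Unit-RMS sum_{k<=k_max} sin(k*phase)/k via the Chebyshev recurrence
    sin((k+1)p) = 2 cos(p) sin(kp) - sin((k-1)p)."""
    m = phase.size
    out = np.empty(m)
    inv_sq = 0.0
    for k in range(1, k_max + 1):
        inv_sq += 1.0 / (k * k)
    norm = 1.0 / np.sqrt(inv_sq / 2.0)
    for i in range(m):
        c = 2.0 * np.cos(phase[i])
        s_prev = 0.0
        s_cur = np.sin(phase[i])
        acc = s_cur
        for k in range(2, k_max + 1):
            s_prev, s_cur = s_cur, c * s_cur - s_prev
            acc += s_cur / k
        out[i] = acc * norm
    return out


#: Fixed upper edge of the harmonic series in Hz.  Ending the series at a
#: frequency (rather than a partial count) keeps the voiced spectral extent
#: identical across speakers, so spectral band occupancy reflects the vocal
#: tract, not the voice pitch.
HARMONIC_CEILING_HZ = 3500.0


def _noise_response(latents: Optional[SpeakerLatents], freqs: np.ndarray) -> np.ndarray:
    """Magnitude response of the aspiration-noise channel.

    The base shape is flat to 500 Hz with a -6 dB/oct roll-off above, which
    keeps the harmonic-to-noise ratio (and hence voicing detectability)
    stable under the speaker-level spectral tilt while still occupying every
    acoustic band of the modulation filterbank.  On top of that, each
    speaker imposes their own tilt, resonance bumps and low-frequency floor
    on the noise alone, so the per-band noise floor relative to the
    harmonics varies speaker by speaker, as breathiness and frication
    placement do in real voices.
    """
    response = 1.0 / np.sqrt(1.0 + (freqs / 500.0) ** 2)
    if latents is not None and latents.noise_res_freqs.size:
        response = response * _noise_colour_response(latents, freqs)
        low_weight = 1.0 / (1.0 + (freqs / 800.0) ** 4)
        response = response * latents.noise_lowband ** low_weight
    return response


def _syllable_noise(m: int, fast_len: int, response: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS coloured Gaussian noise, synthesized in the frequency domain."""
    from scipy.fft import irfft
    n_bins = fast_len // 2 + 1
    spectrum = (rng.standard_normal(n_bins) + 1j * rng.standard_normal(n_bins))
    shaped = irfft(spectrum * response, n=fast_len)[:m]
    rms = np.sqrt(np.mean(shaped**2)) + 1e-30
    return shaped / rms


def _render(plan: UtterancePlan, params: SynthesisParams,
            rng_noise: np.random.Generator,
            latents: Optional[SpeakerLatents] = None,
            response_cache: Optional[dict] = None) -> np.ndarray:
    from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

    sr = params.sample_rate
    n = int(round(plan.duration * sr))
    x = np.zeros(n)
    if response_cache is None:
        response_cache = {}

    def responses(fast_len: int) -> tuple[np.ndarray, Optional[np.ndarray]]:
        if fast_len not in response_cache:
            freqs = rfftfreq(fast_len, d=1.0 / sr)
            vt = (_vocal_tract_response(latents, freqs)
                  if latents is not None and latents.resonance_freqs.size else None)
            response_cache[fast_len] = (_noise_response(latents, freqs), vt)
        return response_cache[fast_len]
    for onset, bd, amp, fa, fb in zip(
        plan.onsets, plan.burst_durations, plan.amplitudes,
        plan.f0_start, plan.f0_end
    ):
        i0 = int(round(onset * sr))
        m = min(int(round(bd * sr)), n - i0)
        if m < 16:
            continue
        frac = np.arange(m) / m
        inst_f0 = fa * (fb / fa) ** frac  # geometric glide between targets
        phase = 2.0 * np.pi * np.cumsum(inst_f0) / sr
        k_max = max(int(HARMONIC_CEILING_HZ / max(fa, fb)), 1)
        harm = _harmonic_complex(phase, k_max)
        window = 0.5 * (1.0 - np.cos(2.0 * np.pi * frac))
        # quantize the padded length so the per-speaker response cache hits
        fast_len = next_fast_len(((m + 255) // 256) * 256)
        noise_resp, vt_resp = responses(fast_len)
        noise_level = params.noise_rel * (latents.breathiness if latents is not None else 1.0)
        seg = amp * window * (harm + noise_level * _syllable_noise(m, fast_len, noise_resp, rng_noise))
        if vt_resp is not None:
            # speaker-level spectral shaping, RMS-preserving per syllable so
            # the vocal tract colours the spectrum without touching the
            # planned amplitude envelope (the rhythm channel)
            target_rms = np.sqrt(np.mean(seg**2))
            shaped = irfft(rfft(seg, n=fast_len) * vt_resp, n=fast_len)[:m]
            shaped_rms = np.sqrt(np.mean(shaped**2)) + 1e-30
            seg = shaped * (target_rms / shaped_rms)
        x[i0:i0 + m] += seg
    peak = np.max(np.abs(x))
    if peak > 0:
        x *= 0.9 / peak
    return x


def _streams(seed: int, speaker_id: str, utt_index: int) -> tuple[np.random.Generator, ...]:
    """Three independent per-utterance RNG streams (rhythm, f0, noise)."""
    sid = zlib.crc32(speaker_id.encode("utf-8"))
    return tuple(
        np.random.default_rng(np.random.SeedSequence([int(seed), sid, utt_index, tag]))
        for tag in (0, 1, 2)
    )


def synth_utterance(
    params: SynthesisParams,
    profile: LanguageProfile,
    effect: GroupEffect,
    seed: int,
    gender: Gender = Gender.M,
    latents: Optional[SpeakerLatents] = None,
    utterance_id: str = "synthetic",
) -> Utterance:
    """Synthesize one utterance; bitwise-deterministic given *seed*."""
    _validate_effect(params, effect)
    if latents is None:
        latents = SpeakerLatents(1.0, 1.0, 1.0, 0.0, 1.0, np.empty(0),
                                 np.empty(0), np.empty(0))
    rng_rhythm, rng_f0, rng_noise = _streams(seed, utterance_id, 0)
    plan = _plan_utterance(params, profile, effect, gender, latents, rng_rhythm, rng_f0)
    x = _render(plan, params, rng_noise, latents)
    return Utterance(utterance_id=utterance_id, samples=x, sample_rate=params.sample_rate)


def speaker_plans(
    speaker_id: str,
    group: Group | str,
    language: Language | str,
    params: Optional[SynthesisParams] = None,
    effect_by_group: Optional[Mapping[Group, GroupEffect]] = None,
    seed: int = 0,
    gender: Gender | str = Gender.M,
    profile: Optional[LanguageProfile] = None,
) -> list[UtterancePlan]:
    """Ground-truth utterance plans for a speaker, without audio rendering.

    Useful for fast distributional checks of the generator itself (syllable
    rates, IOI dispersion, f0 targets) that would otherwise require waveform
    synthesis and re-tracking.
    """
    params = params or SynthesisParams()
    group = Group(group)
    profile = profile or LanguageProfile.default(language)
    effect = _effect_for(group, effect_by_group)
    _validate_effect(params, effect)
    sid = zlib.crc32(speaker_id.encode("utf-8"))
    latents = _draw_latents(
        params, np.random.default_rng(np.random.SeedSequence([int(seed), sid, 9999]))
    )
    plans = []
    for i in range(UTTERANCES_PER_SPEAKER):
        rng_rhythm, rng_f0, _ = _streams(seed, speaker_id, i)
        plans.append(
            _plan_utterance(params, profile, effect, Gender(gender), latents,
                            rng_rhythm, rng_f0)
        )
    return plans


def _effect_for(group: Group, effect_by_group: Optional[Mapping[Group, GroupEffect]]) -> GroupEffect:
    if effect_by_group is None:
        return GroupEffect.null()
    return effect_by_group.get(group, GroupEffect.null())


def generate_speaker(
    speaker_id: str,
    group: Group | str,
    language: Language | str,
    params: Optional[SynthesisParams] = None,
    effect_by_group: Optional[Mapping[Group, GroupEffect]] = None,
    seed: int = 0,
    gender: Gender | str = Gender.M,
    age: Optional[float] = None,
    profile: Optional[LanguageProfile] = None,
) -> SpeakerRecord:
    """Generate a SpeakerRecord with exactly 20 synthetic utterances.

    Per-utterance RNG streams are derived deterministically from
    ``(seed, speaker_id, utterance_index)``, so different speakers under the
    same seed yield different waveforms and repeated calls are reproducible.
    """
    params = params or SynthesisParams()
    group = Group(group)
    language = Language(language)
    gender = Gender(gender)
    profile = profile or LanguageProfile.default(language)
    effect = _effect_for(group, effect_by_group)
    _validate_effect(params, effect)

    sid = zlib.crc32(speaker_id.encode("utf-8"))
    latents = _draw_latents(
        params, np.random.default_rng(np.random.SeedSequence([int(seed), sid, 9999]))
    )
    utterances = []
    response_cache: dict = {}
    for i in range(UTTERANCES_PER_SPEAKER):
        rng_rhythm, rng_f0, rng_noise = _streams(seed, speaker_id, i)
        plan = _plan_utterance(params, profile, effect, gender, latents,
                               rng_rhythm, rng_f0)
        x = _render(plan, params, rng_noise, latents, response_cache)
        utterances.append(
            Utterance(utterance_id=f"{speaker_id}_u{i:02d}", samples=x,
                      sample_rate=params.sample_rate)
        )
    return SpeakerRecord(
        speaker_id=speaker_id, group=group, language=language,
        utterances=utterances, age=age, gender=gender,
    )


def generate_cohort(
    n_asd: int,
    n_td: int,
    language: Language | str,
    params: Optional[SynthesisParams] = None,
    effect: Optional[GroupEffect] = None,
    seed: int = 0,
    profile: Optional[LanguageProfile] = None,
    genders: Optional[Sequence[Gender]] = None,
) -> list[SpeakerRecord]:
    """Generate a two-group cohort (ASD block first, then TD).

    Gender alternates M/F within each group unless *genders* is given.  The
    group effect applies to ASD speakers only; TD speakers are always null.
    """
    if n_asd < 2 or n_td < 2:
        raise SynthesisError("need at least 2 speakers per class for cross-validation")
    language = Language(language)
    params = params or SynthesisParams()
    effect_by_group = {Group.ASD: effect or GroupEffect.null(),
                       Group.TD: GroupEffect.null()}
    speakers = []
    for group, count in ((Group.ASD, n_asd), (Group.TD, n_td)):
        for j in range(count):
            gender = (
                genders[j % len(genders)] if genders
                else (Gender.M if j % 2 == 0 else Gender.F)
            )
            speakers.append(
                generate_speaker(
                    speaker_id=f"{language.value}_{group.value}_{j:03d}",
                    group=group,
                    language=language,
                    params=params,
                    effect_by_group=effect_by_group,
                    seed=seed,
                    gender=gender,
                    profile=profile,
                )
            )
    return speakers
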