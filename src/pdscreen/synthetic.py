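"""Synthetic two-group cohort generator (PD patients vs healthy controls).

The confidential study data cannot ship, so every downstream stage is
exercised on a simulated cohort that reproduces the *structure* of the
recordings: 68-point facial-landmark series at a fixed frame rate,
mono PCM speech recordings per vocal task, and a metadata table with
group, age and gender.

Group effects are injected where Parkinson's disease is known to act,
with directions from the clinical literature and magnitudes chosen here
as free parameters (no quantitative effect sizes are published for the
original cohort):

* face — reduced mouth-opening amplitude (hypomimia), lower blink rate,
  slow drift of one mouth corner, static mouth-corner asymmetry;
* voice — raised jitter and shimmer, lowered harmonics-to-noise ratio,
  larger slow F0 wander in sustained vowels, irregular and slowed
  diadochokinesis.

Age and gender confounds enter *additively on the extracted scalar
features* (:func:`inject_confounds`), which makes linear residualization
exactly correct by construction and therefore testable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .acoustic import Waveform, write_wav
from .facial import LandmarkSeries

__all__ = [
    "GroupFaceParams",
    "GroupVoiceParams",
    "EffectProfile",
    "ConfoundProfile",
    "SyntheticConfig",
    "CohortBundle",
    "ConfigurationError",
    "neutral_template",
    "synth_vowel",
    "synth_ddk",
    "synth_connected_speech",
    "synth_landmark_series",
    "generate_cohort",
    "write_cohort",
    "inject_confounds",
    "synthesize_feature_table",
]

DEFAULT_TASKS = ("TSK3", "TSK18", "TSK41", "TSK42")


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration; message names the field."""


class SamplingError(ValueError):
    pass


class DegenerateSpacingError(ValueError):
    pass


class LayoutError(ValueError):
    pass


# ---------------------------------------------------------------------------
# effect / confound profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupFaceParams:
    """Facial-dynamics parameters of one group."""

    mouth_amplitude_mult: float = 1.0     # scales the mouth-opening sinusoid
    blink_rate_hz: float = 0.35           # exponential inter-blink rate
    drift_slope: float = 0.0005           # mouth-corner sag, face-lengths/s
    asymmetry_offset: float = 0.005       # static corner offset, face-lengths
    eyebrow_noise_sd: float = 0.3         # template units per frame
    point_noise_sd: float = 0.12          # jitter on all points, template units


@dataclass(frozen=True)
class GroupVoiceParams:
    """Voice parameters of one group."""

    jitter_pct: float = 0.7
    shimmer_pct: float = 3.0
    hnr_db: float = 22.0
    relf0sd: float = 0.015                # slow F0 wander, relative
    ddk_rate_hz: float = 6.0
    ddk_reg_sd_s: float = 0.012


_PD_FACE = GroupFaceParams(mouth_amplitude_mult=0.45, blink_rate_hz=0.15,
                           drift_slope=0.004, asymmetry_offset=0.03)
_PD_VOICE = GroupVoiceParams(jitter_pct=2.5, shimmer_pct=9.0, hnr_db=10.0,
                             relf0sd=0.06, ddk_rate_hz=4.5, ddk_reg_sd_s=0.05)


@dataclass(frozen=True)
class EffectProfile:
    """Per-group facial and voice parameters.

    The default profile is the documented reference profile used for
    validation: effects strong enough that the planted group signal
    dominates subject-level variability.  :meth:`null` sets PD equal to
    HC in every field, removing all group structure.
    """

    pd_face: GroupFaceParams = _PD_FACE
    hc_face: GroupFaceParams = GroupFaceParams()
    pd_voice: GroupVoiceParams = _PD_VOICE
    hc_voice: GroupVoiceParams = GroupVoiceParams()

    def __post_init__(self) -> None:
        for name, gp in (("pd_face", self.pd_face), ("hc_face", self.hc_face)):
            if gp.mouth_amplitude_mult <= 0:
                raise ConfigurationError(f"{name}.mouth_amplitude_mult must be > 0")
            if gp.blink_rate_hz < 0:
                raise ConfigurationError(f"{name}.blink_rate_hz must be >= 0")
        for name, gv in (("pd_voice", self.pd_voice), ("hc_voice", self.hc_voice)):
            if gv.ddk_rate_hz <= 0:
                raise ConfigurationError(f"{name}.ddk_rate_hz must be > 0")

    @classmethod
    def null(cls) -> "EffectProfile":
        hc_f, hc_v = GroupFaceParams(), GroupVoiceParams()
        return cls(pd_face=hc_f, hc_face=hc_f, pd_voice=hc_v, hc_voice=hc_v)

    def face(self, group: str) -> GroupFaceParams:
        return self.pd_face if group == "PD" else self.hc_face

    def voice(self, group: str) -> GroupVoiceParams:
        return self.pd_voice if group == "PD" else self.hc_voice


@dataclass(frozen=True)
class ConfoundProfile:
    """Linear age/gender shifts added to extracted scalar features.

    ``age_coeff`` is the shift per year of (age - 65) and
    ``gender_coeff`` the male-vs-female shift, both in units of each
    feature's own standard deviation.  A zero profile leaves features
    independent of the confounds.
    """

    age_range: tuple[float, float] = (45.0, 85.0)
    gender_ratio: float = 0.45            # fraction female
    age_coeff: float = 0.0
    gender_coeff: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gender_ratio <= 1.0):
            raise ConfigurationError("gender_ratio must lie in [0, 1]")
        for f in ("age_coeff", "gender_coeff"):
            if not math.isfinite(getattr(self, f)):
                raise ConfigurationError(f"{f} must be finite")


@dataclass(frozen=True)
class SyntheticConfig:
    """Everything needed to generate one reproducible cohort."""

    n_pd: int = 73
    n_hc: int = 46
    fps: float = 25.0
    audio_fs: float = 48000.0
    task_codes: tuple[str, ...] = DEFAULT_TASKS
    effect: EffectProfile = field(default_factory=EffectProfile)
    confound: ConfoundProfile = field(default_factory=ConfoundProfile)
    seed: int = 0
    vowel_s: float = 2.0
    ddk_s: float = 2.5
    speech_s: float = 8.0
    video_s: float = 6.0

    def __post_init__(self) -> None:
        if self.n_pd < 2:
            raise ConfigurationError("n_pd must be >= 2")
        if self.n_hc < 2:
            raise ConfigurationError("n_hc must be >= 2")
        if self.fps <= 0:
            raise ConfigurationError("fps must be > 0")
        if self.audio_fs < 8000:
            raise ConfigurationError("audio_fs must be >= 8000")
        for t in self.task_codes:
            if not (t.startswith("TSK") and t[3:].isdigit() and 1 <= int(t[3:]) <= 43):
                raise ConfigurationError(f"task_codes contains unknown code {t!r}")


# ---------------------------------------------------------------------------
# canonical 68-point neutral face (image coordinates, y down, face length 100)
# ---------------------------------------------------------------------------

def neutral_template() -> np.ndarray:
    """Neutral 68-point face, iBUG ordering (1-based outside, 0-based here).

    Image convention: origin top-left, y increases downward.  Landmark 28
    (nose-bridge top) sits at (100, 60) and landmark 9 (chin) at
    (100, 160), so the face length is exactly 100 template units.
    """
    pts = np.zeros((68, 2))
    t = np.linspace(0.0, 1.0, 17)
    ang = np.pi * t
    pts[0:17, 0] = 100.0 - 45.0 * np.cos(ang)
    pts[0:17, 1] = 75.0 + 85.0 * np.sin(ang)
    arch = np.array([0.0, 3.0, 5.0, 3.0, 0.0])
    pts[17:22, 0] = np.linspace(62.0, 92.0, 5)
    pts[17:22, 1] = 62.0 - arch
    pts[22:27, 0] = np.linspace(108.0, 138.0, 5)
    pts[22:27, 1] = 62.0 - arch
    pts[27:31] = [(100.0, 60.0), (100.0, 72.0), (100.0, 84.0), (100.0, 96.0)]
    pts[31:36, 0] = [88.0, 94.0, 100.0, 106.0, 112.0]
    pts[31:36, 1] = [102.0, 103.0, 104.0, 103.0, 102.0]
    pts[36:42] = [(68.0, 75.0), (74.0, 72.0), (82.0, 72.0),
                  (88.0, 75.0), (82.0, 78.0), (74.0, 78.0)]
    pts[42:48] = [(112.0, 75.0), (118.0, 72.0), (126.0, 72.0),
                  (132.0, 75.0), (126.0, 78.0), (118.0, 78.0)]
    pts[48:60] = [(80.0, 125.0), (87.0, 121.0), (94.0, 119.0), (100.0, 118.0),
                  (106.0, 119.0), (113.0, 121.0), (120.0, 125.0), (113.0, 130.0),
                  (106.0, 132.0), (100.0, 133.0), (94.0, 132.0), (87.0, 130.0)]
    pts[60:68] = [(85.0, 125.0), (93.0, 122.0), (100.0, 121.0), (107.0, 122.0),
                  (115.0, 125.0), (107.0, 128.0), (100.0, 129.0), (93.0, 128.0)]
    return pts


# landmark index groups used by the animator (0-based)
_LOWER_LIP = np.array([55, 56, 57, 58, 59, 65, 66, 67])
_UPPER_LIP = np.array([49, 50, 51, 52, 53, 61, 62, 63])
_LEFT_UPPER_LID, _LEFT_LOWER_LID = np.array([37, 38]), np.array([40, 41])
_RIGHT_UPPER_LID, _RIGHT_LOWER_LID = np.array([43, 44]), np.array([46, 47])
_RIGHT_CORNER_REGION = np.array([53, 54, 55])   # points 54, 55, 56
_BROWS = np.arange(17, 27)
BLINK_DURATION_S = 0.120
MOUTH_OPEN_HZ = 0.8
MOUTH_OPEN_AMP = 12.0                            # template units at mult = 1


def synth_landmark_series(face: GroupFaceParams, duration_s: float, fps: float,
                          head_motion: tuple[tuple[float, float], float] = ((0.0, 0.0), 0.0),
                          seed: int | np.random.SeedSequence = 0,
                          subject_id: str = "S", task_code: str = "TSK3",
                          ) -> LandmarkSeries:
    """Animate the neutral template into a landmark time series.

    The mouth opens sinusoidally (0.8 Hz, amplitude scaled by the group
    multiplier), the eyelids close in 120 ms triangular blink events with
    exponential inter-blink times, the brows carry frame noise, one mouth
    corner sags linearly at ``drift_slope`` and carries a static
    asymmetry offset.  The rigid head motion (translation px/s, uniform
    scale drift /s, about the face centroid) is applied to all points
    last, so normalized features are unaffected by it.
    """
    if duration_s < 2:
        raise ValueError("duration_s must be >= 2")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    base = neutral_template()
    frames = np.repeat(base[None, :, :], n, axis=0)

    opening = (face.mouth_amplitude_mult * MOUTH_OPEN_AMP
               * 0.5 * (1.0 - np.cos(2 * np.pi * MOUTH_OPEN_HZ * t)))
    frames[:, _LOWER_LIP, 1] += opening[:, None]
    frames[:, _UPPER_LIP, 1] -= 0.3 * opening[:, None]

    closure = np.zeros(n)
    if face.blink_rate_hz > 0:
        tt = rng.exponential(1.0 / face.blink_rate_hz)
        while tt < duration_s:
            phase = (t - tt) / BLINK_DURATION_S
            tri = np.clip(1.0 - np.abs(2.0 * phase - 1.0), 0.0, 1.0)
            tri[(phase < 0) | (phase > 1)] = 0.0
            closure = np.maximum(closure, tri)
            tt += BLINK_DURATION_S + rng.exponential(1.0 / face.blink_rate_hz)
    lid_gap = 6.0   # upper-to-lower lid distance of the neutral template
    for upper, lower in ((_LEFT_UPPER_LID, _LEFT_LOWER_LID),
                         (_RIGHT_UPPER_LID, _RIGHT_LOWER_LID)):
        frames[:, upper, 1] += (0.9 * lid_gap) * closure[:, None]
        frames[:, lower, 1] -= (0.1 * lid_gap) * closure[:, None]

    if face.eyebrow_noise_sd > 0:
        frames[:, _BROWS, 1] += rng.normal(0.0, face.eyebrow_noise_sd, (n, len(_BROWS)))
    frames[:, _RIGHT_CORNER_REGION, 1] += (100.0 * face.drift_slope * t)[:, None]
    frames[:, 48, 1] += 100.0 * face.asymmetry_offset
    if face.point_noise_sd > 0:
        frames += rng.normal(0.0, face.point_noise_sd, frames.shape)

    (vx, vy), scale_drift = head_motion
    centroid = base.mean(axis=0)
    scale = (1.0 + scale_drift * t)[:, None, None]
    frames = (frames - centroid) * scale + centroid
    frames[:, :, 0] += (vx * t)[:, None]
    frames[:, :, 1] += (vy * t)[:, None]
    return LandmarkSeries(subject_id, task_code, fps, frames)


# ---------------------------------------------------------------------------
# audio synthesis
# ---------------------------------------------------------------------------

_VOWEL_A_FORMANTS = ((600.0, 90.0), (1100.0, 130.0), (2500.0, 180.0))


def _resonate(x: np.ndarray, formants, fs: float) -> np.ndarray:
    for fc, bw in formants:
        r = math.exp(-math.pi * bw / fs)
        theta = 2 * math.pi * fc / fs
        x = sps.lfilter([1.0 - r], [1.0, -2 * r * math.cos(theta), r * r], x)
    return x


def _slow_wander(n: int, fs: float, rng: np.random.Generator,
                 cutoff_hz: float = 2.0) -> np.ndarray:
    """Unit-variance low-pass noise for slow F0 drift."""
    noise = rng.normal(size=n)
    b, a = sps.butter(2, cutoff_hz / (fs / 2))
    w = sps.lfilter(b, a, noise)
    sd = w.std()
    return w / sd if sd > 0 else w


def synth_vowel(f0: float, jitter_pct: float, shimmer_pct: float, hnr_db: float,
                formants=_VOWEL_A_FORMANTS, duration_s: float = 2.0,
                fs: float = 48000.0, seed: int | np.random.SeedSequence = 0,
                f0_sd_rel: float = 0.0) -> Waveform:
    """Source-filter synthesis of a sustained vowel.

    A glottal pulse train with per-period multiplicative period
    perturbation (sd ``jitter_pct`` %) and per-pulse amplitude
    perturbation (sd ``shimmer_pct`` %) excites a cascade of formant
    resonators; white noise is added at a level that makes the
    harmonic-to-noise power ratio exactly ``hnr_db``.  ``f0_sd_rel``
    superimposes a slow (< 2 Hz) relative F0 wander.  Peak-normalized.
    """
    if not (50.0 <= f0 <= 500.0):
        raise ValueError("f0 must lie in [50, 500] Hz")
    if duration_s < 0.5:
        raise ValueError("duration_s must be >= 0.5")
    if f0 >= fs / 4:
        raise SamplingError("f0 must be below fs/4")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    wander = _slow_wander(n, fs, rng) if f0_sd_rel > 0 else np.zeros(n)
    exc = np.zeros(n)
    pos = 0.0
    while pos < n:
        exc[int(pos)] = max(0.05, 1.0 + rng.normal(0.0, shimmer_pct / 100.0))
        f_inst = f0 * (1.0 + f0_sd_rel * wander[min(int(pos), n - 1)])
        period = (fs / f_inst) * max(0.2, 1.0 + rng.normal(0.0, jitter_pct / 100.0))
        pos += period
    harm = _resonate(exc, formants, fs)
    p_harm = float((harm**2).mean())
    p_noise = p_harm / (10.0 ** (hnr_db / 10.0))
    x = harm + rng.normal(0.0, math.sqrt(p_noise), n)
    x *= 0.9 / np.abs(x).max()
    return Waveform(x, fs)


def _tone_burst(fs: float, dur_s: float, f0: float = 140.0) -> np.ndarray:
    t = np.arange(int(round(dur_s * fs))) / fs
    x = sum(math.pow(0.6, k) * np.sin(2 * np.pi * (k + 1) * f0 * t) for k in range(3))
    return x * np.hanning(t.size)


def synth_ddk(rate_hz: float, reg_sd_s: float, n_syllables: int,
              fs: float = 48000.0, seed: int | np.random.SeedSequence = 0) -> Waveform:
    """Diadochokinesis proxy: a train of tone bursts.

    Inter-onset intervals are Gaussian with mean ``1/rate_hz`` and sd
    ``reg_sd_s`` (truncated positive); each syllable is a 60 ms
    harmonic burst, with near-silence elsewhere.
    """
    if rate_hz <= 0:
        raise ValueError("rate_hz must be > 0")
    if n_syllables < 3:
        raise ValueError("n_syllables must be >= 3")
    if reg_sd_s >= 1.0 / rate_hz:
        raise DegenerateSpacingError("reg_sd_s must be below the mean interval")
    rng = np.random.default_rng(seed)
    mean_ioi = 1.0 / rate_hz
    iois = np.maximum(0.25 * mean_ioi, rng.normal(mean_ioi, reg_sd_s, n_syllables - 1))
    onsets = np.concatenate(([0.3], 0.3 + np.cumsum(iois)))
    burst = _tone_burst(fs, 0.060)
    n = int(round((onsets[-1] + 0.4) * fs))
    x = rng.normal(0.0, 1e-4, n)
    for on in onsets:
        i = int(round(on * fs))
        x[i:i + burst.size] += burst[: max(0, n - i)]
    x *= 0.9 / np.abs(x).max()
    return Waveform(x, fs)


def synth_connected_speech(speech_segments: int, pause_segments: int,
                           total_s: float, fs: float = 48000.0,
                           seed: int | np.random.SeedSequence = 0,
                           f0: float = 120.0, f0_sd_rel: float = 0.03,
                           jitter_pct: float = 1.0, shimmer_pct: float = 4.0,
                           hnr_db: float = 18.0, syllable_hz: float = 4.0,
                           ) -> tuple[Waveform, pd.DataFrame]:
    """Alternating voiced stretches and silent pauses, with ground truth.

    Each voiced stretch is a synthesized vowel amplitude-modulated at
    ``syllable_hz`` (so syllable nuclei exist at a known rate); pauses
    are near-silence.  Returns the waveform and a segment table
    (``kind, start_s, end_s, n_nuclei``) usable as an oracle for pause
    and speech-rate measures.
    """
    if total_s <= 1:
        raise ValueError("total_s must be > 1")
    if speech_segments < 1 or pause_segments < 0:
        raise LayoutError("need >= 1 speech segment and >= 0 pauses")
    if pause_segments >= speech_segments:
        raise LayoutError("pauses must alternate between speech segments")
    edge_s, pause_s = 0.25, 0.40
    speech_total = total_s - 2 * edge_s - pause_segments * pause_s
    if speech_total <= 0.5 * speech_segments:
        raise LayoutError("pauses and edges leave too little speech time")
    seg_s = speech_total / speech_segments
    rng = np.random.default_rng(seed)
    n = int(round(total_s * fs))
    x = rng.normal(0.0, 1e-5, n)
    rows = []
    cursor = edge_s
    for k in range(speech_segments):
        seg = synth_vowel(f0, jitter_pct, shimmer_pct, hnr_db,
                          duration_s=max(0.5, seg_s), fs=fs,
                          seed=rng.integers(2**31), f0_sd_rel=f0_sd_rel)
        # syllabic gating: raised-cosine bursts, ~45% duty cycle, so the
        # energy envelope dips clearly between consecutive nuclei
        ts = np.arange(seg.samples.size) / fs
        phase = (ts * syllable_hz) % 1.0
        duty = 0.45
        mod = np.where(phase < duty,
                       0.5 * (1.0 - np.cos(2 * np.pi * phase / duty)), 0.0)
        y = seg.samples * (0.03 + 0.97 * mod)
        i = int(round(cursor * fs))
        m = min(y.size, n - i)
        x[i:i + m] += y[:m]
        n_nuclei = max(1, int(round(seg_s * syllable_hz)))
        rows.append({"kind": "speech", "start_s": cursor,
                     "end_s": cursor + seg_s, "n_nuclei": n_nuclei})
        cursor += seg_s
        if k < pause_segments:
            rows.append({"kind": "pause", "start_s": cursor,
                         "end_s": cursor + pause_s, "n_nuclei": 0})
            cursor += pause_s
    x *= 0.9 / np.abs(x).max()
    return Waveform(x, fs), pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class CohortBundle:
    """In-memory cohort: metadata + per-subject/task signals + ground truth."""

    metadata: pd.DataFrame
    landmarks: dict[tuple[str, str], LandmarkSeries]
    audio: dict[tuple[str, str], Waveform]
    ground_truth: dict


def _sample_metadata(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    lo, hi = cfg.confound.age_range
    for i in range(cfg.n_pd + cfg.n_hc):
        group = "PD" if i < cfg.n_pd else "HC"
        mu = 67.0 if group == "PD" else 64.0
        age = float(np.clip(rng.normal(mu, 8.0), lo, hi))
        gender = "F" if rng.random() < cfg.confound.gender_ratio else "M"
        rows.append({"subject": f"S{i + 1:03d}", "group": group,
                     "age": round(age, 1), "gender": gender})
    return pd.DataFrame(rows)


def _subject_audio(task: str, voice: GroupVoiceParams, f0: float,
                   cfg: SyntheticConfig, ss: np.random.SeedSequence) -> Waveform:
    n = int(task[3:])
    if n <= 17:
        return synth_vowel(f0, voice.jitter_pct, voice.shimmer_pct, voice.hnr_db,
                           duration_s=cfg.vowel_s, fs=cfg.audio_fs, seed=ss,
                           f0_sd_rel=voice.relf0sd)
    if n == 18:
        n_syl = max(3, int(round(voice.ddk_rate_hz * cfg.ddk_s)))
        return synth_ddk(voice.ddk_rate_hz, voice.ddk_reg_sd_s, n_syl,
                         fs=cfg.audio_fs, seed=ss)
    wave, _ = synth_connected_speech(
        4, 2, cfg.speech_s, fs=cfg.audio_fs, seed=ss, f0=f0,
        f0_sd_rel=voice.relf0sd, jitter_pct=voice.jitter_pct,
        shimmer_pct=voice.shimmer_pct, hnr_db=voice.hnr_db)
    return wave


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Generate the full cohort deterministically from ``config.seed``.

    Subject-level biological variability multiplies each voice parameter
    by an independent log-normal factor (sd 0.15 on the log scale), so
    groups overlap but remain separable under the reference profile.
    """
    root = np.random.SeedSequence(config.seed)
    meta_rng = np.random.default_rng(root.spawn(1)[0])
    metadata = _sample_metadata(config, meta_rng)
    subj_seeds = root.spawn(len(metadata))
    landmarks: dict[tuple[str, str], LandmarkSeries] = {}
    audio: dict[tuple[str, str], Waveform] = {}
    truth: dict = {"config": {"n_pd": config.n_pd, "n_hc": config.n_hc,
                              "seed": config.seed,
                              "task_codes": list(config.task_codes)},
                   "subjects": {}}
    for (_, row), ss in zip(metadata.iterrows(), subj_seeds):
        rng = np.random.default_rng(ss)
        group = row["group"]
        voice0 = config.effect.voice(group)
        face = config.effect.face(group)
        lv = rng.lognormal(0.0, 0.15, 6)
        voice = GroupVoiceParams(
            jitter_pct=voice0.jitter_pct * lv[0],
            shimmer_pct=voice0.shimmer_pct * lv[1],
            hnr_db=voice0.hnr_db * lv[2],
            relf0sd=voice0.relf0sd * lv[3],
            ddk_rate_hz=voice0.ddk_rate_hz * lv[4],
            ddk_reg_sd_s=min(voice0.ddk_reg_sd_s * lv[5],
                             0.8 / (voice0.ddk_rate_hz * lv[4])),
        )
        f0 = float(np.clip(rng.normal(200.0 if row["gender"] == "F" else 120.0, 12.0),
                           80.0, 320.0))
        head = ((float(rng.uniform(-2, 2)), float(rng.uniform(-2, 2))),
                float(rng.uniform(-0.005, 0.005)))
        truth["subjects"][row["subject"]] = {
            "group": group, "voice": asdict(voice), "face": asdict(face), "f0": f0}
        task_seeds = ss.spawn(2 * len(config.task_codes))
        for j, task in enumerate(config.task_codes):
            audio[(row["subject"], task)] = _subject_audio(
                task, voice, f0, config, task_seeds[2 * j])
            landmarks[(row["subject"], task)] = synth_landmark_series(
                face, config.video_s, config.fps, head_motion=head,
                seed=task_seeds[2 * j + 1], subject_id=row["subject"],
                task_code=task)
    return CohortBundle(metadata, landmarks, audio, truth)


def write_cohort(bundle: CohortBundle, out_dir) -> None:
    """Write metadata CSV, one landmark CSV, WAV files and ground truth."""
    out = Path(out_dir)
    (out / "audio").mkdir(parents=True, exist_ok=True)
    bundle.metadata.to_csv(out / "metadata.csv", index=False)
    rows = []
    for (subj, task), series in sorted(bundle.landmarks.items()):
        for fi, frame in enumerate(series.points):
            row = {"subject": subj, "task": task, "frame": fi, "fps": series.fps}
            for k in range(68):
                row[f"x{k + 1}"] = round(float(frame[k, 0]), 3)
                row[f"y{k + 1}"] = round(float(frame[k, 1]), 3)
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "landmarks.csv", index=False)
    for (subj, task), wave in sorted(bundle.audio.items()):
        write_wav(out / "audio" / f"{subj}__{task}.wav", wave)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=1)


# ---------------------------------------------------------------------------
# post-extraction paths: confound injection, direct feature-table synthesis
# ---------------------------------------------------------------------------

def inject_confounds(features: pd.DataFrame, metadata: pd.DataFrame,
                     confound: ConfoundProfile) -> pd.DataFrame:
    """Add the profile's linear age/gender shifts to every feature column.

    Shifts are ``age_coeff * (age - 65) * sd_col`` plus
    ``gender_coeff * is_male * sd_col``; being exactly linear in the
    confounds, they are removed exactly by OLS residualization.
    """
    meta = metadata.set_index("subject").loc[features.index]
    age_c = (meta["age"].to_numpy(dtype=float) - 65.0) * confound.age_coeff
    male = (meta["gender"].to_numpy() == "M").astype(float) * confound.gender_coeff
    shift = age_c + male
    out = features.copy()
    sds = out.std(ddof=0).replace(0.0, 1.0)
    for col in out.columns:
        out[col] = out[col] + shift * float(sds[col])
    return out


def synthesize_feature_table(n_pd: int = 73, n_hc: int = 46, n_features: int = 100,
                             effect_sd: float = 1.0, informative_frac: float = 0.3,
                             confound: ConfoundProfile | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Directly simulate an extracted feature table (post-extraction path).

    A fraction of the features carries a group mean shift of
    ``effect_sd`` standard deviations; the rest are noise.  Confound
    shifts are injected linearly when a profile with nonzero
    coefficients is given.  ``effect_sd=0`` yields a null cohort with no
    group signal, used for permutation and false-positive checks.
    Returns a wide table indexed by subject with ``label`` (PD=1),
    ``age``, ``gender`` (M=1) and the feature columns.
    """
    rng = np.random.default_rng(seed)
    n = n_pd + n_hc
    label = np.concatenate([np.ones(n_pd), np.zeros(n_hc)])
    age = np.clip(rng.normal(np.where(label == 1, 67.0, 64.0), 8.0), 45, 85)
    gender = (rng.random(n) < 0.55).astype(float)
    n_inf = int(round(informative_frac * n_features))
    x = rng.normal(size=(n, n_features))
    signs = np.where(rng.random(n_inf) < 0.5, -1.0, 1.0)
    x[:, :n_inf] += np.outer(label, signs * effect_sd)
    cols = {f"feat{j:03d}": x[:, j] for j in range(n_features)}
    table = pd.DataFrame({"label": label.astype(int), "age": age, "gender": gender,
                          **cols},
                         index=pd.Index([f"S{i + 1:03d}" for i in range(n)],
                                        name="subject"))
    if confound is not None and (confound.age_coeff or confound.gender_coeff):
        shift = (age - 65.0) * confound.age_coeff + gender * confound.gender_coeff
        feat_cols = [c for c in table.columns if c.startswith("feat")]
        table[feat_cols] = table[feat_cols].add(shift, axis=0)
    return table
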