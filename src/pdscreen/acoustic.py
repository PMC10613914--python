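"""Acoustic measures of hypokinetic dysarthria from mono waveforms.

The 13 measures cover the three dimensions along which Parkinsonian
speech degrades: phonation (MPT, relF0SD, jitter PPQ5, shimmer APQ5,
mean HNR, DUV), articulation (relF1SD, relF2SD, DDK rate, DDK
regularity) and prosody (relSEOSD, SPIR, NSR).  Which measures are
defined for which vocal task (sustained vowels TSK3-17, expirations
TSK1-2, the pa-ta-ka diadochokinetic task TSK18, and the read/repeated
speech tasks TSK19-43) follows the task catalog; inapplicable measures
are reported as NaN.

All analyses run on 40 ms frames with a 10 ms hop.  Voicing and pitch
come from the normalized autocorrelation peak within a 60-500 Hz search
range; a frame is voiced when that peak reaches 0.45 and the frame is
above the silence floor.  Energy thresholds are relative, so every
measure here is invariant to a global gain change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile
from scipy.linalg import solve_toeplitz

__all__ = [
    "Waveform",
    "F0Track",
    "PeriodSequence",
    "AcousticFeatureSet",
    "ACOUSTIC_FEATURE_NAMES",
    "f0_contour",
    "duv",
    "rel_sd",
    "jitter_ppq5",
    "shimmer_apq5",
    "hnr_mean",
    "formant_rel_sd",
    "energy_rel_sd",
    "syllable_nuclei",
    "ddk_measures",
    "pause_metrics",
    "period_sequence",
    "extract_task_features",
    "read_wav",
    "write_wav",
    "task_feature_map",
]

FRAME_S = 0.040
HOP_S = 0.010
F0_MIN = 60.0
F0_MAX = 500.0
VOICING_THRESHOLD = 0.45
PAUSE_DROP_DB = 25.0
MIN_PAUSE_S = 0.060
NUCLEUS_RISE_DB = 6.0
NUCLEUS_DIP_DB = 3.0
MIN_NUCLEUS_SEP_S = 0.060

ACOUSTIC_FEATURE_NAMES = (
    "MPT", "relF0SD", "jitter", "shimmer", "relF1SD", "relF2SD",
    "meanHNR", "DUV", "DDKrate", "DDKreg", "relSEOSD", "SPIR", "NSR",
)

_PHONATION = ("relF0SD", "jitter", "shimmer", "relF1SD", "relF2SD", "meanHNR", "DUV")
_SPIR_TASKS = set(range(20, 27)) | set(range(37, 43))
_NSR_TASKS = set(range(20, 42))


class InsufficientCyclesError(ValueError):
    """Raised when too few glottal cycles are available for a quotient."""


class TaskMappingError(KeyError):
    """Raised for a task code outside TSK1..TSK43."""


@dataclass
class Waveform:
    """Mono audio, samples normalized to [-1, 1]."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs < 8000:
            raise ValueError("sampling rate must be at least 8 kHz")
        if self.samples.size < 0.2 * self.fs:
            raise ValueError("need at least 0.2 s of audio")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class F0Track:
    times: np.ndarray          # frame centres, s
    f0: np.ndarray             # Hz, NaN where unvoiced
    voiced: np.ndarray         # bool per frame
    corr_peak: np.ndarray      # normalized autocorrelation peak per frame
    hop_s: float = HOP_S


@dataclass
class PeriodSequence:
    """Consecutive glottal cycle lengths and their peak amplitudes."""

    periods: np.ndarray        # s
    amplitudes: np.ndarray     # linear


def read_wav(path) -> Waveform:
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    else:
        x = data.astype(float)
    return Waveform(x, float(fs))


def write_wav(path, wave: Waveform) -> None:
    x = np.clip(wave.samples, -1.0, 1.0)
    wavfile.write(path, int(wave.fs), np.round(x * 32767.0).astype(np.int16))


def _frames(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """(n_frames, frame_len) view and frame-centre times."""
    flen = int(round(FRAME_S * fs))
    hop = int(round(HOP_S * fs))
    if x.size < flen:
        x = np.pad(x, (0, flen - x.size))
    n = 1 + (x.size - flen) // hop
    idx = np.arange(flen)[None, :] + hop * np.arange(n)[:, None]
    return x[idx], (np.arange(n) * hop + flen / 2) / fs


def _frame_energy_db(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    fr, t = _frames(x, fs)
    e = (fr**2).mean(axis=1)
    return 10.0 * np.log10(e + 1e-12), t


def f0_contour(wave: Waveform, fmin: float = F0_MIN, fmax: float = F0_MAX,
               voicing_threshold: float = VOICING_THRESHOLD) -> F0Track:
    """Autocorrelation pitch track on 40 ms / 10 ms frames.

    The normalized autocorrelation of each mean-removed frame is
    searched in the lag band [1/fmax, 1/fmin]; the peak location gives
    the period (with parabolic refinement) and the peak height both the
    voicing decision (>= 0.45, above the silence floor) and the
    harmonicity estimate used by :func:`hnr_mean`.
    """
    if not (fmin < fmax < wave.fs / 2):
        raise ValueError("need fmin < fmax < fs/2")
    fr, t = _frames(wave.samples, wave.fs)
    fr = fr - fr.mean(axis=1, keepdims=True)
    flen = fr.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * flen)))
    spec = np.fft.rfft(fr, nfft, axis=1)
    ac = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, :flen]
    r0 = ac[:, 0].copy()
    r0[r0 <= 0] = np.inf
    rho = ac / r0[:, None]
    lag_lo = max(2, int(np.floor(wave.fs / fmax)))
    lag_hi = min(flen - 2, int(np.ceil(wave.fs / fmin)))
    # peak picked on the biased estimate (its lag taper suppresses the
    # octave-down ambiguity); peak height taken bias-corrected so a
    # periodic frame scores ~1 regardless of its period
    band = rho[:, lag_lo:lag_hi + 1]
    k = band.argmax(axis=1) + lag_lo
    peak = rho[np.arange(len(rho)), k] * flen / np.maximum(flen - k, 1)
    peak = np.clip(peak, -1.0, 1.0)
    # parabolic interpolation around the peak lag
    km1 = rho[np.arange(len(rho)), k - 1]
    kp1 = rho[np.arange(len(rho)), k + 1]
    denom = km1 - 2 * peak + kp1
    with np.errstate(invalid="ignore", divide="ignore"):
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (km1 - kp1) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    lag = k + shift
    f0 = wave.fs / lag
    rms = np.sqrt((fr**2).mean(axis=1))
    floor = max(1e-6, 0.02 * float(np.percentile(rms, 95)))
    voiced = (peak >= voicing_threshold) & (rms > floor) & (f0 >= fmin) & (f0 <= fmax)
    f0 = np.where(voiced, f0, np.nan)
    return F0Track(times=t, f0=f0, voiced=voiced, corr_peak=peak)


def duv(track: F0Track) -> float:
    """Fraction of pitch frames classified unvoiced, in [0, 1]."""
    if track.voiced.size == 0:
        raise ValueError("empty track")
    return float((~track.voiced).sum() / track.voiced.size)


def rel_sd(values: Sequence[float]) -> float:
    """Population standard deviation divided by the mean (scale-free)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 values")
    m = x.mean()
    if abs(m) < 1e-12:
        return math.nan
    return float(x.std() / m)


def _ppq(values: np.ndarray, width: int = 5) -> float:
    half = width // 2
    if values.size < width:
        raise InsufficientCyclesError(f"need at least {width} cycles")
    sw = np.lib.stride_tricks.sliding_window_view(values, width)
    dev = np.abs(values[half:-half] - sw.mean(axis=1))
    return float(100.0 * dev.mean() / values.mean())


def jitter_ppq5(periods: PeriodSequence) -> float:
    """Five-point period perturbation quotient, percent.

    100 * mean_i |T_i - (1/5) sum_{k=i-2..i+2} T_k| / mean(T).
    """
    return _ppq(np.asarray(periods.periods, dtype=float))


def shimmer_apq5(periods: PeriodSequence) -> float:
    """Five-point amplitude perturbation quotient, percent."""
    return _ppq(np.asarray(periods.amplitudes, dtype=float))


def period_sequence(wave: Waveform, track: F0Track) -> PeriodSequence:
    """Segment voiced speech into glottal cycles by guided peak-picking.

    The median voiced F0 predicts the cycle length; waveform peaks at
    least 0.7 predicted periods apart mark cycle boundaries.  Intervals
    far from the median (outside 0.5-2x) are treated as tracking slips
    and discarded together with their amplitudes.
    """
    f0s = track.f0[track.voiced]
    if f0s.size == 0:
        raise InsufficientCyclesError("no voiced frames")
    t0 = 1.0 / float(np.median(f0s))
    x = wave.samples
    dist = max(1, int(0.7 * t0 * wave.fs))
    height = 0.2 * float(np.percentile(np.abs(x), 99))
    peaks, props = sps.find_peaks(x, distance=dist, height=height)
    if peaks.size < 6:
        raise InsufficientCyclesError("too few cycle peaks")
    periods = np.diff(peaks) / wave.fs
    amps = props["peak_heights"][1:]
    ok = (periods > 0.5 * t0) & (periods < 2.0 * t0)
    return PeriodSequence(periods=periods[ok], amplitudes=amps[ok])


def hnr_mean(wave: Waveform, track: F0Track) -> float:
    """Mean harmonics-to-noise ratio over voiced frames, dB.

    Per frame HNR = 10 log10(r' / (1 - r')) where r' is the normalized
    autocorrelation peak at the pitch lag; r' is clipped so a perfectly
    periodic frame saturates at 60 dB rather than diverging.
    """
    r = track.corr_peak[track.voiced]
    if r.size == 0:
        return math.nan
    r = np.clip(r, 1e-6, 1.0 - 1e-6)
    return float((10.0 * np.log10(r / (1.0 - r))).mean())


def _lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    r = np.correlate(frame, frame, "full")[frame.size - 1: frame.size + order]
    if r[0] <= 0:
        return None
    try:
        a = solve_toeplitz((r[:-1], r[:-1]), -r[1:])
    except np.linalg.LinAlgError:
        return None
    return np.concatenate(([1.0], a))


def formant_rel_sd(wave: Waveform, track: F0Track,
                   order: int = 12, fs_lpc: float = 10000.0,
                   f1_band: tuple[float, float] = (200.0, 1200.0),
                   f2_band: tuple[float, float] = (600.0, 3200.0),
                   ) -> tuple[float, float]:
    """Relative std of the F1 and F2 contours over voiced frames.

    The signal is resampled to 10 kHz, pre-emphasized, and an order-12
    autocorrelation LPC fit per voiced frame yields the vocal-tract
    resonances: F1 is the lowest pole frequency in 200-1200 Hz, F2 the
    next above it in 600-3200 Hz (pole bandwidth < 700 Hz).  Frames
    missing either formant are skipped; (NaN, NaN) if all are.
    """
    if int(track.voiced.sum()) < 5:
        return math.nan, math.nan
    up, down = int(fs_lpc), int(wave.fs)
    g = math.gcd(up, down)
    x = sps.resample_poly(wave.samples, up // g, down // g)
    x = np.append(x[0], x[1:] - 0.97 * x[:-1])
    fr, t = _frames(x, fs_lpc)
    fr = fr * np.hamming(fr.shape[1])
    voiced_times = track.times[track.voiced]
    f1s, f2s = [], []
    for i, tc in enumerate(t):
        if np.min(np.abs(voiced_times - tc)) > HOP_S:
            continue
        a = _lpc(fr[i], order)
        if a is None:
            continue
        roots = np.roots(a)
        roots = roots[roots.imag > 0]
        freqs = np.angle(roots) * fs_lpc / (2 * np.pi)
        bws = -np.log(np.abs(roots)) * fs_lpc / np.pi
        cand = np.sort(freqs[(bws < 700.0) & (freqs > 50.0)])
        f1 = next((f for f in cand if f1_band[0] <= f <= f1_band[1]), None)
        if f1 is None:
            continue
        f2 = next((f for f in cand if f > f1 + 1.0 and f2_band[0] <= f <= f2_band[1]), None)
        if f2 is None:
            continue
        f1s.append(f1)
        f2s.append(f2)
    if len(f1s) < 5:
        return math.nan, math.nan
    return rel_sd(f1s), rel_sd(f2s)


def energy_rel_sd(wave: Waveform) -> float:
    """Relative std of the short-time energy over speech-active frames."""
    if wave.duration_s < 0.5:
        raise ValueError("need at least 0.5 s")
    fr, _ = _frames(wave.samples, wave.fs)
    e = (fr**2).mean(axis=1)
    active = e > 0.01 * float(np.percentile(e, 95))
    if active.sum() < 2 or float(np.percentile(e, 95)) < 1e-10:
        return math.nan
    return rel_sd(e[active])


def _envelope_db(wave: Waveform) -> tuple[np.ndarray, np.ndarray]:
    env, t = _frame_energy_db(wave.samples, wave.fs)
    if env.size >= 3:
        env = np.convolve(env, np.ones(3) / 3, mode="same")
    return env, t


def syllable_nuclei(wave: Waveform) -> np.ndarray:
    """Times (s) of syllable nuclei: energy-envelope peaks.

    A nucleus is a smoothed-envelope peak at least 6 dB above the median
    envelope level, separated from its neighbours by >= 60 ms with an
    intervening dip of >= 3 dB (enforced through peak prominence).
    """
    if wave.duration_s < 0.5:
        raise ValueError("need at least 0.5 s")
    env, t = _envelope_db(wave)
    height = float(np.median(env)) + NUCLEUS_RISE_DB
    dist = max(1, int(round(MIN_NUCLEUS_SEP_S / HOP_S)))
    peaks, _ = sps.find_peaks(env, height=height, distance=dist,
                              prominence=NUCLEUS_DIP_DB)
    return t[peaks]


def ddk_measures(onsets: Sequence[float]) -> tuple[float, float]:
    """Diadochokinetic rate (syll/s) and regularity (s) from nuclei times.

    Rate is the onset count over the first-to-last span plus one mean
    inter-onset interval (so k perfectly spaced onsets at interval d give
    exactly 1/d); regularity is the population std of the intervals.
    """
    on = np.asarray(onsets, dtype=float)
    if on.size < 2:
        return math.nan, math.nan
    iois = np.diff(on)
    span = on[-1] - on[0] + iois.mean()
    rate = on.size / span
    reg = float(iois.std()) if on.size >= 3 else math.nan
    return float(rate), reg


def pause_metrics(wave: Waveform) -> dict[str, float]:
    """Pause and speech-rate measures of a connected-speech recording.

    Frames whose energy falls 25 dB below the median speech level count
    as silent; internal silent runs of >= 60 ms are pauses.  Returns
    SPIR (pauses per recording minute), net speech time NST (duration
    minus pauses and edge silences), total speech time from first to
    last active frame, and NSR (syllable nuclei per second of NST — a
    syllable-nucleus proxy for a phone count, flagged as such).
    """
    if wave.duration_s < 2.0:
        raise ValueError("need at least 2 s")
    env, t = _frame_energy_db(wave.samples, wave.fs)
    loud = env > env.max() - 30.0
    if not loud.any() or env.max() < -70.0:
        return {"SPIR": math.nan, "NST": math.nan,
                "total_speech_time": math.nan, "NSR": math.nan}
    thresh = float(np.median(env[loud])) - PAUSE_DROP_DB
    active = env >= thresh
    first, last = np.flatnonzero(active)[[0, -1]]
    inner = active[first:last + 1]
    # runs of consecutive silent frames between first and last activity
    pad = np.concatenate(([True], inner, [True]))
    starts = np.flatnonzero(pad[:-1] & ~pad[1:])
    ends = np.flatnonzero(~pad[:-1] & pad[1:])
    run_s = (ends - starts) * HOP_S
    pauses = run_s[run_s >= MIN_PAUSE_S]
    total_min = wave.duration_s / 60.0
    spir = len(pauses) / total_min
    edge_s = (first + (env.size - 1 - last)) * HOP_S
    nst = wave.duration_s - float(pauses.sum()) - edge_s
    total_speech = (last - first + 1) * HOP_S
    nuclei = syllable_nuclei(wave)
    nsr = len(nuclei) / nst if nst > 0 else math.nan
    return {"SPIR": float(spir), "NST": float(nst),
            "total_speech_time": float(total_speech), "NSR": float(nsr)}


@dataclass
class AcousticFeatureSet:
    """The 13 task-dependent acoustic measures; NaN = not applicable."""

    MPT: float = math.nan
    relF0SD: float = math.nan
    jitter: float = math.nan
    shimmer: float = math.nan
    relF1SD: float = math.nan
    relF2SD: float = math.nan
    meanHNR: float = math.nan
    DUV: float = math.nan
    DDKrate: float = math.nan
    DDKreg: float = math.nan
    relSEOSD: float = math.nan
    SPIR: float = math.nan
    NSR: float = math.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _task_number(task_code: str) -> int:
    if not (isinstance(task_code, str) and task_code.startswith("TSK")):
        raise TaskMappingError(f"unknown task code {task_code!r}")
    try:
        n = int(task_code[3:])
    except ValueError:
        raise TaskMappingError(f"unknown task code {task_code!r}") from None
    if not 1 <= n <= 43:
        raise TaskMappingError(f"unknown task code {task_code!r}")
    return n


def task_feature_map(task_code: str) -> tuple[str, ...]:
    """Names of the measures defined for a task (the applicability map)."""
    n = _task_number(task_code)
    if n <= 2:
        return ("MPT",) + _PHONATION
    if n <= 17:
        return _PHONATION
    if n == 18:
        return ("DDKrate", "DDKreg")
    feats = ["relF0SD", "relF1SD", "relF2SD", "relSEOSD"]
    if n in _SPIR_TASKS:
        feats.append("SPIR")
    if n in _NSR_TASKS:
        feats.append("NSR")
    return tuple(feats)


def _longest_voiced_stretch_s(track: F0Track) -> float:
    v = track.voiced
    if not v.any():
        return math.nan
    pad = np.concatenate(([False], v, [False]))
    starts = np.flatnonzero(pad[1:] & ~pad[:-1])
    ends = np.flatnonzero(~pad[1:] & pad[:-1])
    return float((ends - starts).max() * track.hop_s)


def extract_task_features(wave: Waveform, task_code: str) -> AcousticFeatureSet:
    """Compute exactly the measures applicable to one vocal task.

    Phonation tasks get the sustained-vowel set (plus MPT on the
    expiration tasks TSK1-2), the diadochokinetic task its rate and
    regularity, and the connected-speech tasks the articulation/prosody
    set with SPIR/NSR per the applicability map.  Measures outside the
    task family stay NaN.
    """
    wanted = set(task_feature_map(task_code))
    out = AcousticFeatureSet()
    track = f0_contour(wave)
    if "MPT" in wanted:
        out.MPT = _longest_voiced_stretch_s(track)
    if "DUV" in wanted:
        out.DUV = duv(track)
    if "relF0SD" in wanted:
        f0s = track.f0[track.voiced]
        out.relF0SD = rel_sd(f0s) if f0s.size >= 2 else math.nan
    if "jitter" in wanted or "shimmer" in wanted:
        try:
            ps = period_sequence(wave, track)
            out.jitter = jitter_ppq5(ps)
            out.shimmer = shimmer_apq5(ps)
        except InsufficientCyclesError:
            pass
    if "meanHNR" in wanted:
        out.meanHNR = hnr_mean(wave, track)
    if "relF1SD" in wanted:
        out.relF1SD, out.relF2SD = formant_rel_sd(wave, track)
    if "relSEOSD" in wanted:
        out.relSEOSD = energy_rel_sd(wave)
    if "DDKrate" in wanted:
        rate, reg = ddk_measures(syllable_nuclei(wave))
        out.DDKrate, out.DDKreg = rate, reg
    if "SPIR" in wanted or "NSR" in wanted:
        pm = pause_metrics(wave)
        if "SPIR" in wanted:
            out.SPIR = pm["SPIR"]
        if "NSR" in wanted:
            out.NSR = pm["NSR"]
    return out
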