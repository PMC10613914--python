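"""Geometric facial-feature extraction from 68-point landmark time series.

Hypomimia — the reduced facial expressiveness of Parkinson's disease — is
quantified here from the trajectories of the 68 iBUG facial landmarks
(jaw 1-17, brows 18-27, nose 28-36, eyes 37-48, mouth 49-68; 1-based).
A fixed catalog of 55 per-frame geometric measures (point distances,
vertical offsets, brow angles, eye/mouth polygon areas and ratios) is
evaluated on every frame, normalized for head position and size, and each
resulting time series is collapsed to 10 scalar statistics: mean, std,
rsd, min, max, range, var, OLS slope versus time, Shannon entropy and
approximate entropy.  55 x 10 = 550 scalar features per recording.

Head-motion compensation: distances and vertical offsets are divided by
the per-frame face length (landmark 28, top of the nose bridge, to
landmark 9, chin tip); polygon areas by face length squared; angles and
ratios are dimensionless already.  Under any per-frame translation plus
uniform scaling every normalized measure is therefore invariant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSeries",
    "FeatureCatalogEntry",
    "ScalarSummary",
    "STAT_NAMES",
    "default_catalog",
    "face_length",
    "eval_catalog_feature",
    "extract_series",
    "summarize",
    "summarize_all",
    "approx_entropy",
    "shannon_entropy",
    "read_landmark_csv",
]

STAT_NAMES = ("mean", "std", "rsd", "min", "max", "range", "var", "slope", "se", "ae")

#: gaps of undetected frames up to this many seconds are linearly interpolated
MAX_INTERP_GAP_S = 0.5

ENTROPY_BINS = 16
APEN_M = 2
APEN_R_FACTOR = 0.2
MIN_LEN_ENTROPY = 8


class DegenerateFrameError(ValueError):
    """Raised when a frame's geometry makes normalization impossible."""


class InsufficientDataError(ValueError):
    """Raised when a series has too few usable frames/values."""


@dataclass
class LandmarkSeries:
    """A per-subject, per-task sequence of 68-point landmark frames.

    ``points`` has shape (n_frames, 68, 2) in image coordinates (origin
    top-left, y down).  ``gap_mask`` flags frames where the detector
    failed; those coordinates are ignored.
    """

    subject_id: str
    task_code: str
    fps: float
    points: np.ndarray
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (68, 2):
            raise ValueError("points must have shape (n_frames, 68, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(len(self.points), dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if int((~self.gap_mask).sum()) < 2:
            raise InsufficientDataError("need at least 2 detected frames")


@dataclass(frozen=True)
class FeatureCatalogEntry:
    """One named geometric measure evaluated per frame.

    ``point_spec`` holds 1-based landmark indices for geometric kinds, or
    the two component feature names for ``ratio`` entries.
    """

    name: str
    kind: Literal["distance", "vertical", "angle", "area", "ratio"]
    point_spec: tuple
    normalization: Literal["face_length", "face_length_squared", "none"] = "none"


def _d(name: str, i: int, j: int) -> FeatureCatalogEntry:
    return FeatureCatalogEntry(name, "distance", (i, j), "face_length")


_DISTANCES = [
    ("D1", 37, 49), ("D2", 46, 55), ("D3", 22, 23), ("D4", 52, 58),
    ("D5", 20, 38), ("D6", 25, 45), ("D7", 39, 41), ("D8", 45, 47),
    ("D9", 31, 9), ("D10", 1, 17), ("D11", 18, 22), ("D12", 23, 27),
    ("D13", 34, 52),
]

_EYES = [
    ("EYE1", 37, 38), ("EYE2", 37, 39), ("EYE3", 46, 45), ("EYE4", 46, 44),
    ("EYE5", 40, 39), ("EYE6", 40, 38), ("EYE7", 43, 44), ("EYE8", 43, 45),
    ("EYE9", 37, 42), ("EYE10", 37, 41), ("EYE11", 43, 48), ("EYE12", 43, 47),
    ("EYE13", 40, 41), ("EYE14", 40, 42), ("EYE15", 46, 48), ("EYE16", 46, 47),
    ("EYE17", 38, 42), ("EYE18", 45, 47), ("EYE19", 39, 41), ("EYE20", 44, 48),
    ("EYE21", 37, 40), ("EYE22", 43, 46),
]

_MOUTH = [
    ("M1", 49, 52), ("M2", 49, 58), ("M3", 55, 52), ("M4", 55, 58),
    ("M5", 49, 55), ("M6", 52, 58), ("M7", 60, 54), ("M8", 50, 56),
]


def default_catalog() -> list[FeatureCatalogEntry]:
    """The full 55-entry catalog of per-frame facial measures.

    EYEBROW2 and EYEBROW3 share one definition (the published catalog
    lists them identically); both names are kept so downstream feature
    naming stays stable, and a warning is logged once per call.
    """
    cat: list[FeatureCatalogEntry] = [_d(n, i, j) for n, i, j in _DISTANCES]
    cat += [
        FeatureCatalogEntry("EYEBROW1", "angle", ((22, 19), (40, 43))),
        FeatureCatalogEntry("EYEBROW2", "angle", ((22, 19), (23, 26))),
        FeatureCatalogEntry("EYEBROW3", "angle", ((22, 19), (23, 26))),
        FeatureCatalogEntry("EYEBROW4", "vertical", (19, 37), "face_length"),
        FeatureCatalogEntry("EYEBROW5", "vertical", (26, 46), "face_length"),
    ]
    cat += [_d(n, i, j) for n, i, j in _EYES]
    cat += [_d(n, i, j) for n, i, j in _MOUTH]
    cat += [
        FeatureCatalogEntry("RATIO_MOUTH", "ratio", ("M5", "M6")),
        FeatureCatalogEntry("MOUTH_AREA", "area", tuple(range(61, 69)), "face_length_squared"),
        FeatureCatalogEntry("LEYE_AREA", "area", tuple(range(37, 43)), "face_length_squared"),
        FeatureCatalogEntry("REYE_AREA", "area", tuple(range(43, 49)), "face_length_squared"),
        FeatureCatalogEntry("RATIO_FACE", "ratio", ("D1", "D2")),
        FeatureCatalogEntry("RATIO_MOUTH_SKEW_UP", "ratio", ("M3", "M1")),
        FeatureCatalogEntry("RATIO_MOUTH_SKEW_DOWN", "ratio", ("M4", "M2")),
    ]
    logger.warning("catalog: EYEBROW3 aliases EYEBROW2 (identical published definition)")
    return cat


def face_length(frame: np.ndarray) -> float:
    """Nose-bridge-to-chin distance (landmarks 28 and 9) of one frame.

    ``frame`` is a (68, 2) array; landmark indices are 1-based.
    """
    frame = np.asarray(frame, dtype=float)
    d = float(np.hypot(*(frame[27] - frame[8])))
    if d <= 0.0:
        raise DegenerateFrameError("landmarks 28 and 9 coincide; face length undefined")
    return d


def _face_lengths(points: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(points[:, 27, :] - points[:, 8, :], axis=1)
    if np.any(d <= 0.0):
        raise DegenerateFrameError("landmarks 28 and 9 coincide in some frame")
    return d


def _shoelace(poly: np.ndarray) -> np.ndarray:
    # poly: (n_frames, n_vertices, 2) closed implicitly
    x, y = poly[..., 0], poly[..., 1]
    xr, yr = np.roll(x, -1, axis=-1), np.roll(y, -1, axis=-1)
    return 0.5 * np.abs(np.sum(x * yr - xr * y, axis=-1))


def _eval_vectorized(
    points: np.ndarray,
    entry: FeatureCatalogEntry,
    fl: np.ndarray,
    computed: dict[str, np.ndarray],
) -> np.ndarray:
    if entry.kind == "distance":
        i, j = entry.point_spec
        v = np.linalg.norm(points[:, i - 1, :] - points[:, j - 1, :], axis=1)
        return v / fl
    if entry.kind == "vertical":
        i, j = entry.point_spec
        return np.abs(points[:, i - 1, 1] - points[:, j - 1, 1]) / fl
    if entry.kind == "angle":
        (a, b), (c, d) = entry.point_spec
        u = points[:, b - 1, :] - points[:, a - 1, :]
        w = points[:, d - 1, :] - points[:, c - 1, :]
        nu = np.linalg.norm(u, axis=1)
        nw = np.linalg.norm(w, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,ij->i", u, w) / (nu * nw)
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        # unsigned angle, half-open [0, 180)
        return np.where(ang >= 180.0, 0.0, ang)
    if entry.kind == "area":
        idx = np.asarray(entry.point_spec, dtype=int) - 1
        return _shoelace(points[:, idx, :]) / fl**2
    if entry.kind == "ratio":
        num_name, den_name = entry.point_spec
        num, den = computed[num_name], computed[den_name]
        with np.errstate(invalid="ignore", divide="ignore"):
            out = num / den
        out[np.abs(den) < 1e-300] = np.nan
        return out
    raise ValueError(f"unknown catalog kind {entry.kind!r}")


def eval_catalog_feature(frame: np.ndarray, entry: FeatureCatalogEntry,
                         catalog: Sequence[FeatureCatalogEntry] | None = None) -> float:
    """Evaluate one catalog entry on a single (68, 2) frame.

    ``ratio`` entries need the component definitions; pass ``catalog`` or
    the default one is used.  Returns NaN for a zero ratio denominator.
    """
    frame = np.asarray(frame, dtype=float)[None, :, :]
    fl = _face_lengths(frame)
    computed: dict[str, np.ndarray] = {}
    if entry.kind == "ratio":
        lookup = {e.name: e for e in (catalog or default_catalog())}
        for comp in entry.point_spec:
            computed[comp] = _eval_vectorized(frame, lookup[comp], fl, computed)
    return float(_eval_vectorized(frame, entry, fl, computed)[0])


def _interpolate_gaps(points: np.ndarray, gap_mask: np.ndarray, fps: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Fill short detector dropouts; return (points, keep_mask).

    Gaps no longer than MAX_INTERP_GAP_S are linearly interpolated on raw
    coordinates; longer gaps (and missing edges) are dropped from every
    feature series consistently.
    """
    n = len(points)
    keep = np.ones(n, dtype=bool)
    if not gap_mask.any():
        return points, keep
    max_gap = int(round(MAX_INTERP_GAP_S * fps))
    pts = points.copy()
    idx = np.flatnonzero(gap_mask)
    # group consecutive missing frames
    splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    for run in splits:
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= n or len(run) > max_gap:
            keep[run] = False
            continue
        t = (run - lo) / (hi - lo)
        pts[run] = pts[lo][None] + t[:, None, None] * (pts[hi] - pts[lo])[None]
    return pts, keep


def extract_series(series: LandmarkSeries,
                   catalog: Sequence[FeatureCatalogEntry] | None = None
                   ) -> pd.DataFrame:
    """Evaluate the full catalog on every usable frame.

    Returns a DataFrame with one column per catalog entry and the kept
    frame indices as the index; short detector gaps are interpolated
    first (see :func:`_interpolate_gaps`).
    """
    catalog = list(catalog) if catalog is not None else default_catalog()
    pts, keep = _interpolate_gaps(series.points, series.gap_mask, series.fps)
    pts = pts[keep]
    if len(pts) < 2:
        raise InsufficientDataError("fewer than 2 usable frames after gap handling")
    fl = _face_lengths(pts)
    computed: dict[str, np.ndarray] = {}
    for entry in catalog:
        computed[entry.name] = _eval_vectorized(pts, entry, fl, computed)
    return pd.DataFrame(computed, index=np.flatnonzero(keep))


def shannon_entropy(values: Sequence[float], bins: int = ENTROPY_BINS) -> float:
    """Histogram Shannon entropy in bits.

    Equal-width bins spanning [min, max]; 0 for a constant series.
    Bounded by log2(bins).
    """
    x = np.asarray(values, dtype=float)
    if bins < 2:
        raise ValueError("bins must be >= 2")
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(x, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log2(p)).sum())


def approx_entropy(values: Sequence[float], m: int = APEN_M, r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) with Chebyshev distance.

    Self-matches are included (the original regularity-statistic
    definition), so the result is non-negative up to rounding.  ``r``
    defaults to 0.2 times the population std of the series.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"need at least {m + 2} values for ApEn(m={m})")
    if r is None:
        r = APEN_R_FACTOR * float(np.std(x))
    if r <= 0:
        return 0.0

    def phi(mm: int) -> float:
        nvec = n - mm + 1
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)  # (nvec, mm)
        # Chebyshev distances between all template pairs
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        c = (d <= r).sum(axis=1) / nvec
        return float(np.log(c).mean())

    return phi(m) - phi(m + 1)


@dataclass
class ScalarSummary:
    """The 10 per-series statistics; NaN marks an undefined value."""

    mean: float
    std: float
    rsd: float
    min: float
    max: float
    range: float
    var: float
    slope: float
    se: float
    ae: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in STAT_NAMES}


def summarize(values: Sequence[float], fps: float) -> ScalarSummary:
    """Collapse one feature series to its 10 summary statistics.

    The slope is the OLS slope of value against time in seconds
    (frame index / fps), which makes it frame-rate independent; std and
    var are population moments so var == std**2 exactly.  Entropy
    statistics need at least 8 values and are NaN below that.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InsufficientDataError("need at least 2 finite values")
    mean = float(x.mean())
    std = float(x.std())
    rsd = 0.0 if std == 0.0 else (std / abs(mean) if abs(mean) > 1e-300 else math.nan)
    lo, hi = float(x.min()), float(x.max())
    t = np.arange(x.size) / fps
    slope = float(np.polyfit(t, x, 1)[0]) if x.size >= 2 else math.nan
    if x.size >= MIN_LEN_ENTROPY:
        se = shannon_entropy(x)
        ae = 0.0 if std == 0.0 else approx_entropy(x)
    else:
        se = ae = math.nan
    return ScalarSummary(mean=mean, std=std, rsd=rsd, min=lo, max=hi,
                         range=hi - lo, var=std**2, slope=slope, se=se, ae=ae)


def summarize_all(features: pd.DataFrame, fps: float) -> dict[str, float]:
    """Summaries of every feature column, keyed ``<stat><NAME>``."""
    out: dict[str, float] = {}
    for name in features.columns:
        s = summarize(features[name].to_numpy(), fps)
        for stat, v in s.as_dict().items():
            out[f"{stat}{name}"] = v
    return out


def read_landmark_csv(path) -> list[LandmarkSeries]:
    """Read ``subject,task,frame,x1,y1,...,x68,y68`` CSV into series."""
    df = pd.read_csv(path)
    cols = [f"{ax}{i}" for i in range(1, 69) for ax in ("x", "y")]
    out = []
    for (subj, task), g in df.groupby(["subject", "task"], sort=True):
        g = g.sort_values("frame")
        pts = g[cols].to_numpy(dtype=float).reshape(len(g), 68, 2)
        fps = float(g["fps"].iloc[0]) if "fps" in g else 25.0
        gap = g["gap"].to_numpy(dtype=bool) if "gap" in g else None
        out.append(LandmarkSeries(str(subj), str(task), fps, pts, gap))
    return out
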