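"""Univariate group statistics and mRMR feature preselection.

Each feature is compared between PD and HC with the two-sided
Mann-Whitney U test (exact enumeration for small tie-free groups,
otherwise the tie- and continuity-corrected normal approximation), and
p-values are adjusted across features by Benjamini-Hochberg FDR.  The
test results are reported but do not gate selection: feature
preselection is driven solely by the greedy mRMR algorithm (MID
criterion: mutual-information relevance with the label minus mean
mutual information with the already-selected set, continuous features
discretized into 3 equal-frequency bins).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .tables import feature_columns

logger = logging.getLogger(__name__)

__all__ = ["mannwhitney_fdr", "mrmr_select", "SelectionResult", "mutual_information"]

MRMR_BINS = 3


def _iqr(x: np.ndarray) -> float:
    q1, q3 = np.percentile(x, [25, 75])
    return float(q3 - q1)


def mannwhitney_fdr(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature Mann-Whitney U with BH-FDR adjustment.

    Returns a frame (feature, U, p_value, p_value_fdr, median/IQR per
    group) sorted by raw p-value; U is reported for the PD sample.
    Features with fewer than 2 non-missing values in either group are
    skipped with a warning.
    """
    if "label" not in table.columns:
        raise ValueError("table must carry a 'label' column")
    y = table["label"].to_numpy()
    if not ((y == 1).any() and (y == 0).any()):
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in feature_columns(table):
        v = table[col].to_numpy(dtype=float)
        pdv = v[(y == 1) & np.isfinite(v)]
        hcv = v[(y == 0) & np.isfinite(v)]
        if pdv.size < 2 or hcv.size < 2:
            logger.warning("mannwhitney_fdr: skipping %s (too few values)", col)
            continue
        tie_free = np.unique(np.concatenate([pdv, hcv])).size == pdv.size + hcv.size
        method = "exact" if (pdv.size <= 8 and hcv.size <= 8 and tie_free) else "asymptotic"
        res = sstats.mannwhitneyu(pdv, hcv, alternative="two-sided", method=method)
        rows.append({"feature": col, "U": float(res.statistic),
                     "p_value": float(res.pvalue),
                     "median_pd": float(np.median(pdv)),
                     "median_hc": float(np.median(hcv)),
                     "iqr_pd": _iqr(pdv), "iqr_hc": _iqr(hcv)})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_value_fdr"] = multipletests(out["p_value"], alpha=alpha,
                                       method="fdr_bh")[1]
    out["significant_fdr"] = out["p_value_fdr"] < alpha
    cols = ["feature", "U", "p_value", "p_value_fdr", "median_pd", "median_hc",
            "iqr_pd", "iqr_hc", "significant_fdr"]
    return out[cols].sort_values("p_value", kind="stable").reset_index(drop=True)


def _discretize(x: np.ndarray, bins: int = MRMR_BINS) -> np.ndarray:
    """Equal-frequency binning to integer codes; NaNs get their own bin."""
    codes = np.zeros(x.size, dtype=int)
    ok = np.isfinite(x)
    if ok.sum() > 0:
        ranks = sstats.rankdata(x[ok], method="average")
        codes[ok] = np.minimum((ranks - 1) * bins // ok.sum(), bins - 1).astype(int)
    codes[~ok] = bins
    return codes


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two small integer code vectors, from counts."""
    ja = np.unique(a, return_inverse=True)[1]
    jb = np.unique(b, return_inverse=True)[1]
    na, nb = ja.max() + 1, jb.max() + 1
    joint = np.bincount(ja * nb + jb, minlength=na * nb).reshape(na, nb) / a.size
    pa, pb = joint.sum(axis=1), joint.sum(axis=0)
    nz = joint > 0
    return float((joint[nz] * np.log(joint[nz] / np.outer(pa, pb)[nz])).sum())


@dataclass
class SelectionResult:
    """Ordered mRMR selection with per-step scores."""

    features: list[str]
    relevance: list[float]
    redundancy: list[float]
    k: int
    scores: list[float] = field(default_factory=list)


def mrmr_select(features: pd.DataFrame, labels, k: int = 50) -> SelectionResult:
    """Greedy mRMR (MID) selection of up to ``k`` features.

    The first pick maximizes relevance (MI with the label); every later
    pick maximizes relevance minus mean MI with the selected set.
    Redundancy against the growing set is maintained incrementally, so
    each step costs one MI evaluation per remaining candidate.  Ties
    break on column order.  Constant features are excluded; asking for
    more features than exist selects all with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    y = np.asarray(labels)
    cols = [c for c in features.columns
            if np.nanstd(features[c].to_numpy(dtype=float)) > 0]
    if k > len(cols):
        logger.warning("mrmr_select: k=%d > %d candidates; selecting all", k, len(cols))
        k = len(cols)
    if k == 0:
        raise ValueError("no non-constant candidate features")
    codes = {c: _discretize(features[c].to_numpy(dtype=float)) for c in cols}
    ycodes = np.unique(y, return_inverse=True)[1]
    relevance = {c: mutual_information(codes[c], ycodes) for c in cols}
    selected: list[str] = []
    rel_hist, red_hist, score_hist = [], [], []
    red_sum = {c: 0.0 for c in cols}
    remaining = list(cols)
    while len(selected) < k:
        if selected:
            last = selected[-1]
            for c in remaining:
                red_sum[c] += mutual_information(codes[c], codes[last])
        best, best_score, best_red = None, -np.inf, 0.0
        for c in remaining:
            red = red_sum[c] / len(selected) if selected else 0.0
            score = relevance[c] - red
            if score > best_score:
                best, best_score, best_red = c, score, red
        selected.append(best)
        remaining.remove(best)
        rel_hist.append(relevance[best])
        red_hist.append(best_red)
        score_hist.append(best_score)
    return SelectionResult(features=selected, relevance=rel_hist,
                           redundancy=red_hist, k=k, scores=score_hist)
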