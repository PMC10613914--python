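"""Wide subject-by-feature table assembly and confound residualization.

Feature columns follow ``<stat><MEASURE>__TSKnn`` for video (e.g.
``slopeM7__TSK41``) and ``<measure>__TSKnn`` for audio (e.g.
``jitter__TSK3``).  The table carries ``label`` (PD=1, HC=0) and the
confounds ``age`` (years) and ``gender`` (male=1) alongside features.

Confound removal is the regression-out method: each feature is replaced
by its residual from an OLS fit on [intercept, age, gender].  ``fit_all``
fits on the whole cohort (the original study's order — residualized
values exist before any train/test split, which leaks distributional
information into preprocessing and is therefore also offered as
``fit_train``, where coefficients come from training folds only).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["assemble_table", "select_task", "regress_out",
           "feature_columns", "META_COLUMNS"]

META_COLUMNS = ("label", "age", "gender")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def _encode_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.set_index("subject")
    return pd.DataFrame({
        "label": (meta["group"] == "PD").astype(int),
        "age": meta["age"].astype(float),
        "gender": (meta["gender"] == "M").astype(int),
    })


def assemble_table(video: pd.DataFrame | None, audio: pd.DataFrame | None,
                   metadata: pd.DataFrame, modality: str = "multimodal",
                   ) -> pd.DataFrame:
    """Early-fusion assembly of the wide feature table.

    ``video``/``audio`` are subject-indexed feature frames; multimodal
    concatenates their columns.  Subjects with no features in the
    requested modality are dropped with a warning; duplicate column
    names are an error.  Missing cells stay NaN (imputation happens on
    training folds at model time).
    """
    if modality == "video":
        parts = [video]
    elif modality == "audio":
        parts = [audio]
    elif modality == "multimodal":
        parts = [video, audio]
    else:
        raise ValueError(f"unknown modality {modality!r}")
    parts = [p for p in parts if p is not None]
    if not parts:
        raise ValueError("no feature tables for requested modality")
    feats = pd.concat(parts, axis=1)
    if feats.columns.duplicated().any():
        dups = sorted(set(feats.columns[feats.columns.duplicated()]))
        raise ValueError(f"duplicate feature columns: {dups[:5]}")
    meta = _encode_metadata(metadata)
    empty = feats.isna().all(axis=1)
    missing = meta.index.difference(feats.index)
    dropped = set(feats.index[empty]) | set(missing)
    if dropped:
        logger.warning("dropping %d subjects without features", len(dropped))
    keep = [s for s in meta.index if s in feats.index and not empty.get(s, True)]
    return pd.concat([meta.loc[keep], feats.loc[keep]], axis=1)


def select_task(table: pd.DataFrame, task_code: str) -> pd.DataFrame:
    """Sub-table with the metadata columns plus one task's features."""
    cols = [c for c in feature_columns(table) if c.endswith(f"__{task_code}")]
    if not cols:
        raise KeyError(f"no features for task {task_code}")
    return table[list(META_COLUMNS) + cols]


def regress_out(table: pd.DataFrame, confound_names=("age", "gender"),
                mode: str = "fit_all", train_index=None) -> pd.DataFrame:
    """Replace every feature by its OLS residual on the confounds.

    The design matrix is [1, *confounds]; residuals of a ``fit_all``
    fit are exactly uncorrelated with each confound and have mean zero.
    In ``fit_train`` mode coefficients are estimated on ``train_index``
    rows only and applied everywhere (no test-set leakage).  Features
    with fewer than 3 non-missing values are left unchanged.
    """
    if mode not in ("fit_all", "fit_train"):
        raise ValueError(f"unknown mode {mode!r}")
    for c in confound_names:
        if c not in table.columns:
            raise ValueError(f"confound column {c!r} missing")
        if table[c].nunique(dropna=True) < 2:
            raise ValueError(f"confound {c!r} is constant")
    fit_rows = (table.index if mode == "fit_all"
                else pd.Index(train_index))
    X_all = np.column_stack([np.ones(len(table))]
                            + [table[c].to_numpy(dtype=float) for c in confound_names])
    fit_mask = table.index.isin(fit_rows)
    out = table.copy()
    for col in feature_columns(table):
        y = table[col].to_numpy(dtype=float)
        ok = np.isfinite(y)
        use = ok & fit_mask
        if use.sum() < 3:
            logger.warning("regress_out: feature %s has <3 values; left unchanged", col)
            continue
        beta, *_ = np.linalg.lstsq(X_all[use], y[use], rcond=None)
        resid = y - X_all @ beta
        resid[~ok] = np.nan
        out[col] = resid
    return out
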