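"""Scoring of predicted vs true cell-type proportions: Pearson r and RMSE.

Metrics are reported per cell type (across samples) and pooled over all
(sample, cell type) pairs.  Correlations of constant vectors are undefined and
reported as missing rather than imputed.  A rescaling helper drops the
uncharacterized column and renormalizes rows to sum 1, matching the protocol
used when comparing against tools that cannot estimate that fraction.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

__all__ = [
    "pearson",
    "rmse",
    "metrics_table",
    "rescale_excluding_uncharacterized",
]

UNCHARACTERIZED = "uncharacterized"


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN (never a crash) when either input is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least two observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(xc @ yc) / denom


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared error."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def metrics_table(pred: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type and pooled (r, RMSE) between two fraction tables.

    Both tables are samples x cell types with matching ids; the uncharacterized
    column is scored like any other when present in both.  Undefined
    correlations appear as NaN and are excluded from nothing else (their RMSE
    is still computed).  The pooled row concatenates every (sample, cell type)
    pair.
    """
    if set(pred.columns) != set(truth.columns):
        only_p = sorted(set(pred.columns) - set(truth.columns))
        only_t = sorted(set(truth.columns) - set(pred.columns))
        raise ValueError(
            f"column mismatch: only in predictions {only_p}, only in truth {only_t}"
        )
    if set(pred.index) != set(truth.index):
        raise ValueError("sample id mismatch between predictions and truth")
    truth = truth.loc[pred.index, pred.columns]
    rows = []
    for ct in pred.columns:
        rows.append(
            {
                "cell_type": ct,
                "pearson_r": pearson(pred[ct].to_numpy(), truth[ct].to_numpy()),
                "rmse": rmse(pred[ct].to_numpy(), truth[ct].to_numpy()),
                "n": len(pred),
            }
        )
    flat_p = pred.to_numpy().ravel()
    flat_t = truth.to_numpy().ravel()
    rows.append(
        {
            "cell_type": "pooled",
            "pearson_r": pearson(flat_p, flat_t),
            "rmse": rmse(flat_p, flat_t),
            "n": flat_p.size,
        }
    )
    return pd.DataFrame(rows).set_index("cell_type")


def rescale_excluding_uncharacterized(
    pred: pd.DataFrame, truth: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop the uncharacterized column and renormalize each row to sum 1.

    Rows whose remaining fractions sum to 0 in either table are excluded from
    both (they carry no information about the characterized mixture).
    """
    for name, df in (("predictions", pred), ("truth", truth)):
        if UNCHARACTERIZED not in df.columns:
            raise ValueError(f"{name} table has no '{UNCHARACTERIZED}' column")
    p = pred.drop(columns=[UNCHARACTERIZED])
    t = truth.drop(columns=[UNCHARACTERIZED]).loc[p.index, p.columns]
    p_sum = p.sum(axis=1)
    t_sum = t.sum(axis=1)
    keep = (p_sum > 0) & (t_sum > 0)
    p = p.loc[keep].div(p_sum[keep], axis=0)
    t = t.loc[keep].div(t_sum[keep], axis=0)
    return p, t
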