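"""Agreement and error metrics between reference and predicted maps.

Implements the per-tissue report used to judge the reconstruction:
MAPE (%), intraclass correlation (two-way random, absolute agreement,
single measures by default), and Bland-Altman difference statistics
with the Pearson correlation of difference against mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TissueMasks",
    "BlandAltman",
    "threshold_probability_map",
    "mape",
    "icc_agreement",
    "bland_altman",
    "evaluate_maps",
]


@dataclass
class TissueMasks:
    masks: dict[str, np.ndarray]

    def __post_init__(self):
        self.masks = {name: np.asarray(m).astype(bool) for name, m in self.masks.items()}
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError("tissue masks must share a shape")

    def items(self):
        return self.masks.items()


@dataclass(frozen=True)
class BlandAltman:
    mean: np.ndarray
    diff: np.ndarray
    mean_diff: float
    diff_sd: float
    pearson_r: float      # NaN when the difference or mean series is degenerate
    p_value: float


def threshold_probability_map(prob: np.ndarray, frac: float = 0.8) -> np.ndarray:
    """Binary mask of voxels at or above ``frac`` of the map's maximum."""
    prob = np.asarray(prob, dtype=np.float64)
    if np.any(prob < 0):
        raise ValueError("probability map must be non-negative")
    peak = prob.max()
    if peak == 0:
        raise ValueError("probability map is identically zero")
    return prob >= frac * peak


def mape(reference, predicted) -> float:
    """Mean absolute percentage error: 100 * mean(|ref - pred| / ref)."""
    ref = np.asarray(reference, dtype=np.float64).ravel()
    pred = np.asarray(predicted, dtype=np.float64).ravel()
    if ref.shape != pred.shape:
        raise ValueError("series lengths differ")
    if np.any(ref <= 0):
        raise ValueError("reference values must be positive")
    return float(100.0 * np.mean(np.abs(ref - pred) / ref))


def icc_agreement(x, y, form: str = "ICC2") -> float:
    """Intraclass correlation between two raters/methods over shared targets.

    ``ICC2`` (the default) is the two-way random-effects, absolute-agreement,
    single-measure coefficient; other pingouin type labels (ICC1, ICC3, and
    the average-measure ICC1k/2k/3k) are accepted.
    """
    import pingouin as pg

    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("series lengths differ")
    if x.size < 3:
        raise ValueError("ICC requires at least 3 paired measurements")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance in both series; ICC undefined")
    n = x.size
    frame = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([x, y]),
    })
    table = pg.intraclass_corr(frame, targets="target", raters="rater", ratings="score")
    # accept both Shrout-Fleiss shorthand and McGraw-Wong labels
    aliases = {"ICC1": "ICC(1,1)", "ICC2": "ICC(A,1)", "ICC3": "ICC(C,1)",
               "ICC1k": "ICC(1,k)", "ICC2k": "ICC(A,k)", "ICC3k": "ICC(C,k)"}
    wanted = {form, aliases.get(form, form)}
    value = table.loc[table["Type"].isin(wanted), "ICC"]
    if value.empty:
        raise ValueError(f"unknown ICC form {form!r}")
    return float(value.iloc[0])


def bland_altman(x, y) -> BlandAltman:
    """Difference-vs-mean agreement statistics for paired series (diff = x - y)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length series with at least 3 pairs")
    mean = (x + y) / 2.0
    diff = x - y
    mean_diff = float(diff.mean())
    diff_sd = float(diff.std(ddof=1))
    if np.ptp(diff) == 0 or np.ptp(mean) == 0:
        r, p = np.nan, np.nan      # degenerate variance: correlation undefined
    else:
        r, p = stats.pearsonr(diff, mean)
    return BlandAltman(mean, diff, mean_diff, diff_sd, float(r), float(p))


def evaluate_maps(reference, predicted, masks: TissueMasks, icc_form: str = "ICC2") -> pd.DataFrame:
    """Per-tissue, per-parameter agreement report (voxelwise pairing).

    ``reference`` and ``predicted`` are objects exposing ``t1_map`` and
    ``t2s_map`` (matching results, phantom-truth adapters or predicted
    maps).  One row per tissue x parameter with MAPE, ICC, the pooled
    mean, the Bland-Altman difference statistics, and the voxel count.
    """
    rows = []
    for tissue, mask in masks.items():
        if not mask.any():
            raise ValueError(f"tissue mask {tissue!r} is empty")
        for param, attr in (("T1", "t1_map"), ("T2s", "t2s_map")):
            ref = getattr(reference, attr)[mask]
            pred = getattr(predicted, attr)[mask]
            ba = bland_altman(ref, pred)
            if np.array_equal(ref, pred):
                icc = 1.0
            elif np.ptp(ref) == 0 and np.ptp(pred) == 0:
                icc = np.nan  # constant maps: agreement is indeterminate
            else:
                icc = icc_agreement(ref, pred, form=icc_form)
            rows.append({
                "tissue": tissue,
                "parameter": param,
                "icc": icc,
                "mape_pct": mape(ref, pred),
                "mean_ms": float(np.mean((ref + pred) / 2.0)),
                "mean_diff_ms": ba.mean_diff,
                "diff_sd_ms": ba.diff_sd,
                "pearson_r": ba.pearson_r,
                "p_value": ba.p_value,
                "n_voxels": int(mask.sum()),
            })
    return pd.DataFrame.from_records(rows)
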