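"""Agreement statistics between predicted and reference segmentations/volumes.

Dice similarity for voxel overlap; a two-way random-effects, single-measure,
absolute-agreement intraclass correlation (ICC(2,1)) with its F-based 95% CI
and p-value for paired volume series; and Bland-Altman bias with 95% limits
of agreement.  The ICC is delegated to pingouin's ANOVA-based implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|); two empty masks score 1."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        warnings.warn("both masks empty; Dice defined as 1", stacklevel=2)
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float


def icc(x, y) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1D series")
    n = len(x)
    if n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("ICC undefined: zero variance in both series")
    import pingouin as pg

    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["x", "y"], n),
        "score": np.concatenate([x, y]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = pg.intraclass_corr(df, targets="target", raters="rater",
                                   ratings="score")
    table = table.set_index("Type")
    # pingouin labels the two-way random absolute-agreement single-measure
    # form ICC2 or ICC(A,1) depending on version
    key = "ICC2" if "ICC2" in table.index else "ICC(A,1)"
    row = table.loc[key]
    ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
    lo, hi = row[ci_col]
    return ICCResult(icc=float(row["ICC"]), ci_low=float(lo),
                     ci_high=float(hi), p_value=float(row["pval"]))


@dataclass(frozen=True)
class BlandAltman:
    mean_difference: float
    loa_low: float
    loa_high: float
    sd_difference: float


def bland_altman(x, y) -> BlandAltman:
    """Mean difference (x - y) and 95% limits of agreement d +/- 1.96 SD,
    SD with the n-1 denominator."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need paired 1D series with n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        mean_difference=mean,
        loa_low=mean - 1.96 * sd,
        loa_high=mean + 1.96 * sd,
        sd_difference=sd,
    )


def agreement_report(
    predicted_ml,
    reference_ml,
    per_case_dice: list[float] | None = None,
) -> dict:
    """Cohort-level agreement summary: ICC, Bland-Altman, Dice median + IQR."""
    res = {
        "icc": icc(predicted_ml, reference_ml).__dict__,
        "bland_altman": bland_altman(predicted_ml, reference_ml).__dict__,
    }
    if per_case_dice is not None:
        d = np.asarray(per_case_dice, dtype=float)
        res["dice"] = {
            "median": float(np.median(d)),
            "iqr_low": float(np.percentile(d, 25)),
            "iqr_high": float(np.percentile(d, 75)),
            "per_case": d.tolist(),
        }
    return res
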