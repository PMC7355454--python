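"""Target-mismatch classification, infarct growth, tertiles, outcomes.

Target mismatch follows the DEFUSE-style rule on baseline volumes: perfusion
to core ratio >= 1.8, perfusion minus core >= 15 mL, core < 70 mL and severe
lesion < 100 mL (all four must hold).  Infarct growth is final minus baseline
core volume, sign preserved.  Growth groups come either from empirical
tertiles of a cohort or from fixed cutoffs (low < 15 mL, high >= 35 mL).
A favorable 90-day outcome is a modified Rankin Scale score of 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISMATCH_RATIO = 1.8
MISMATCH_DIFF_ML = 15.0
MISMATCH_CORE_MAX_ML = 70.0
MISMATCH_SEVERE_MAX_ML = 100.0
TERTILE_LOW_ML = 15.0
TERTILE_HIGH_ML = 35.0
FAVORABLE_MRS_MAX = 1


@dataclass(frozen=True)
class MismatchResult:
    ratio_met: bool
    difference_met: bool
    core_size_met: bool
    severe_met: bool
    core_ml: float
    perfusion_ml: float
    severe_ml: float

    @property
    def mismatch(self) -> bool:
        return (self.ratio_met and self.difference_met
                and self.core_size_met and self.severe_met)


def classify_mismatch(
    core_ml: float,
    perfusion_ml: float,
    severe_ml: float,
    ratio: float = MISMATCH_RATIO,
    diff_ml: float = MISMATCH_DIFF_ML,
    core_max_ml: float = MISMATCH_CORE_MAX_ML,
    severe_max_ml: float = MISMATCH_SEVERE_MAX_ML,
) -> MismatchResult:
    """Evaluate the four target-mismatch criteria on baseline volumes.

    A zero core counts as meeting the ratio criterion iff the perfusion
    lesion is non-empty (the limit of an infinite ratio).
    """
    if min(core_ml, perfusion_ml, severe_ml) < 0:
        raise ValueError("lesion volumes must be non-negative")
    if core_ml == 0:
        ratio_met = perfusion_ml > 0
    else:
        ratio_met = perfusion_ml / core_ml >= ratio
    return MismatchResult(
        ratio_met=ratio_met,
        difference_met=perfusion_ml - core_ml >= diff_ml,
        core_size_met=core_ml < core_max_ml,
        severe_met=severe_ml < severe_max_ml,
        core_ml=core_ml,
        perfusion_ml=perfusion_ml,
        severe_ml=severe_ml,
    )


def infarct_growth(final_ml: float, core_ml: float) -> float:
    """Final infarct volume minus baseline core volume (mL, may be negative)."""
    if final_ml < 0 or core_ml < 0:
        raise ValueError("volumes must be non-negative")
    return final_ml - core_ml


def growth_tertiles(
    growth_ml,
    cutoffs: tuple[float, float] | None = None,
) -> tuple[list[str], tuple[float, float], str]:
    """Label each growth value low / intermediate / high.

    With ``cutoffs=None`` the cohort's empirical tertile cutpoints (1/3 and
    2/3 quantiles, linear interpolation) are used; otherwise the fixed
    ``(low, high)`` bounds are applied (value < low -> low, value >= high ->
    high).  Values tied with a cutpoint go to the lower group.  Returns
    (labels, cutoffs used, mode).
    """
    growth = np.asarray(growth_ml, dtype=float)
    if cutoffs is None:
        if len(growth) < 3:
            raise ValueError("need >= 3 cases for empirical tertiles")
        lo, hi = np.quantile(growth, [1 / 3, 2 / 3])
        mode = "empirical"
        labels = ["low" if g <= lo else ("intermediate" if g <= hi else "high")
                  for g in growth]
    else:
        lo, hi = cutoffs
        mode = "fixed"
        labels = ["low" if g < lo else ("high" if g >= hi else "intermediate")
                  for g in growth]
    return labels, (float(lo), float(hi)), mode


@dataclass(frozen=True)
class OutcomeSummary:
    group: str
    n: int
    n_favorable: int
    percent_favorable: float
    mrs_histogram: tuple[int, ...]     # counts for mRS 0..6
    n_missing_mrs: int = 0


def outcome_summary(groups: dict[str, list[int | None]]) -> list[OutcomeSummary]:
    """Favorable-outcome percentage and full mRS distribution per group.

    ``groups`` maps a group label to its cases' 90-day mRS scores; ``None``
    entries (missing scores) are excluded from the denominators and counted.
    """
    out = []
    for name, scores in groups.items():
        known = [int(s) for s in scores if s is not None]
        missing = len(scores) - len(known)
        if any(not 0 <= s <= 6 for s in known):
            raise ValueError("mRS scores must lie in 0..6")
        fav = sum(s <= FAVORABLE_MRS_MAX for s in known)
        hist = tuple(int(np.sum([s == m for s in known])) for m in range(7))
        pct = 100.0 * fav / len(known) if known else float("nan")
        out.append(OutcomeSummary(
            group=name, n=len(known), n_favorable=fav,
            percent_favorable=pct, mrs_histogram=hist, n_missing_mrs=missing,
        ))
    return out


def cohort_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble the per-case clinical table from pipeline row dicts.

    Each row supplies baseline/predicted/final volumes and mRS; mismatch and
    growth columns are derived here so the table is self-consistent.
    """
    df = pd.DataFrame(rows)
    mm = [classify_mismatch(r["core_ml"], r["perfusion_ml"], r["severe_ml"])
          for _, r in df.iterrows()]
    df["mismatch"] = [m.mismatch for m in mm]
    for scen in ("sr", "ur"):
        col = f"predicted_{scen}_ml"
        if col in df:
            df[f"predicted_growth_{scen}_ml"] = df[col] - df["core_ml"]
    if "final_ml" in df:
        df["actual_growth_ml"] = df["final_ml"] - df["core_ml"]
    return df
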