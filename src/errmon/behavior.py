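"""Trial classification and behavioral statistics for the Go/Nogo task.

Response categories
-------------------
correct_go        go stimulus, one press (a second press outside the
                  signaling window is ignored)
miss_go           go stimulus, no press
incorrect_go      go stimulus, press plus a valid error-signaling press
correct_withhold  nogo stimulus, no press
detected_error    nogo stimulus, press plus second press inside the
                  signaling window (1200-2000 ms after stimulus onset,
                  i.e. after the fixation cross appears)
undetected_error  nogo stimulus, press without a valid second press

Post-error slowing is quantified as dPES = PES - PCS, where PES is the
median RT of correct go trials immediately preceded (within the same block)
by a detected error and PCS the median RT of correct go trials preceded by
a correct go trial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "BehavioralSummary",
    "DataIntegrityError",
    "classify_trials",
    "summarize",
    "delta_pes",
    "inclusion",
    "classify_phase",
]

CATEGORIES = ("correct_go", "miss_go", "incorrect_go",
              "correct_withhold", "detected_error", "undetected_error")

GO_CATEGORIES = ("correct_go", "miss_go", "incorrect_go")
NOGO_CATEGORIES = ("correct_withhold", "detected_error", "undetected_error")


class DataIntegrityError(ValueError):
    pass


def classify_trials(trials: pd.DataFrame,
                    signaling_window: tuple[float, float] = (1200.0, 2000.0)
                    ) -> pd.DataFrame:
    """Assign exactly one response category per trial (new frame returned).

    Second presses outside the signaling window are ignored: the trial
    counts as correct_go / undetected_error respectively.
    """
    lo, hi = signaling_window
    out = trials.copy()
    cats = []
    for row in out.itertuples(index=False):
        has1, has2 = np.isfinite(row.rt1_ms), np.isfinite(row.rt2_ms)
        if has2 and not has1:
            raise DataIntegrityError(
                f"trial {row.trial}: second press without a first press")
        signaled = has2 and lo <= row.rt2_ms <= hi
        if row.stimulus_kind == "go":
            if not has1:
                cats.append("miss_go")
            elif signaled:
                cats.append("incorrect_go")
            else:
                cats.append("correct_go")
        else:
            if not has1:
                cats.append("correct_withhold")
            elif signaled:
                cats.append("detected_error")
            else:
                cats.append("undetected_error")
    out["category"] = cats
    return out


@dataclass
class BehavioralSummary:
    """Per-subject behavioral variables (rates in %, times in ms)."""

    rates: dict                 # category -> % of its stimulus type
    counts: dict                # category -> raw count
    error_detection_rate: float # % detected of all nogo errors; NaN if no errors
    baseline_rt: float          # median RT, correct go
    error_rt: float             # median RT, detected errors
    delta_pes: float            # PES - PCS; NaN when no qualifying pairs


def summarize(trials: pd.DataFrame) -> BehavioralSummary:
    if "category" not in trials.columns or (trials["category"] == "").any():
        raise ValueError("trials must be classified first")
    n_go = int((trials["stimulus_kind"] == "go").sum())
    n_nogo = int((trials["stimulus_kind"] == "nogo").sum())
    if n_nogo == 0:
        raise ValueError("no nogo trials in session")
    counts = {c: int((trials["category"] == c).sum()) for c in CATEGORIES}
    rates = {}
    for c in CATEGORIES:
        denom = n_go if c in GO_CATEGORIES else n_nogo
        rates[c] = 100.0 * counts[c] / denom if denom else math.nan
    n_err = counts["detected_error"] + counts["undetected_error"]
    detection = 100.0 * counts["detected_error"] / n_err if n_err else math.nan

    def _median_rt(cat: str) -> float:
        vals = trials.loc[trials["category"] == cat, "rt1_ms"].dropna()
        return float(vals.median()) if len(vals) else math.nan

    return BehavioralSummary(
        rates=rates, counts=counts, error_detection_rate=detection,
        baseline_rt=_median_rt("correct_go"),
        error_rt=_median_rt("detected_error"),
        delta_pes=delta_pes(trials),
    )


def delta_pes(trials: pd.DataFrame) -> float:
    """Median post-error minus median post-correct RT (NaN if undefined).

    Only consecutive same-block pairs count; the post trial must be a
    correct go, the preceding trial a detected error (PES) or a correct go
    (PCS).  Trials following misses, undetected errors, or incorrect go
    trials enter neither pool.
    """
    if "category" not in trials.columns:
        raise ValueError("trials must be classified first")
    t = trials.sort_values("trial").reset_index(drop=True)
    pes_pool, pcs_pool = [], []
    for k in range(1, len(t)):
        prev, cur = t.iloc[k - 1], t.iloc[k]
        if cur["category"] != "correct_go" or cur["block"] != prev["block"] \
                or cur["trial"] != prev["trial"] + 1 or not np.isfinite(cur["rt1_ms"]):
            continue
        if prev["category"] == "detected_error":
            pes_pool.append(cur["rt1_ms"])
        elif prev["category"] == "correct_go":
            pcs_pool.append(cur["rt1_ms"])
    if not pes_pool or not pcs_pool:
        return math.nan
    return float(np.median(pes_pool) - np.median(pcs_pool))


def inclusion(counts: dict, purpose: str,
              min_erp_trials: int = 6, min_mvpa_errors: int = 10
              ) -> tuple[bool, str]:
    """Apply the per-subject trial-count inclusion criteria.

    ERP analyses need >= 6 trials for each analyzed response type (correct
    go and detected errors); decoding needs >= 10 errors with detected and
    undetected collapsed.
    """
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative trial count")
    if purpose == "erp":
        for cat in ("correct_go", "detected_error"):
            if counts.get(cat, 0) < min_erp_trials:
                return False, f"{cat}<{min_erp_trials}"
        return True, "ok"
    if purpose == "mvpa":
        n_err = counts.get("detected_error", 0) + counts.get("undetected_error", 0)
        if n_err < min_mvpa_errors:
            return False, f"errors<{min_mvpa_errors}"
        return True, "ok"
    raise ValueError(f"unknown purpose {purpose!r}")


def classify_phase(days_post_stroke: float) -> str:
    """Sub-acute within 4-28 days post-stroke, chronic beyond 28 days."""
    if days_post_stroke < 4:
        raise ValueError("days post-stroke < 4 is outside the recruitment window")
    return "subacute" if days_post_stroke <= 28 else "chronic"
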