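"""Trial- and subject-level exclusion rules.

The pipeline applies, in order:

1. RT floor: trials with RT < 250 ms are dropped from RT analyses.
2. RT outliers: trials with RT more than 3 SD above the subject's mean for
   the respective condition cell are dropped (mean/SD computed once on the
   >= 250 ms trials; no iterative re-trimming).
3. Error trials are dropped from RT analyses only.

Error rates for subject-level exclusion are always computed on the
*untrimmed* log. A (subject, condition cell) with error rate > .30 (strict)
is excluded from every analysis involving that cell -- condition-wise, not
globally. A subject who never switched response hands in the feedback run is
flagged ``never_switched`` and excluded from feedback-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RT_FLOOR_MS = 250.0
OUTLIER_SD = 3.0
MAX_ERROR_RATE = 0.30


def condition_cell(log: pd.DataFrame) -> pd.Series:
    """Analysis condition cell per trial.

    Cognitive trials use their condition name; affective trials cross task
    with transition (e.g. ``gender_switch``); feedback trials form a single
    cell.
    """
    paradigm = log["paradigm"].astype(str)
    cond = log["condition"].astype(str)
    rule = log["rule"].astype(str)
    cell = cond.copy()
    aff = paradigm == "affective"
    cell[aff] = rule[aff] + "_" + cond[aff]
    cell[paradigm == "feedback"] = "feedback"
    return cell


@dataclass
class ExclusionReport:
    """Outcome of the exclusion rules.

    ``subject_conditions``: one row per (subject, paradigm, cell) with its
    untrimmed error rate, an ``excluded`` flag and a reason
    (``high_error_rate`` / ``never_switched`` / ``none``).
    ``trials``: one row per *dropped* trial with its single drop reason
    (``rt_too_fast`` / ``rt_outlier``); kept trials are not listed.
    ``warnings``: free-text notes (e.g. cells too small for an SD).
    """

    subject_conditions: pd.DataFrame
    trials: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def excluded_cells(self) -> set[tuple[int, str]]:
        sc = self.subject_conditions
        bad = sc[sc["excluded"]]
        return set(zip(bad["subject"].astype(int), bad["cell"]))


def trim_rts(log: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the RT floor and the single-pass +3 SD outlier rule.

    Returns the trimmed log (all columns preserved; rows without an RT are
    kept -- they are invisible to RT analyses anyway) and a report listing
    each removal. Cells with fewer than 2 valid RTs keep their trials and
    produce a warning (the SD is undefined).
    """
    log = log.reset_index(drop=True)
    cell = condition_cell(log)
    rt = log["rt"].to_numpy(dtype=float)
    has_rt = ~np.isnan(rt)
    too_fast = has_rt & (rt < RT_FLOOR_MS)

    keep = has_rt & ~too_fast
    df = pd.DataFrame({"subject": log["subject"], "cell": cell, "rt": rt})
    stats = (df[keep].groupby(["subject", "cell"])["rt"]
             .agg(["mean", "std", "count"]))
    warnings: list[str] = []
    thresh = pd.Series(np.inf, index=stats.index)
    ok = stats["count"] >= 2
    thresh[ok] = stats.loc[ok, "mean"] + OUTLIER_SD * stats.loc[ok, "std"]
    for (s, c), n in stats.loc[~ok, "count"].items():
        warnings.append(f"subject {s} cell {c}: only {n} valid RT(s); "
                        "SD undefined, trials kept")
    cutoffs = pd.MultiIndex.from_arrays([df["subject"], df["cell"]]).map(thresh)
    outlier = keep & (rt > np.asarray(cutoffs, dtype=float))

    dropped = pd.DataFrame({
        "row": np.flatnonzero(too_fast | outlier),
        "subject": log.loc[too_fast | outlier, "subject"].to_numpy(),
        "reason": np.where(too_fast[too_fast | outlier], "rt_too_fast",
                           "rt_outlier"),
    })
    trimmed = log[~(too_fast | outlier)].reset_index(drop=True)
    report = ExclusionReport(
        subject_conditions=pd.DataFrame(
            columns=["subject", "paradigm", "cell", "error_rate",
                     "excluded", "reason"]),
        trials=dropped, warnings=warnings)
    return trimmed, report


def drop_error_trials_for_rt(log: pd.DataFrame) -> pd.DataFrame:
    """Correct trials only (for RT analyses); the input is left untouched."""
    return log[log["accuracy"] == 1].reset_index(drop=True)


def apply_subject_exclusions(log: pd.DataFrame) -> ExclusionReport:
    """Condition-wise error-rate rule plus the never-switched rule.

    Error rates come from the untrimmed log (trial-level RT drops never
    affect them).
    """
    cell = condition_cell(log)
    df = pd.DataFrame({
        "subject": log["subject"].to_numpy(),
        "paradigm": log["paradigm"].astype(str).to_numpy(),
        "cell": cell.to_numpy(),
        "error": 1 - log["accuracy"].to_numpy(),
    })
    er = (df.groupby(["subject", "paradigm", "cell"], as_index=False)["error"]
          .mean().rename(columns={"error": "error_rate"}))
    er["excluded"] = er["error_rate"] > MAX_ERROR_RATE
    er["reason"] = np.where(er["excluded"], "high_error_rate", "none")

    fb = log[log["paradigm"].astype(str) == "feedback"]
    if len(fb):
        responded = fb[fb["response_hand"].astype(str) != "none"]
        n_hands = responded.groupby("subject")["response_hand"].nunique()
        never = set(n_hands[n_hands < 2].index)
        mask = (er["paradigm"] == "feedback") & er["subject"].isin(never)
        er.loc[mask, ["excluded", "reason"]] = [True, "never_switched"]
    return ExclusionReport(subject_conditions=er,
                           trials=pd.DataFrame(columns=["row", "subject",
                                                        "reason"]))


@dataclass
class PreprocessResult:
    """Everything downstream index computation needs."""

    full_log: pd.DataFrame     # untrimmed, all trials (ER analyses)
    rt_log: pd.DataFrame       # floor+outlier trimmed, correct trials only
    exclusions: ExclusionReport
    trim_report: ExclusionReport


def preprocess(log: pd.DataFrame) -> PreprocessResult:
    """Run the full exclusion pipeline in the study's order."""
    trimmed, trim_report = trim_rts(log)
    rt_log = drop_error_trials_for_rt(trimmed)
    exclusions = apply_subject_exclusions(log)
    return PreprocessResult(full_log=log.reset_index(drop=True),
                            rt_log=rt_log, exclusions=exclusions,
                            trim_report=trim_report)
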