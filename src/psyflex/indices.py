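"""Per-subject flexibility indices.

Five primary indices (plus the accuracy-based switch costs):

* ``sc_rt_cog`` / ``sc_er_cog`` -- cognitive switch costs: mean(switch) -
  mean(baseline), RT on trimmed correct trials, ER on all trials.
* ``switch_rate`` -- spontaneous switch rate: hand switches in ambiguous
  trials / ambiguous trials responded to.
* ``sc_rt_aff_emotion`` / ``sc_rt_aff_gender`` (and ER analogues) --
  direction-specific affective switch costs, using repetition trials of the
  *target* task as baseline.
* ``reversal_errors`` -- mean number of consecutive errors after each rule
  reversal, counted until the first response consistent with the new rule.

An index is missing (NaN) whenever one of its condition cells was excluded
for that subject, or the cell is empty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import PreprocessResult, condition_cell

INDEX_COLUMNS = ["sc_rt_cog", "sc_er_cog", "switch_rate",
                 "sc_rt_aff_emotion", "sc_rt_aff_gender",
                 "sc_er_aff_emotion", "sc_er_aff_gender",
                 "reversal_errors"]

#: index -> condition cells whose exclusion voids it
INDEX_CELLS = {
    "sc_rt_cog": ("baseline", "switch"),
    "sc_er_cog": ("baseline", "switch"),
    "switch_rate": ("ambiguous",),
    "sc_rt_aff_emotion": ("emotion_repeat", "emotion_switch"),
    "sc_er_aff_emotion": ("emotion_repeat", "emotion_switch"),
    "sc_rt_aff_gender": ("gender_repeat", "gender_switch"),
    "sc_er_aff_gender": ("gender_repeat", "gender_switch"),
    "reversal_errors": ("feedback",),
}


def _cell_means(log: pd.DataFrame, value: np.ndarray) -> pd.DataFrame:
    cells = condition_cell(log)
    df = pd.DataFrame({"subject": log["subject"].to_numpy(),
                       "cell": cells.to_numpy(), "value": value})
    g = df.groupby(["subject", "cell"])["value"]
    out = g.agg(["mean", "count"])
    return out


def _cost(means: pd.DataFrame, subject: int, switch_cell: str,
          base_cell: str) -> tuple[float, int]:
    try:
        sw = means.loc[(subject, switch_cell)]
        ba = means.loc[(subject, base_cell)]
    except KeyError:
        return np.nan, 0
    if sw["count"] == 0 or ba["count"] == 0:
        return np.nan, 0
    return float(sw["mean"] - ba["mean"]), int(sw["count"] + ba["count"])


def spontaneous_switch_rate(log: pd.DataFrame) -> pd.Series:
    """Hand switches in ambiguous trials / ambiguous trials responded to.

    Non-responses (omissions) leave both numerator and denominator.
    """
    amb = log[(log["paradigm"].astype(str) == "cognitive")
              & (log["condition"].astype(str) == "ambiguous")]
    amb = amb[amb["response_hand"].astype(str) != "none"]
    if not len(amb):
        return pd.Series(dtype=float, name="switch_rate")
    switched = (amb["response_hand"].astype(str) == "right").astype(float)
    out = switched.groupby(amb["subject"].to_numpy()).mean()
    out.name = "switch_rate"
    return out


def reversal_error_counts(log: pd.DataFrame) -> dict[int, list[int]]:
    """Per subject, the list of per-reversal error counts.

    For each reversal, errors are counted from the first post-reversal trial
    until the first response consistent with the new rule (exclusive).
    """
    fb = log[log["paradigm"].astype(str) == "feedback"]
    out: dict[int, list[int]] = {}
    for subject, sub in fb.groupby("subject"):
        acc = sub["accuracy"].to_numpy()
        conds = sub["condition"].astype(str).to_numpy()
        starts = np.flatnonzero(conds == "reversal_first")
        counts = []
        for s in starts:
            c = 0
            i = s
            while i < len(acc) and acc[i] == 0:
                c += 1
                i += 1
            counts.append(c)
        out[int(subject)] = counts
    return out


def mean_reversal_errors(log: pd.DataFrame) -> pd.Series:
    """Mean per-reversal error count per subject."""
    counts = reversal_error_counts(log)
    out = pd.Series({s: float(np.mean(c)) if c else np.nan
                     for s, c in counts.items()}, dtype=float)
    out.name = "reversal_errors"
    return out


def cognitive_switch_costs(pre: PreprocessResult) -> pd.DataFrame:
    """RT and ER switch costs (switch minus baseline) per subject."""
    return _paradigm_costs(pre, "cognitive",
                           {"sc_rt_cog": ("switch", "baseline")},
                           {"sc_er_cog": ("switch", "baseline")})


def affective_switch_costs(pre: PreprocessResult) -> pd.DataFrame:
    """Direction-specific affective switch costs per subject."""
    return _paradigm_costs(
        pre, "affective",
        {"sc_rt_aff_emotion": ("emotion_switch", "emotion_repeat"),
         "sc_rt_aff_gender": ("gender_switch", "gender_repeat")},
        {"sc_er_aff_emotion": ("emotion_switch", "emotion_repeat"),
         "sc_er_aff_gender": ("gender_switch", "gender_repeat")})


def _paradigm_costs(pre: PreprocessResult, paradigm: str,
                    rt_defs: dict, er_defs: dict) -> pd.DataFrame:
    rt_par = pre.rt_log[pre.rt_log["paradigm"].astype(str) == paradigm]
    er_par = pre.full_log[pre.full_log["paradigm"].astype(str) == paradigm]
    subjects = sorted(pre.full_log["subject"].unique())
    rt_means = _cell_means(rt_par, rt_par["rt"].to_numpy(dtype=float))
    er_means = _cell_means(er_par, 1.0 - er_par["accuracy"].to_numpy(dtype=float))
    rows = {}
    for s in subjects:
        row = {}
        for name, (sw, ba) in rt_defs.items():
            row[name], row[f"n_{name}"] = _cost(rt_means, s, sw, ba)
        for name, (sw, ba) in er_defs.items():
            row[name], row[f"n_{name}"] = _cost(er_means, s, sw, ba)
        rows[s] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def compute_indices(pre: PreprocessResult) -> pd.DataFrame:
    """The full per-subject index table, with exclusions applied.

    Indexed by subject; contains the eight indices, their contributing-trial
    counts (``n_*``), and NaN wherever an involved condition cell was
    excluded or empty.
    """
    subjects = sorted(pre.full_log["subject"].unique())
    table = pd.DataFrame(index=pd.Index(subjects, name="subject"))
    cog = cognitive_switch_costs(pre)
    aff = affective_switch_costs(pre)
    table = table.join(cog).join(aff)

    sw = spontaneous_switch_rate(pre.full_log)
    amb = pre.full_log[(pre.full_log["paradigm"].astype(str) == "cognitive")
                       & (pre.full_log["condition"].astype(str) == "ambiguous")]
    n_amb = amb[amb["response_hand"].astype(str) != "none"].groupby("subject").size()
    table["switch_rate"] = sw
    table["n_switch_rate"] = (n_amb.astype(float).reindex(table.index)
                              .fillna(0.0).astype(int))

    rev = mean_reversal_errors(pre.full_log)
    counts = reversal_error_counts(pre.full_log)
    table["reversal_errors"] = rev
    table["n_reversal_errors"] = (
        pd.Series({s: len(c) for s, c in counts.items()}, dtype=float)
        .reindex(table.index).fillna(0.0).astype(int))

    excluded = pre.exclusions.excluded_cells()
    for name, cells in INDEX_CELLS.items():
        if name not in table.columns:
            continue
        for s in table.index:
            if any((int(s), cell) in excluded for cell in cells):
                table.loc[s, name] = np.nan
    return table[INDEX_COLUMNS + [f"n_{c}" for c in INDEX_COLUMNS]]
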