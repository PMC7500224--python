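"""Split-half internal-consistency estimators.

Three procedures, mirroring how each index can be halved:

``permutation_split_half``
    For trial-based indices (switch costs): in each of ``n_iterations``
    random splits, every subject's trials in each involved condition are
    halved, the index is computed per half, and the across-subject Pearson
    correlation between halves gives one split-half coefficient. The
    Spearman-Brown correction ``2r / (1 + r)`` is applied per iteration;
    estimates and percentile CIs aggregate the iteration distribution.

``reversal_split_half``
    For the feedback paradigm: each subject's list of per-reversal error
    counts is shuffled, split, and the half means correlated across
    subjects; otherwise identical machinery.

``half_vs_half_switch_rate``
    For the spontaneous switch rate, random splits of binary switch/stay
    trials are degenerate (complementary halves push the estimate towards 1
    regardless of the true reliability), so the number of switch responses
    in the first half of ambiguous trials is correlated with the number in
    the second half, once, in presentation order; no Spearman-Brown
    correction, Fisher-z CI.

Odd trial counts put the extra trial into split 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .indices import INDEX_CELLS, reversal_error_counts
from .preprocess import PreprocessResult

DEFAULT_ITERATIONS = 5000


def spearman_brown(r: float) -> float:
    """Project a half-length reliability to full length: 2r / (1 + r)."""
    if r <= -1.0:
        raise ConfigurationError("Spearman-Brown correction undefined at r = -1")
    return 2.0 * r / (1.0 + r)


@dataclass
class ReliabilityEstimate:
    """Split-half coefficient with optional Spearman-Brown correction."""

    method: str
    r_uncorrected: float
    r_sb: float | None
    ci95: tuple[float, float]
    ci95_sb: tuple[float, float] | None
    n_iterations: int
    n_subjects: int
    warnings: list[str] = field(default_factory=list)


def _half_means(rng: np.random.Generator, values: np.ndarray,
                n_iterations: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-iteration means of the two random halves of ``values``.

    Returns two ``(n_iterations,)`` arrays. The random halving is a uniform
    permutation whose first ``ceil(L/2)`` entries form split 1.
    """
    L = len(values)
    h = (L + 1) // 2
    order = np.argsort(rng.random((n_iterations, L)), axis=1)
    shuffled = values[order]
    return shuffled[:, :h].mean(axis=1), shuffled[:, h:].mean(axis=1)


def _iterate_correlations(split1: np.ndarray, split2: np.ndarray,
                          warnings: list[str]) -> np.ndarray:
    """Pearson r per iteration between the subject-wise half indices.

    ``split1``/``split2`` are ``(n_iterations, n_subjects)``. Iterations in
    which either half has zero across-subject variance are skipped.
    """
    s1 = split1 - split1.mean(axis=1, keepdims=True)
    s2 = split2 - split2.mean(axis=1, keepdims=True)
    v1 = (s1 ** 2).sum(axis=1)
    v2 = (s2 ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s1 * s2).sum(axis=1) / np.sqrt(v1 * v2)
    bad = ~np.isfinite(r)
    if bad.any():
        warnings.append(f"{int(bad.sum())} iteration(s) skipped: zero "
                        "between-subject variance in a half")
    return r[~bad]


def _aggregate(r_iter: np.ndarray, method: str, n_iterations: int,
               n_subjects: int, warnings: list[str],
               correct: bool = True) -> ReliabilityEstimate:
    if not len(r_iter):
        raise ConfigurationError("no valid split-half iterations")
    sb = np.array([spearman_brown(r) for r in r_iter]) if correct else None
    return ReliabilityEstimate(
        method=method,
        r_uncorrected=float(r_iter.mean()),
        r_sb=float(sb.mean()) if correct else None,
        ci95=(float(np.percentile(r_iter, 2.5)),
              float(np.percentile(r_iter, 97.5))),
        ci95_sb=((float(np.percentile(sb, 2.5)),
                  float(np.percentile(sb, 97.5))) if correct else None),
        n_iterations=n_iterations,
        n_subjects=n_subjects,
        warnings=warnings,
    )


def permutation_split_half(subject_values: dict[int, tuple[np.ndarray, ...]],
                           n_iterations: int = DEFAULT_ITERATIONS,
                           seed: int | None = None,
                           signs: tuple[int, ...] = (1, -1),
                           method: str = "perm_split") -> ReliabilityEstimate:
    """Permutation-based split-half reliability of a trial-level index.

    ``subject_values`` maps subject -> tuple of per-condition trial value
    arrays; the half index is ``sum(sign_k * mean(half of array_k))`` (for a
    switch cost: ``(+1, -1)`` over (switch, baseline) trials). Subjects with
    any involved condition holding fewer than 2 trials are dropped with a
    warning.
    """
    rng = np.random.default_rng(seed)
    warnings: list[str] = []
    kept: list[int] = []
    halves1 = []
    halves2 = []
    for subject in sorted(subject_values):
        arrays = subject_values[subject]
        if any(len(a) < 2 for a in arrays):
            warnings.append(f"subject {subject} dropped: a condition has "
                            "fewer than 2 trials")
            continue
        h1 = np.zeros(n_iterations)
        h2 = np.zeros(n_iterations)
        for sign, arr in zip(signs, arrays):
            m1, m2 = _half_means(rng, np.asarray(arr, dtype=float), n_iterations)
            h1 += sign * m1
            h2 += sign * m2
        kept.append(subject)
        halves1.append(h1)
        halves2.append(h2)
    if len(kept) < 2:
        raise ConfigurationError("need at least 2 subjects with splittable data")
    split1 = np.column_stack(halves1)
    split2 = np.column_stack(halves2)
    r_iter = _iterate_correlations(split1, split2, warnings)
    return _aggregate(r_iter, method, n_iterations, len(kept), warnings)


def reversal_split_half(error_lists: dict[int, list[int]],
                        n_iterations: int = DEFAULT_ITERATIONS,
                        seed: int | None = None) -> ReliabilityEstimate:
    """Shuffle-split reliability of per-reversal error counts.

    Each subject's equal-length list is shuffled and split; half means are
    correlated across subjects per iteration, Spearman-Brown corrected, and
    aggregated with percentile CIs.
    """
    lengths = {len(v) for v in error_lists.values()}
    if len(lengths) > 1:
        raise ConfigurationError(
            f"per-reversal lists must have equal length, got {sorted(lengths)}")
    if len(error_lists) < 3:
        raise ConfigurationError("need at least 3 subjects")
    values = {s: (np.asarray(v, dtype=float),) for s, v in error_lists.items()}
    return permutation_split_half(values, n_iterations=n_iterations,
                                  seed=seed, signs=(1,),
                                  method="reversal_shuffle_split")


def half_vs_half_switch_rate(log: pd.DataFrame) -> ReliabilityEstimate:
    """First-half vs second-half switch counts in ambiguous trials.

    A deterministic (non-permutation) estimate: ambiguous trials are taken
    in presentation order, switch responses counted per half, and the counts
    correlated across subjects. No Spearman-Brown correction is reported;
    the CI is a Fisher-z interval.
    """
    warnings: list[str] = []
    amb = log[(log["paradigm"].astype(str) == "cognitive")
              & (log["condition"].astype(str) == "ambiguous")]
    amb = amb[amb["response_hand"].astype(str) != "none"]
    first = {}
    second = {}
    for subject, sub in amb.groupby("subject"):
        switched = (sub["response_hand"].astype(str) == "right").to_numpy(int)
        h = (len(switched) + 1) // 2
        first[subject] = switched[:h].sum()
        second[subject] = switched[h:].sum()
    subjects = sorted(first)
    n = len(subjects)
    if n < 2:
        raise ConfigurationError("need at least 2 subjects with ambiguous trials")
    x = np.array([first[s] for s in subjects], dtype=float)
    y = np.array([second[s] for s in subjects], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return ReliabilityEstimate("half_vs_half", np.nan, None,
                                   (np.nan, np.nan), None, 1, n,
                                   ["zero variance in a half-count vector"])
    r = float(np.corrcoef(x, y)[0, 1])
    if n == 2:
        warnings.append("two subjects only: correlation is degenerate (+/-1)")
        ci = (np.nan, np.nan)
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        ci = (float(np.tanh(z - 1.959964 * se)),
              float(np.tanh(z + 1.959964 * se)))
    return ReliabilityEstimate("half_vs_half", r, None, ci, None, 1, n,
                               warnings)


# ---------------------------------------------------------------------------
# Wrappers from preprocessed logs

_RT_INDICES = {"sc_rt_cog", "sc_rt_aff_emotion", "sc_rt_aff_gender"}
_ER_INDICES = {"sc_er_cog", "sc_er_aff_emotion", "sc_er_aff_gender"}


def _paradigm_of(index: str) -> str:
    return "cognitive" if index.endswith("_cog") else "affective"


def split_half_from_log(pre: PreprocessResult, index: str,
                        n_iterations: int = DEFAULT_ITERATIONS,
                        seed: int | None = None) -> ReliabilityEstimate:
    """Dispatch a named index to its split-half procedure.

    Switch costs use the permutation procedure (RT costs on trimmed correct
    trials, ER costs on all trials); ``reversal_errors`` uses the shuffle
    split of per-reversal counts; ``switch_rate`` uses the deterministic
    half-vs-half counts.
    """
    excluded = pre.exclusions.excluded_cells()
    if index == "switch_rate":
        keep = ~pre.full_log["subject"].map(
            lambda s: (int(s), "ambiguous") in excluded)
        return half_vs_half_switch_rate(pre.full_log[keep])
    if index == "reversal_errors":
        lists = reversal_error_counts(pre.full_log)
        lists = {s: v for s, v in lists.items()
                 if (s, "feedback") not in excluded}
        return reversal_split_half(lists, n_iterations=n_iterations, seed=seed)
    if index in _RT_INDICES:
        log = pre.rt_log
        value = log["rt"].to_numpy(dtype=float)
    elif index in _ER_INDICES:
        log = pre.full_log
        value = 1.0 - log["accuracy"].to_numpy(dtype=float)
    else:
        raise ConfigurationError(f"unknown index {index!r}")
    switch_cell, base_cell = INDEX_CELLS[index]
    from .preprocess import condition_cell
    paradigm = _paradigm_of(index)
    mask = (log["paradigm"].astype(str) == paradigm).to_numpy()
    cells = condition_cell(log).to_numpy()
    subjects = log["subject"].to_numpy()
    subject_values = {}
    for s in np.unique(subjects):
        if (int(s), switch_cell) in excluded or (int(s), base_cell) in excluded:
            continue
        sw = value[mask & (subjects == s) & (cells == switch_cell)]
        ba = value[mask & (subjects == s) & (cells == base_cell)]
        subject_values[int(s)] = (sw, ba)
    return permutation_split_half(subject_values, n_iterations=n_iterations,
                                  seed=seed, signs=(1, -1))


def reliability_table(pre: PreprocessResult,
                      n_iterations: int = DEFAULT_ITERATIONS,
                      seed: int | None = None) -> pd.DataFrame:
    """Reliability of every study index, one row per index."""
    rows = []
    for index in ("sc_rt_cog", "sc_er_cog", "switch_rate",
                  "sc_rt_aff_emotion", "sc_rt_aff_gender",
                  "sc_er_aff_emotion", "sc_er_aff_gender",
                  "reversal_errors"):
        est = split_half_from_log(pre, index, n_iterations=n_iterations,
                                  seed=seed)
        rows.append({
            "index": index, "method": est.method, "n": est.n_subjects,
            "r": est.r_uncorrected,
            "ci_low": est.ci95[0], "ci_high": est.ci95[1],
            "r_sb": est.r_sb,
            "sb_ci_low": est.ci95_sb[0] if est.ci95_sb else np.nan,
            "sb_ci_high": est.ci95_sb[1] if est.ci95_sb else np.nan,
        })
    return pd.DataFrame(rows).set_index("index")
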