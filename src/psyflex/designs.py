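"""Constraint-satisfying trial-sequence generators for the three paradigms.

Each generator returns a :class:`ParadigmDesign` whose ``trials`` table has one
row per trial with the columns

``run, trial, condition, rule, stimulus, cue, correct_hand, onset, iti``

``trial`` is the 0-based index within its run; the DataFrame's integer index
is the 0-based position across the whole session. ``segment_boundaries``
lists the across-session indices at which a new task segment starts (the
first trial of each affective task run, and each post-reversal trial in the
feedback paradigm).

Digits never include 5; the rule→hand mapping is fixed (parity/gender →
left, magnitude/emotion → right). The generators are deterministic given
``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DesignConfig, RULE_HAND, default_config
from .errors import DesignConstraintError

ODD_DIGITS = (1, 3, 7, 9)
EVEN_DIGITS = (2, 4, 6, 8)
LOW_DIGITS = (1, 2, 3, 4)
HIGH_DIGITS = (6, 7, 8, 9)

TRIAL_COLUMNS = ["run", "trial", "condition", "rule", "stimulus", "cue",
                 "correct_hand", "onset", "iti"]


@dataclass
class ParadigmDesign:
    """Ordered trial specifications for one subject-run of one paradigm."""

    config: DesignConfig
    trials: pd.DataFrame
    segment_boundaries: list[int]

    @property
    def paradigm(self) -> str:
        return self.config.paradigm

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


def _composition(rng: np.random.Generator, total: int, n_parts: int,
                 lo: int, hi: int, what: str) -> list[int]:
    """Sample a length-``n_parts`` composition of ``total`` with every part in
    [lo, hi], by constrained sequential sampling (each part uniform over the
    values that keep the remainder feasible)."""
    if not n_parts * lo <= total <= n_parts * hi:
        raise DesignConstraintError(
            f"{what}: cannot write {total} as {n_parts} parts in [{lo}, {hi}] "
            f"(feasible range [{n_parts * lo}, {n_parts * hi}])")
    parts: list[int] = []
    remaining = total
    for i in range(n_parts):
        rest = n_parts - i - 1
        v_lo = max(lo, remaining - rest * hi)
        v_hi = min(hi, remaining - rest * lo)
        v = int(rng.integers(v_lo, v_hi + 1))
        parts.append(v)
        remaining -= v
    return parts


def _balanced_digits(rng: np.random.Generator, n: int,
                     split_by: str) -> np.ndarray:
    """``n`` digits with the two response categories of ``split_by``
    ('parity' or 'magnitude') as balanced as possible, in random order."""
    a, b = (ODD_DIGITS, EVEN_DIGITS) if split_by == "parity" else (LOW_DIGITS, HIGH_DIGITS)
    half = n // 2
    cats = np.array([0] * half + [1] * (n - half))
    rng.shuffle(cats)
    out = np.where(cats == 0,
                   rng.choice(a, size=n),
                   rng.choice(b, size=n))
    return out


def generate_cognitive_design(config: DesignConfig | None = None,
                              seed: int | None = None) -> ParadigmDesign:
    """Oddball task-switching design: frequent single-digit parity baseline,
    rare two-digit critical trials (switch / distractor / ambiguous), each
    followed by 3-6 baseline trials.

    Under the defaults (2 runs x 150 trials, 80% baseline) every subject gets
    exactly 240 baseline trials and 20 trials per critical condition.
    """
    config = config or default_config("cognitive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.trials_per_run
    n_critical = round((1.0 - config.baseline_fraction) * T)
    if n_critical % 3 != 0:
        raise DesignConstraintError(
            f"critical trials per run ({n_critical}) must divide evenly into "
            "3 conditions; adjust baseline_fraction or trials_per_run")
    per_cond = n_critical // 3
    n_baseline = T - n_critical
    g_lo, g_hi = config.post_critical_gap
    rows = []
    boundaries: list[int] = []
    for run in range(config.n_runs):
        conditions = []
        if n_critical:
            lead_hi = min(g_hi, n_baseline - n_critical * g_lo)
            if lead_hi < 0:
                raise DesignConstraintError(
                    f"baseline budget {n_baseline} below the minimum "
                    f"{n_critical} gaps x {g_lo} trials")
            lead = int(rng.integers(0, lead_hi + 1))
            gaps = _composition(rng, n_baseline - lead, n_critical,
                                g_lo, g_hi, "cognitive post-critical gaps")
            crit = (["switch"] * per_cond + ["distractor"] * per_cond
                    + ["ambiguous"] * per_cond)
            rng.shuffle(crit)
            conditions.extend(["baseline"] * lead)
            for c, gap in zip(crit, gaps):
                conditions.append(c)
                conditions.extend(["baseline"] * gap)
        else:
            conditions = ["baseline"] * T
        conditions = np.array(conditions)
        assert len(conditions) == T
        # Single baseline digit; critical trials carry an upper and a lower
        # digit. The digit governing the correct response is balanced within
        # condition across the run.
        upper = np.empty(T, dtype=int)
        lower = np.full(T, -1, dtype=int)
        for cond, split, which in (("baseline", "parity", "upper"),
                                   ("switch", "magnitude", "lower"),
                                   ("distractor", "parity", "upper"),
                                   ("ambiguous", "parity", "upper")):
            mask = conditions == cond
            n = int(mask.sum())
            if not n:
                continue
            relevant = _balanced_digits(rng, n, split)
            other = rng.choice([d for d in range(1, 10) if d != 5], size=n)
            if which == "upper":
                upper[mask] = relevant
                if cond != "baseline":
                    lower[mask] = other
            else:
                lower[mask] = relevant
                upper[mask] = other
        rule = np.where(conditions == "switch", "magnitude", "parity")
        cue = np.select(
            [conditions == "baseline", conditions == "distractor",
             conditions == "switch", conditions == "ambiguous"],
            ["upper", "upper", "lower", "ambiguous"], default="upper")
        stim = np.where(lower < 0,
                        upper.astype(str),
                        np.char.add(np.char.add(upper.astype(str), "|"),
                                    lower.astype(str)))
        for t in range(T):
            rows.append((run, t, conditions[t], rule[t], stim[t], cue[t],
                         RULE_HAND[rule[t]], t * config.trial_duration, 0))
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return ParadigmDesign(config=config, trials=trials,
                          segment_boundaries=boundaries)


def _affective_segment_counts(total: int, lo: int, hi: int) -> tuple[int, int]:
    """Numbers of task segments (starting task, other task) alternating
    through ``total`` trials with each task receiving ``total/2`` trials in
    segments of length [lo, hi]. Falls back to a single segment when no
    alternating composition exists."""
    if lo <= total <= hi:
        single_ok = True
    else:
        single_ok = False
    if total % 2 == 0:
        half = total // 2
        target = round(2 * total / (lo + hi) / 2)  # segments per task, rough
        candidates = sorted(range(1, half // lo + 1),
                            key=lambda k: abs(k - target))
        for kb in candidates:
            ka = kb + 1
            if kb * lo <= half <= kb * hi and ka * lo <= half <= ka * hi:
                return ka, kb
    if single_ok:
        return 1, 0
    raise DesignConstraintError(
        f"affective run of {total} trials admits no alternating composition "
        f"with segment lengths in [{lo}, {hi}]")


def generate_affective_design(config: DesignConfig | None = None,
                              seed: int | None = None) -> ParadigmDesign:
    """Position-cued gender/emotion switching design.

    Tasks alternate in segments of 3-7 trials; the first trial of every
    segment after the first is a switch trial. Under the defaults each task
    contributes 24 switch and 96 repeat trials (240 total). Stimuli are face
    descriptors from a pool of 120 identities x 2 valences, each used once.
    """
    config = config or default_config("affective")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.trials_per_run * config.n_runs
    lo, hi = config.run_length_interval
    ka, kb = _affective_segment_counts(T, lo, hi)
    tasks = ["gender", "emotion"]
    rng.shuffle(tasks)
    if kb == 0:
        lengths = [T]
    else:
        lens_a = _composition(rng, T // 2, ka, lo, hi, "affective segments (first task)")
        lens_b = _composition(rng, T // 2, kb, lo, hi, "affective segments (second task)")
        lengths = [x for pair in zip(lens_a, lens_b + [0]) for x in pair if x]
    seg_task = [tasks[i % 2] for i in range(len(lengths))]
    # face pool: identities 1-60 female, 61-120 male; two valences each
    ids = np.arange(1, 121)
    pool = [f"face{i:03d}_{v}" for i in ids for v in ("happy", "angry")]
    pool = list(rng.permutation(pool))
    if T > len(pool):
        pool = list(rng.permutation(pool * (T // len(pool) + 1)))
    rows = []
    boundaries = []
    pos = 0
    for s, (task, length) in enumerate(zip(seg_task, lengths)):
        if s > 0:
            boundaries.append(pos)
        for i in range(length):
            cond = "switch" if (s > 0 and i == 0) else "repeat"
            stim = pool[pos]
            cue = "above" if task == "gender" else "below"
            run = pos // config.trials_per_run
            t_in_run = pos % config.trials_per_run
            rows.append((run, t_in_run, cond, task, stim, cue,
                         RULE_HAND[task], t_in_run * config.trial_duration, 0))
            pos += 1
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return ParadigmDesign(config=config, trials=trials,
                          segment_boundaries=boundaries)


def _prob_error_positions(length: int) -> list[int]:
    """Eligible within-segment positions (0-based) for a probabilistic
    error: never the first four trials after a reversal, never the last
    trial before the next reversal; length-6 segments have no eligible
    position (their single candidate is excluded by design)."""
    if length <= 6:
        return []
    return list(range(4, length - 1))


def generate_feedback_design(config: DesignConfig | None = None,
                             seed: int | None = None) -> ParadigmDesign:
    """Feedback-driven rule-reversal design.

    Segments of 6-15 same-rule trials separated by uninstructed reversals;
    20% of segments long enough to admit one (length >= 7) contain a single
    probabilistic error at an allowed position. Defaults: 109 trials, 10
    reversals.
    """
    config = config or default_config("feedback")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.trials_per_run * config.n_runs
    n_seg = config.n_reversals + 1
    lo, hi = config.inter_reversal_interval
    lengths = _composition(rng, T, n_seg, lo, hi, "feedback inter-reversal segments")
    eligible = [i for i, L in enumerate(lengths) if _prob_error_positions(L)]
    n_pe = round(config.prob_error_fraction * len(eligible))
    pe_segments = rng.choice(eligible, size=n_pe, replace=False) if n_pe else []
    pe_pos = {}
    for s in pe_segments:
        pe_pos[int(s)] = int(rng.choice(_prob_error_positions(lengths[s])))
    rules = ["parity", "magnitude"]
    rng.shuffle(rules)
    digits = _balanced_digits(rng, T, "parity")
    itis = rng.integers(config.iti_interval[0], config.iti_interval[1] + 1, size=T)
    rows = []
    boundaries = []
    pos = 0
    onset = 0
    for s, length in enumerate(lengths):
        rule = rules[s % 2]
        if s > 0:
            boundaries.append(pos)
        for i in range(length):
            if s > 0 and i == 0:
                cond = "reversal_first"
            elif pe_pos.get(s) == i:
                cond = "prob_error"
            else:
                cond = "standard"
            rows.append((0, pos, cond, rule, str(digits[pos]), "none",
                         RULE_HAND[rule], onset, int(itis[pos])))
            onset += config.trial_duration + int(itis[pos])
            pos += 1
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return ParadigmDesign(config=config, trials=trials,
                          segment_boundaries=boundaries)


_GENERATORS = {
    "cognitive": generate_cognitive_design,
    "affective": generate_affective_design,
    "feedback": generate_feedback_design,
}


def generate_design(paradigm: str, config: DesignConfig | None = None,
                    seed: int | None = None) -> ParadigmDesign:
    """Dispatch to the paradigm-specific generator."""
    return _GENERATORS[paradigm](config, seed)


def segment_lengths(design: ParadigmDesign) -> list[int]:
    """Lengths of the task segments delimited by ``segment_boundaries``."""
    edges = [0] + list(design.segment_boundaries) + [len(design)]
    return [b - a for a, b in zip(edges[:-1], edges[1:])]


def validate_design(design: ParadigmDesign) -> list[CheckResult]:
    """Run every design-count and placement invariant for the paradigm.

    Failures come back as report entries, never exceptions, so the function
    can audit hand-edited or imported designs.
    """
    checks: list[CheckResult] = []
    t = design.trials
    cfg = design.config

    def add(name: str, ok: bool, detail: str = "") -> None:
        checks.append(CheckResult(name, bool(ok), detail))

    if cfg.paradigm == "cognitive":
        counts = t["condition"].value_counts()
        T = cfg.trials_per_run
        n_crit = round((1 - cfg.baseline_fraction) * T) * cfg.n_runs
        n_base = T * cfg.n_runs - n_crit
        add("baseline_count", counts.get("baseline", 0) == n_base,
            f"expected {n_base}, got {counts.get('baseline', 0)}")
        for cond in ("switch", "distractor", "ambiguous"):
            add(f"{cond}_count", counts.get(cond, 0) == n_crit // 3,
                f"expected {n_crit // 3}, got {counts.get(cond, 0)}")
        add("trials_per_run",
            (t.groupby("run").size() == T).all(), "")
        g_lo, g_hi = cfg.post_critical_gap
        ok = True
        bad = ""
        for run, sub in t.groupby("run"):
            crit_idx = np.flatnonzero((sub["condition"] != "baseline").to_numpy())
            nxt = np.append(crit_idx[1:], len(sub))
            gaps = nxt - crit_idx - 1
            if len(gaps) and not ((gaps >= g_lo) & (gaps <= g_hi)).all():
                ok = False
                bad = f"run {run} gaps {sorted(set(gaps.tolist()))}"
        add("post_critical_gap", ok, bad)
        add("digit_never_5",
            not t["stimulus"].str.contains("5").any(), "")
        add("baseline_rule_parity",
            (t.loc[t["condition"] == "baseline", "rule"] == "parity").all(), "")
    elif cfg.paradigm == "affective":
        T = cfg.trials_per_run * cfg.n_runs
        add("total_trials", len(t) == T, f"expected {T}, got {len(t)}")
        seg_starts = [0] + list(design.segment_boundaries)
        for task in ("gender", "emotion"):
            sub = t[t["rule"] == task]
            n_sw = int((sub["condition"] == "switch").sum())
            expected_sw = sum(1 for b in design.segment_boundaries
                              if t["rule"].iloc[b] == task)
            add(f"{task}_switch_count", n_sw == expected_sw,
                f"expected {expected_sw}, got {n_sw}")
        lens = segment_lengths(design)
        add("segment_lengths_in_interval",
            all(cfg.run_length_interval[0] <= L <= cfg.run_length_interval[1]
                for L in lens) or len(lens) == 1,
            f"lengths {sorted(set(lens))}")
        seg_tasks = [t["rule"].iloc[b] for b in seg_starts]
        add("tasks_alternate",
            all(a != b for a, b in zip(seg_tasks[:-1], seg_tasks[1:])), "")
        sw_idx = t.index[t["condition"] == "switch"]
        add("switch_trials_open_segments",
            set(sw_idx) == set(design.segment_boundaries),
            "switch trials must be exactly the segment-opening trials")
    else:  # feedback
        T = cfg.trials_per_run * cfg.n_runs
        add("total_trials", len(t) == T, f"expected {T}, got {len(t)}")
        add("n_reversals",
            len(design.segment_boundaries) == cfg.n_reversals,
            f"expected {cfg.n_reversals}, got {len(design.segment_boundaries)}")
        lens = segment_lengths(design)
        lo, hi = cfg.inter_reversal_interval
        add("segment_lengths_in_interval",
            all(lo <= L <= hi for L in lens), f"lengths {sorted(set(lens))}")
        edges = [0] + list(design.segment_boundaries) + [len(t)]
        ok = True
        bad = ""
        n_pe_segments = 0
        n_eligible = 0
        for a, b in zip(edges[:-1], edges[1:]):
            seg = t.iloc[a:b]
            if _prob_error_positions(b - a):
                n_eligible += 1
            pe = np.flatnonzero((seg["condition"] == "prob_error").to_numpy())
            if len(pe) > 1:
                ok = False
                bad = f"segment at {a} has {len(pe)} probabilistic errors"
            if len(pe):
                n_pe_segments += 1
                allowed = _prob_error_positions(b - a)
                if pe[0] not in allowed:
                    ok = False
                    bad = (f"probabilistic error at within-segment position "
                           f"{pe[0]} of a length-{b - a} segment")
        add("prob_error_placement", ok, bad)
        add("prob_error_count",
            n_pe_segments == round(cfg.prob_error_fraction * n_eligible),
            f"expected {round(cfg.prob_error_fraction * n_eligible)}, "
            f"got {n_pe_segments}")
        rules = [t["rule"].iloc[e] for e in edges[:-1]]
        add("rules_alternate",
            all(a != b for a, b in zip(rules[:-1], rules[1:])), "")
        add("itis_in_interval",
            t["iti"].between(*cfg.iti_interval).all(), "")
    return checks
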