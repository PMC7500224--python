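"""Trial-level behavior generation for synthetic participants.

Generative model (an explicit stand-in -- the source study fitted no
trial-level model):

* RTs are log-normal around a subject/condition mean ``mu``:
  ``rt = mu * exp(sigma * z - sigma**2 / 2)`` so the expected RT equals
  ``mu``. Draws beyond the response window become omissions (no response,
  counted as errors, missing RT) in the cue-based paradigms and are clipped
  to the window in the feedback paradigm (whose state machine needs a
  response every trial).
* Accuracy is Bernoulli(1 - error_prob(condition)); a lapse (probability
  ``lapse_rate``) replaces the response with a random hand.
* Ambiguous trials: the subject responds with the switch-task hand with
  probability ``theta`` (the spontaneous switch propensity); accuracy is
  Bernoulli within the chosen task.
* Feedback paradigm: a two-state win-stay/lose-shift rule follower. After
  negative feedback the internal rule switches with probability ``q``
  (``perseveration`` is the stay probability on the first error after a
  reversal); positive feedback never triggers a switch. A probabilistic
  error (negative feedback after a correct response) can trigger an
  unwarranted switch with probability ``q``, after which the next negative
  feedback restores the correct rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import DesignConfig, default_configs
from .designs import ParadigmDesign, generate_design
from .population import ParticipantParams, PopulationModel, sample_population

LOG_COLUMNS = ["subject", "paradigm", "run", "trial", "condition", "rule",
               "correct_hand", "response_hand", "accuracy", "rt", "feedback"]

_OTHER_HAND = {"left": "right", "right": "left"}

#: number of pre-generated pseudo-random sequence variants per paradigm
N_SEQUENCE_VARIANTS = 4


def _cued_paradigm_arrays(params: ParticipantParams, design: ParadigmDesign,
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorized simulation of one cognitive or affective session."""
    t = design.trials
    paradigm = design.paradigm
    n = len(t)
    conditions = t["condition"].to_numpy()
    rules = t["rule"].to_numpy()
    correct_hand = t["correct_hand"].to_numpy()
    window = design.config.response_window

    # subject/condition mean RT per trial
    mu = np.empty(n)
    for cond in np.unique(conditions):
        for rule in np.unique(rules):
            m = (conditions == cond) & (rules == rule)
            if m.any():
                mu[m] = params.rt_mean(paradigm, cond, rule)
    sigma = params.rt_noise
    rt = mu * np.exp(sigma * rng.standard_normal(n) - sigma * sigma / 2.0)
    omitted = (rt > window) | (rng.random(n) < params.omission_rate)

    err = params.error_probs
    key = ("cog_" if paradigm == "cognitive" else "aff_")
    p_err = np.empty(n)
    for cond in np.unique(conditions):
        for rule in np.unique(rules):
            m = (conditions == cond) & (rules == rule)
            if not m.any():
                continue
            if paradigm == "cognitive":
                p_err[m] = err[key + cond]
            else:
                p_err[m] = err[f"{key}{rule}_{cond}"]
    correct = rng.random(n) >= p_err

    response = np.where(correct, correct_hand,
                        np.vectorize(_OTHER_HAND.get)(correct_hand))
    if paradigm == "cognitive":
        amb = conditions == "ambiguous"
        if amb.any():
            switch_hand = rng.random(n) < params.theta
            response = np.where(amb & switch_hand, "right",
                                np.where(amb, "left", response))
    lapse = rng.random(n) < params.lapse_rate
    if lapse.any():
        rand_hand = np.where(rng.random(n) < 0.5, "left", "right")
        response = np.where(lapse, rand_hand, response)
        correct = np.where(lapse, rand_hand == correct_hand, correct)

    accuracy = correct.astype(np.int8)
    accuracy[omitted] = 0
    rt = np.where(omitted, np.nan, rt)
    response = response.astype(object)
    response[omitted] = "none"
    return {
        "paradigm": np.repeat(paradigm, n),
        "run": t["run"].to_numpy(),
        "trial": t["trial"].to_numpy(),
        "condition": conditions,
        "rule": rules,
        "correct_hand": correct_hand,
        "response_hand": response.astype("U5"),
        "accuracy": accuracy,
        "rt": rt,
        "feedback": np.repeat("none", n),
    }


def _feedback_arrays(params: ParticipantParams, design: ParadigmDesign,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sequential simulation of the feedback-driven reversal session."""
    t = design.trials
    n = len(t)
    conditions = t["condition"].to_numpy()
    correct_hand = t["correct_hand"].to_numpy()
    window = design.config.response_window

    mu = params.rt_mean("feedback", "standard", "parity")
    sigma = params.rt_noise
    rt = mu * np.exp(sigma * rng.standard_normal(n) - sigma * sigma / 2.0)
    np.clip(rt, 250.0, window, out=rt)
    lapse_draw = rng.random(n) < params.lapse_rate
    lapse_hand = np.where(rng.random(n) < 0.5, "left", "right")
    switch_draw = rng.random(n)

    q = params.lose_shift_prob
    pers = params.perseveration
    internal = correct_hand[0]          # initial rule is trained
    unwarranted = False                 # switched away after a prob. error
    pending_first_error = False         # next error is the first post-reversal
    response = np.empty(n, dtype="U5")
    accuracy = np.empty(n, dtype=np.int8)
    feedback = np.empty(n, dtype="U8")
    for i in range(n):
        if conditions[i] == "reversal_first":
            pending_first_error = True
        resp = lapse_hand[i] if lapse_draw[i] else internal
        ok = resp == correct_hand[i]
        neg = (not ok) or conditions[i] == "prob_error"
        response[i] = resp
        accuracy[i] = 1 if ok else 0
        feedback[i] = "negative" if neg else "positive"
        if not neg:
            continue  # win-stay: positive feedback never triggers a switch
        if ok:  # probabilistic error: may trigger an unwarranted switch
            if switch_draw[i] < q:
                internal = _OTHER_HAND[internal]
                unwarranted = True
            continue
        if unwarranted:
            internal = correct_hand[i]  # negative feedback restores the rule
            unwarranted = False
            continue
        p_switch = (1.0 - pers) * q if pending_first_error else q
        pending_first_error = False
        if switch_draw[i] < p_switch:
            internal = _OTHER_HAND[internal]
    return {
        "paradigm": np.repeat("feedback", n),
        "run": t["run"].to_numpy(),
        "trial": t["trial"].to_numpy(),
        "condition": conditions,
        "rule": t["rule"].to_numpy(),
        "correct_hand": correct_hand,
        "response_hand": response,
        "accuracy": accuracy,
        "rt": rt,
        "feedback": feedback,
    }


def simulate_subject(params: ParticipantParams,
                     designs: list[ParadigmDesign],
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate one subject through the given paradigm designs.

    Deterministic given ``(params, designs, seed)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    parts = []
    for design in designs:
        if design.paradigm == "feedback":
            arrays = _feedback_arrays(params, design, rng)
        else:
            arrays = _cued_paradigm_arrays(params, design, rng)
        arrays["subject"] = np.repeat(params.subject_id, len(design))
        parts.append(arrays)
    merged = {c: np.concatenate([p[c] for p in parts]) for c in LOG_COLUMNS}
    return pd.DataFrame(merged)[LOG_COLUMNS]


def study_designs(configs: dict[str, DesignConfig] | None = None
                  ) -> dict[str, list[ParadigmDesign]]:
    """The pre-generated pseudo-random sequence variants (seeds 1..4) for
    each paradigm, mirroring the study's four counterbalanced sequences."""
    configs = configs or default_configs()
    return {p: [generate_design(p, cfg, seed=s)
                for s in range(1, N_SEQUENCE_VARIANTS + 1)]
            for p, cfg in configs.items()}


def simulate_study(model: PopulationModel,
                   configs: dict[str, DesignConfig] | None = None,
                   seed: int | None = None,
                   return_params: bool = False):
    """Simulate the full study: every subject runs every paradigm.

    Each subject is assigned one of the four sequence variants per paradigm
    (round-robin) and draws behavior from an independent random stream seeded
    by ``(master seed, subject id)``, so per-subject logs do not depend on
    simulation order.
    """
    master = model.seed if seed is None else seed
    variants = study_designs(configs)
    participants = sample_population(model, seed=master)
    parts = []
    for p in participants:
        subj_designs = [variants[par][p.subject_id % N_SEQUENCE_VARIANTS]
                        for par in variants]
        rng = np.random.default_rng([master, p.subject_id])
        for design in subj_designs:
            if design.paradigm == "feedback":
                arrays = _feedback_arrays(p, design, rng)
            else:
                arrays = _cued_paradigm_arrays(p, design, rng)
            arrays["subject"] = np.repeat(p.subject_id, len(design))
            parts.append(arrays)
    merged = {c: np.concatenate([pt[c] for pt in parts]) for c in LOG_COLUMNS}
    log = pd.DataFrame(merged)[LOG_COLUMNS]
    for c in ("paradigm", "condition", "rule", "correct_hand",
              "response_hand", "feedback"):
        log[c] = log[c].astype("category")
    if return_params:
        return log, participants
    return log
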