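"""Paradigm design configurations.

Three paradigms are supported:

``cognitive``
    Cue-instructed switching between a parity (odd/even) and a magnitude
    (</> 5) judgement on digits 1-9 (excluding 5), arranged as an oddball
    design: 80% single-digit baseline trials, with rare critical trials
    (switch, distractor, ambiguous) each followed by a 3-6 trial baseline gap.
``affective``
    Position-cued switching between a gender and an emotion judgement on face
    stimuli; task runs of 3-7 trials alternate through a single 240-trial run.
``feedback``
    Uninstructed, feedback-driven reversals between the parity and magnitude
    rules: 109 trials containing 10 reversals with inter-reversal segment
    lengths of 6-15 trials and probabilistic (misleading) negative feedback in
    20% of eligible segments.

Defaults reproduce the published trial counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .errors import ConfigurationError

PARADIGMS = ("cognitive", "affective", "feedback")

#: rule -> responding hand; constant across paradigms and participants.
RULE_HAND = {
    "parity": "left",
    "magnitude": "right",
    "gender": "left",
    "emotion": "right",
}


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of one paradigm's trial-sequence generator.

    Intervals are inclusive ``(low, high)`` pairs. Durations are in
    milliseconds. ``seed`` is a default generator seed; the ``generate_*``
    functions accept an explicit seed that overrides it.
    """

    paradigm: str
    n_runs: int = 1
    trials_per_run: int = 240
    baseline_fraction: float = 0.8
    post_critical_gap: tuple[int, int] = (3, 6)
    run_length_interval: tuple[int, int] = (3, 7)
    n_reversals: int = 0
    inter_reversal_interval: tuple[int, int] = (6, 15)
    prob_error_fraction: float = 0.2
    trial_duration: int = 2000
    stimulus_duration: int = 1000
    feedback_duration: int = 0
    iti_interval: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise ConfigurationError(f"unknown paradigm {self.paradigm!r}")
        for name in ("post_critical_gap", "run_length_interval",
                     "inter_reversal_interval", "iti_interval"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} lower bound {lo} > upper bound {hi}")
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise ConfigurationError("n_runs and trials_per_run must be positive")
        if not 0.0 <= self.baseline_fraction <= 1.0:
            raise ConfigurationError("baseline_fraction must lie in [0, 1]")
        if not 0.0 <= self.prob_error_fraction <= 1.0:
            raise ConfigurationError("prob_error_fraction must lie in [0, 1]")
        if self.trial_duration <= 0 or self.stimulus_duration <= 0:
            raise ConfigurationError("durations must be positive")

    @property
    def response_window(self) -> int:
        """Milliseconds during which a response is registered."""
        return self.trial_duration - self.feedback_duration

    def to_dict(self) -> dict:
        return asdict(self)


def default_config(paradigm: str, seed: int = 0) -> DesignConfig:
    """Published default configuration for a paradigm."""
    if paradigm == "cognitive":
        # 2 runs x 150 trials; 80% baseline; 3-6 trial post-critical gaps.
        return DesignConfig(
            paradigm="cognitive", n_runs=2, trials_per_run=150,
            baseline_fraction=0.8, post_critical_gap=(3, 6),
            trial_duration=2000, stimulus_duration=1000, seed=seed,
        )
    if paradigm == "affective":
        # One run of 240 trials; task runs of 3-7 trials.
        return DesignConfig(
            paradigm="affective", n_runs=1, trials_per_run=240,
            run_length_interval=(3, 7),
            trial_duration=2000, stimulus_duration=1000, seed=seed,
        )
    if paradigm == "feedback":
        # 109 trials, 10 reversals, segments of 6-15 trials, probabilistic
        # errors in 20% of eligible segments, 1500 ms stimulus + 500 ms
        # feedback, jittered 1000-6000 ms ITI.
        return DesignConfig(
            paradigm="feedback", n_runs=1, trials_per_run=109,
            n_reversals=10, inter_reversal_interval=(6, 15),
            prob_error_fraction=0.2,
            trial_duration=2000, stimulus_duration=1500,
            feedback_duration=500, iti_interval=(1000, 6000), seed=seed,
        )
    raise ConfigurationError(f"unknown paradigm {paradigm!r}")


def default_configs(seed: int = 0) -> dict[str, DesignConfig]:
    """Default configuration for every paradigm, keyed by paradigm name."""
    return {p: default_config(p, seed=seed) for p in PARADIGMS}
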