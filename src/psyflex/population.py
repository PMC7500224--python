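"""Latent-factor population model for synthetic participants.

Every between-subject parameter (a *trait*) is generated from a one-factor
model on the standardized scale::

    value = mean + sd * (lambda * eta + sqrt(1 - lambda**2) * u)

with ``eta`` (the latent flexibility factor) and ``u`` independent standard
normals per subject. Traits with ``lambda = 0`` vary independently. The
five study indicators (cognitive RT switch cost, spontaneous switch rate,
affective RT switch costs to emotion and to gender, mean reversal errors)
default to the loadings estimated in the source study's confirmatory factor
analysis; all other traits default to zero loading.

Default means and SDs are calibrated so that group-level condition means of
simulated behavior match the published descriptive tables: e.g. cognitive
baseline RT 687.96 ms and an RT switch cost of mean 335.60 / SD 132.39 ms.

The feedback-paradigm trait is the subject's target mean reversal-error
count ``m``; the generative lose-shift probability is ``q = 1/m`` (a
win-stay/lose-shift rule follower with no perseveration makes on average
``1/q`` errors per reversal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

#: The five indicators entering the study's factor analysis, in table order.
FACTOR_INDICATORS = ("sc_rt_aff_emotion", "sc_rt_aff_gender", "sc_rt_cog",
                     "switch_rate", "reversal_errors")

#: trait -> (population mean, population SD, (truncation low, high))
DEFAULT_TRAITS: dict[str, tuple[float, float, tuple[float, float]]] = {
    # reaction times (ms): condition means of the published descriptives
    "base_rt_cog":        (687.96, 87.93, (300.0, 1500.0)),
    "sc_rt_cog":          (335.60, 132.39, (-400.0, 1000.0)),
    "amb_rt_cost":        (455.34, 160.00, (-400.0, 1200.0)),   # 1143.30 - 687.96
    "distractor_rt_cost": (100.00, 60.00, (-400.0, 800.0)),     # not tabled; modest
    "base_rt_emotion":    (708.97, 89.31, (300.0, 1500.0)),
    "sc_rt_aff_emotion":  (268.82, 119.26, (-400.0, 1000.0)),
    "base_rt_gender":     (652.77, 91.93, (300.0, 1500.0)),
    "sc_rt_aff_gender":   (247.23, 96.75, (-400.0, 1000.0)),
    # error probabilities: means are pre-truncation locations calibrated so
    # that the truncated per-condition error rates hit the published
    # descriptives (.04/.11/.20 cognitive, .08/.16 emotion, .06/.07 gender);
    # flooring probabilities at 0 would otherwise inflate the small cells
    "err_base_cog":       (0.0386, 0.03, (0.0, 1.0)),
    "sc_er_cog":          (0.0610, 0.10, (-1.0, 1.0)),
    "amb_er_cost":        (0.1526, 0.15, (-1.0, 1.0)),
    "distractor_er_cost": (0.0100, 0.02, (-1.0, 1.0)),          # not tabled; modest
    "err_base_emotion":   (0.0788, 0.05, (0.0, 1.0)),
    "sc_er_aff_emotion":  (0.0726, 0.12, (-1.0, 1.0)),
    "err_base_gender":    (0.0540, 0.06, (0.0, 1.0)),
    "sc_er_aff_gender":   (-0.0027, 0.07, (-1.0, 1.0)),
    # dispositional parameters
    "switch_rate":        (0.47, 0.32, (0.0, 1.0)),
    "reversal_errors":    (1.72, 0.42, (1.0, 4.0)),
}

#: Standardized loadings of the five indicators on the latent factor
#: (study CFA estimates); every other trait loads 0 by default.
DEFAULT_LOADINGS: dict[str, float] = {
    "sc_rt_aff_emotion": 0.72,
    "sc_rt_aff_gender": 0.97,
    "sc_rt_cog": 0.58,
    "switch_rate": 0.06,
    "reversal_errors": 0.08,
}


@dataclass
class PopulationModel:
    """Generative description of a synthetic participant sample."""

    n_subjects: int = 100
    loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    indicator_means: dict[str, float] = field(
        default_factory=lambda: {k: v[0] for k, v in DEFAULT_TRAITS.items()})
    indicator_sds: dict[str, float] = field(
        default_factory=lambda: {k: v[1] for k, v in DEFAULT_TRAITS.items()})
    rt_noise: float = 0.20          # within-subject log-scale RT SD
    lapse_rate: float = 0.0         # probability of a random-hand response
    omission_rate: float = 0.0      # extra probability of no response
    perseveration: float = 0.0      # stay probability on the first post-reversal error
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be positive")
        for name, lam in self.loadings.items():
            if lam * lam > 1.0 + 1e-12:
                raise ConfigurationError(
                    f"loading for {name!r} gives negative unique variance "
                    f"(lambda^2 = {lam * lam:.3f} > 1)")
        for p in ("lapse_rate", "omission_rate", "perseveration"):
            v = getattr(self, p)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{p} must lie in [0, 1]")
        if self.rt_noise < 0:
            raise ConfigurationError("rt_noise must be non-negative")

    def with_loadings(self, value: float | dict[str, float]) -> "PopulationModel":
        """Copy of the model with the five indicator loadings replaced
        (scalar applies to all five)."""
        if np.isscalar(value):
            new = {k: float(value) for k in FACTOR_INDICATORS}
        else:
            new = dict(value)
        return replace(self, loadings=new)


@dataclass
class ParticipantParams:
    """Per-subject generative parameters (ground truth for recovery tests)."""

    subject_id: int
    eta: float
    traits: dict[str, float]
    rt_noise: float
    lapse_rate: float
    omission_rate: float
    perseveration: float

    def __getattr__(self, name: str):
        traits = object.__getattribute__(self, "traits")
        if name in traits:
            return traits[name]
        raise AttributeError(name)

    @property
    def theta(self) -> float:
        """Spontaneous switch propensity in ambiguous trials."""
        return self.traits["switch_rate"]

    @property
    def lose_shift_prob(self) -> float:
        """Probability q of abandoning the current rule after negative
        feedback; q = 1 / (target mean reversal errors)."""
        return 1.0 / self.traits["reversal_errors"]

    @property
    def error_probs(self) -> dict[str, float]:
        """Condition -> error probability, clipped to [0, 1]."""
        t = self.traits
        raw = {
            "cog_baseline": t["err_base_cog"],
            "cog_switch": t["err_base_cog"] + t["sc_er_cog"],
            "cog_distractor": t["err_base_cog"] + t["distractor_er_cost"],
            "cog_ambiguous": t["err_base_cog"] + t["amb_er_cost"],
            "aff_emotion_repeat": t["err_base_emotion"],
            "aff_emotion_switch": t["err_base_emotion"] + t["sc_er_aff_emotion"],
            "aff_gender_repeat": t["err_base_gender"],
            "aff_gender_switch": t["err_base_gender"] + t["sc_er_aff_gender"],
        }
        return {k: float(np.clip(v, 0.0, 1.0)) for k, v in raw.items()}

    def rt_mean(self, paradigm: str, condition: str, rule: str) -> float:
        """Subject/condition-specific mean RT (ms) before trial noise."""
        t = self.traits
        if paradigm == "cognitive":
            mu = t["base_rt_cog"]
            mu += {"baseline": 0.0, "switch": t["sc_rt_cog"],
                   "distractor": t["distractor_rt_cost"],
                   "ambiguous": t["amb_rt_cost"]}[condition]
        elif paradigm == "affective":
            base = t["base_rt_emotion"] if rule == "emotion" else t["base_rt_gender"]
            cost = (t["sc_rt_aff_emotion"] if rule == "emotion"
                    else t["sc_rt_aff_gender"])
            mu = base + (cost if condition == "switch" else 0.0)
        else:
            mu = t["base_rt_cog"]
        return float(max(mu, 300.0))


def sample_population(model: PopulationModel,
                      seed: int | None = None) -> list[ParticipantParams]:
    """Draw per-subject trait vectors from the one-factor population model.

    Deterministic given the seed. Trait values are truncated (clipped) to
    their admissible ranges after the factor draw.
    """
    rng = np.random.default_rng(model.seed if seed is None else seed)
    n = model.n_subjects
    eta = rng.standard_normal(n)
    names = list(model.indicator_means)
    participants: list[ParticipantParams] = []
    draws = {}
    for name in names:
        lam = float(model.loadings.get(name, 0.0))
        mean = model.indicator_means[name]
        sd = model.indicator_sds[name]
        u = rng.standard_normal(n)
        z = lam * eta + np.sqrt(max(0.0, 1.0 - lam * lam)) * u
        lo, hi = DEFAULT_TRAITS.get(name, (None, None, (-np.inf, np.inf)))[2]
        draws[name] = np.clip(mean + sd * z, lo, hi)
    for i in range(n):
        participants.append(ParticipantParams(
            subject_id=i,
            eta=float(eta[i]),
            traits={name: float(draws[name][i]) for name in names},
            rt_noise=model.rt_noise,
            lapse_rate=model.lapse_rate,
            omission_rate=model.omission_rate,
            perseveration=model.perseveration,
        ))
    return participants
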