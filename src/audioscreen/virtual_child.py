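"""Probabilistic model of a child doing the 6-picture word identification task.

Each presentation is a 6-alternative forced choice: the child hears a
spondee and taps one of six pictures within 10 s. The probability of a
correct response follows a standard m-AFC psychometric function

    psi(x) = gamma + (1 - gamma - lambda) * F((x - theta) / sigma)

with guess rate gamma = 1/6 fixed by the task, lapse rate lambda, logistic
link F, presentation level x (dB HL), the ear's true threshold theta, and
slope sigma in dB. Independently of hearing, the child may simply not
answer in time (timeout probability tau).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import expit

from .audiogram import Ear, EarAudiogram

GUESS_RATE_6AFC = 1.0 / 6.0


class Outcome(str, enum.Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    TIMEOUT = "timeout"


@dataclass(frozen=True)
class PsychometricParams:
    """Behavioral parameters of the virtual child.

    Defaults are simulator priors for a cooperative 4-5-year-old, not
    measured quantities: slope 4 dB, lapse 2%, timeout 1%. ``slope=0`` is
    the deterministic step-function limit (correct iff level >= threshold,
    ties counting as correct) used for noiseless oracle checks.
    """

    guess_rate: float = GUESS_RATE_6AFC
    lapse_rate: float = 0.02
    slope: float = 4.0
    timeout_prob: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.guess_rate < 1.0:
            raise ValueError("guess rate must be in [0, 1)")
        if not 0.0 <= self.lapse_rate <= 0.2:
            raise ValueError("lapse rate must be in [0, 0.2]")
        if self.slope < 0.0:
            raise ValueError("slope must be >= 0 dB")
        if not 0.0 <= self.timeout_prob < 1.0:
            raise ValueError("timeout probability must be in [0, 1)")
        if self.guess_rate + self.lapse_rate >= 1.0:
            raise ValueError("guess rate + lapse rate must be < 1")

    @classmethod
    def noiseless(cls) -> "PsychometricParams":
        """Deterministic limit: no guessing, no lapses, no timeouts, step link."""
        return cls(guess_rate=0.0, lapse_rate=0.0, slope=0.0, timeout_prob=0.0)


@dataclass(frozen=True)
class ChildProfile:
    """Ground truth for one simulated child: both audiograms plus behavior."""

    child_id: str
    right: EarAudiogram
    left: EarAudiogram
    behavior: PsychometricParams = field(default_factory=PsychometricParams)

    def __post_init__(self) -> None:
        if self.right.ear is not Ear.RIGHT or self.left.ear is not Ear.LEFT:
            raise ValueError("right/left audiograms have mismatched ear labels")

    def audiogram(self, ear: Ear | str) -> EarAudiogram:
        return self.right if Ear(ear) is Ear.RIGHT else self.left


def p_correct(
    presentation_level: float,
    ear_threshold: float,
    params: PsychometricParams,
) -> float:
    """Probability of a correct picture choice, given that the child answers."""
    gamma, lam = params.guess_rate, params.lapse_rate
    if params.slope == 0.0:
        f = 1.0 if presentation_level >= ear_threshold else 0.0
    else:
        f = float(expit((presentation_level - ear_threshold) / params.slope))
    return gamma + (1.0 - gamma - lam) * f


def respond(
    presentation_level: float,
    ear_threshold: float,
    params: PsychometricParams,
    rng: np.random.Generator,
) -> Outcome:
    """One presentation: timeout with probability tau, else Bernoulli(psi)."""
    if params.timeout_prob > 0 and rng.random() < params.timeout_prob:
        return Outcome.TIMEOUT
    p = p_correct(presentation_level, ear_threshold, params)
    return Outcome.CORRECT if rng.random() < p else Outcome.INCORRECT


# ---------------------------------------------------------------------------
# Profile serialization (JSON round-trip; CSV via the cohort module's tables)

def profile_to_dict(profile: ChildProfile) -> dict:
    return {
        "child_id": profile.child_id,
        "right": dict(profile.right.thresholds),
        "left": dict(profile.left.thresholds),
        "behavior": {
            "guess_rate": profile.behavior.guess_rate,
            "lapse_rate": profile.behavior.lapse_rate,
            "slope": profile.behavior.slope,
            "timeout_prob": profile.behavior.timeout_prob,
        },
    }


def profile_from_dict(d: dict) -> ChildProfile:
    return ChildProfile(
        child_id=str(d["child_id"]),
        right=EarAudiogram(Ear.RIGHT, {float(k): float(v) for k, v in d["right"].items()}),
        left=EarAudiogram(Ear.LEFT, {float(k): float(v) for k, v in d["left"].items()}),
        behavior=PsychometricParams(**d.get("behavior", {})),
    )


def write_profiles_json(path, profiles: list[ChildProfile]) -> None:
    with open(path, "w") as fh:
        json.dump([profile_to_dict(p) for p in profiles], fh, indent=1)


def read_profiles_json(path) -> list[ChildProfile]:
    with open(path) as fh:
        return [profile_from_dict(d) for d in json.load(fh)]


def with_behavior(profile: ChildProfile, behavior: PsychometricParams) -> ChildProfile:
    return replace(profile, behavior=behavior)
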