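"""The adaptive screening protocol engine.

Per ear, the app descends 40 -> 30 -> 20 dB HL. At each level it shows up
to three 6-picture sets; 2-of-3 correct passes the level, a timeout (no
answer within 10 s) fails the level outright. The descent stops at the
first failed level; the lowest level passed determines the screened
category (pass 20 -> normal, lowest pass 30/40 -> mild, fail 40 -> moderate).
The right ear is tested first, then the left.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import acoustics
from .acoustics import HeadphoneSpec, CalibrationTable, effective_level, get_headphone
from .audiogram import (
    Ear,
    HearingCategory,
    PROTOCOL_LEVELS,
    pure_tone_average,
    screened_category,
)
from .virtual_child import ChildProfile, Outcome, respond

#: Default pool of spondee word identifiers (stand-ins for the app's
#: two-syllable Thai words; word identity does not affect the response model).
DEFAULT_WORDS: tuple[str, ...] = tuple(f"spondee_{i:02d}" for i in range(1, 13))


@dataclass(frozen=True)
class ProtocolConfig:
    """Knobs of the adaptive protocol, defaulting to the deployed settings."""

    levels: tuple[int, ...] = PROTOCOL_LEVELS
    sets_per_level: int = 3
    pass_criterion: int = 2
    pictures_per_set: int = 6
    timeout_s: float = 10.0
    ear_order: tuple[Ear, ...] = (Ear.RIGHT, Ear.LEFT)
    early_stop: bool = True
    #: log-normal response-time model (median seconds, log-sd), truncated at
    #: the timeout, plus fixed inter-trial overhead; only affects durations.
    response_time_median_s: float = 4.0
    response_time_sigma: float = 0.5
    inter_trial_s: float = 2.0
    words: tuple[str, ...] = DEFAULT_WORDS

    def __post_init__(self) -> None:
        if any(b >= a for a, b in zip(self.levels, self.levels[1:])):
            raise ValueError("levels must be strictly decreasing")
        if not 1 <= self.pass_criterion <= self.sets_per_level:
            raise ValueError("pass criterion must be in [1, sets_per_level]")
        if len(self.words) < self.sets_per_level:
            raise ValueError("word pool smaller than sets_per_level")


@dataclass(frozen=True)
class HeadphoneContext:
    """Acoustic context a screening runs under: transducer, room, calibration.

    cal_bias_db is a fixed post-calibration offset; cal_error_sd_db draws an
    independent zero-mean residual per presentation (default 0: the
    calibration procedure is taken at face value).
    """

    spec: HeadphoneSpec
    ambient_noise_dba: float = 35.0
    masking_offset_db: float = 10.0
    cal_bias_db: float = 0.0
    cal_error_sd_db: float = 0.0
    calibration: Optional[CalibrationTable] = None

    @classmethod
    def preset(cls, key: str, **kwargs) -> "HeadphoneContext":
        return cls(spec=get_headphone(key), **kwargs)

    def presentation_level(
        self, nominal: int, word: str, rng: np.random.Generator
    ) -> float:
        cal = self.cal_bias_db
        if self.calibration is not None:
            cal += self.calibration.coefficient(word, nominal)
        if self.cal_error_sd_db > 0:
            cal += rng.normal(0.0, self.cal_error_sd_db)
        return effective_level(
            nominal, cal, self.ambient_noise_dba, self.spec, self.masking_offset_db
        )


@dataclass(frozen=True)
class Presentation:
    level: int
    set_index: int
    word: str
    outcome: Outcome
    response_time_s: float


@dataclass(frozen=True)
class ScreeningResult:
    child_id: str
    ear: Ear
    headphone: str
    lowest_passed_level: Optional[int]
    category: HearingCategory
    presentations: tuple[Presentation, ...]
    duration_s: float

    def __post_init__(self) -> None:
        if self.category is not screened_category(self.lowest_passed_level):
            raise ValueError("category inconsistent with lowest passed level")


def _response_time(outcome: Outcome, config: ProtocolConfig, rng) -> float:
    if outcome is Outcome.TIMEOUT:
        rt = config.timeout_s
    else:
        rt = min(
            float(rng.lognormal(np.log(config.response_time_median_s),
                                config.response_time_sigma)),
            config.timeout_s,
        )
    return rt + config.inter_trial_s


def run_level(
    level: int,
    child: ChildProfile,
    ear: Ear,
    context: HeadphoneContext,
    config: ProtocolConfig,
    rng: np.random.Generator,
) -> tuple[bool, list[Presentation]]:
    """Present up to sets_per_level picture sets at one level.

    Fails immediately on any timeout; otherwise passes once pass_criterion
    correct answers are in. With early_stop the level also ends as soon as
    the criterion becomes unreachable.
    """
    if level not in config.levels:
        raise ValueError(f"level {level} not in protocol levels {config.levels}")
    threshold = pure_tone_average(child.audiogram(ear))
    words = list(rng.choice(config.words, size=config.sets_per_level, replace=False))
    log: list[Presentation] = []
    n_correct = 0
    for set_index, word in enumerate(words):
        x = context.presentation_level(level, word, rng)
        outcome = respond(x, threshold, child.behavior, rng)
        log.append(Presentation(level, set_index, word, outcome,
                                _response_time(outcome, config, rng)))
        if outcome is Outcome.TIMEOUT:
            return False, log
        if outcome is Outcome.CORRECT:
            n_correct += 1
        remaining = config.sets_per_level - (set_index + 1)
        if config.early_stop:
            if n_correct >= config.pass_criterion:
                return True, log
            if n_correct + remaining < config.pass_criterion:
                return False, log
    return n_correct >= config.pass_criterion, log


def run_ear(
    child: ChildProfile,
    ear: Ear,
    context: HeadphoneContext,
    config: Optional[ProtocolConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> ScreeningResult:
    """Full descent for one ear: stop at the first failed level."""
    config = config or ProtocolConfig()
    rng = rng if rng is not None else np.random.default_rng()
    lowest_passed: Optional[int] = None
    log: list[Presentation] = []
    for level in config.levels:
        passed, level_log = run_level(level, child, ear, context, config, rng)
        log.extend(level_log)
        if not passed:
            break
        lowest_passed = level
    return ScreeningResult(
        child_id=child.child_id,
        ear=ear,
        headphone=context.spec.name,
        lowest_passed_level=lowest_passed,
        category=screened_category(lowest_passed),
        presentations=tuple(log),
        duration_s=float(sum(p.response_time_s for p in log)),
    )


def run_screening(
    child: ChildProfile,
    context: HeadphoneContext,
    config: Optional[ProtocolConfig] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ScreeningResult, ...]:
    """Screen both ears in protocol order, one independent RNG stream per ear."""
    config = config or ProtocolConfig()
    rng = rng if rng is not None else np.random.default_rng()
    streams = rng.spawn(len(config.ear_order))
    return tuple(
        run_ear(child, ear, context, config, stream)
        for ear, stream in zip(config.ear_order, streams)
    )


def results_to_frame(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    rows = [
        {
            "child_id": r.child_id,
            "ear": r.ear.value,
            "headphone": r.headphone,
            "lowest_passed_level": "" if r.lowest_passed_level is None
            else r.lowest_passed_level,
            "category": str(r.category),
            "duration_s": round(r.duration_s, 2),
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=["child_id", "ear", "headphone", "lowest_passed_level",
                 "category", "duration_s"],
    )
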