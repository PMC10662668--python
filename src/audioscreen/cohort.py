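"""Synthetic cohort of 4-5-year-old children plus the simulated reference test.

The generative unit is the child: each is bilaterally normal, has a
unilateral loss, or has a bilateral loss, with default prevalences 70% /
21% / 9% matching the study composition (31 / 9 / 4 of 44 children). Loss
ears are mild or moderate (default 20% moderate among loss ears), with
flat audiograms drawn from severity-specific threshold distributions.

The reference test emulates conditioned play audiometry in a soundproof
room: per-frequency measured threshold = true threshold + Normal(0,
noise_sd), quantized to the audiometer's 5 dB steps, classified by
5-frequency pure-tone average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .audiogram import (
    Ear,
    EarAudiogram,
    HearingCategory,
    TEST_FREQUENCIES,
    classify_hearing_level,
    pure_tone_average,
    quantize_5db,
)
from .virtual_child import ChildProfile, PsychometricParams


@dataclass(frozen=True)
class CohortConfig:
    """Prevalence structure and threshold distributions of the cohort."""

    n_children: int = 44
    p_bilateral_normal: float = 0.70
    p_unilateral_loss: float = 0.21
    p_bilateral_loss: float = 0.09
    #: probability that a loss ear is moderate rather than mild
    severity_mix: float = 0.2
    #: normal ears ~ Normal(10, 5) truncated to [-10, 20] dB HL
    normal_mean: float = 10.0
    normal_sd: float = 5.0
    normal_range: tuple[float, float] = (-10.0, 20.0)
    #: mild ears ~ Uniform(25, 40); moderate ears ~ Uniform(45, 70) dB HL
    mild_range: tuple[float, float] = (25.0, 40.0)
    moderate_range: tuple[float, float] = (45.0, 70.0)
    #: optional per-frequency jitter around the flat severity level
    frequency_jitter_sd: float = 0.0
    behavior: PsychometricParams = field(default_factory=PsychometricParams)

    def __post_init__(self) -> None:
        probs = (self.p_bilateral_normal, self.p_unilateral_loss, self.p_bilateral_loss)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("status prevalences must be >= 0 and sum to 1")
        if not 0.0 <= self.severity_mix <= 1.0:
            raise ValueError("severity_mix must be a probability")
        if self.n_children < 1:
            raise ValueError("cohort needs at least one child")

    @property
    def status_probs(self) -> tuple[float, float, float]:
        return (self.p_bilateral_normal, self.p_unilateral_loss, self.p_bilateral_loss)


def _truncated_normal(mean, sd, lo, hi, rng) -> float:
    # rejection sampling; bounds are ~2 sd out, so this is cheap
    while True:
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)


def _ear_audiogram(ear: Ear, level: float, config: CohortConfig, rng,
                   bounds: tuple[float, float]) -> EarAudiogram:
    if config.frequency_jitter_sd > 0:
        lo, hi = bounds
        thresholds = {
            f: float(np.clip(level + rng.normal(0.0, config.frequency_jitter_sd), lo, hi))
            for f in TEST_FREQUENCIES
        }
        return EarAudiogram(ear, thresholds)
    return EarAudiogram.flat(ear, level)


def _draw_ear(ear: Ear, has_loss: bool, config: CohortConfig, rng) -> EarAudiogram:
    if not has_loss:
        level = _truncated_normal(config.normal_mean, config.normal_sd,
                                  *config.normal_range, rng=rng)
        return _ear_audiogram(ear, level, config, rng, config.normal_range)
    if rng.random() < config.severity_mix:
        bounds = config.moderate_range
    else:
        bounds = config.mild_range
    level = float(rng.uniform(*bounds))
    return _ear_audiogram(ear, level, config, rng, bounds)


def generate_cohort(
    config: Optional[CohortConfig] = None,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[ChildProfile]:
    """Draw a cohort: child status multinomially, then per-ear thresholds."""
    config = config or CohortConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    children: list[ChildProfile] = []
    for i in range(config.n_children):
        status = rng.choice(3, p=config.status_probs)
        if status == 0:
            loss = (False, False)
        elif status == 1:
            side = rng.random() < 0.5
            loss = (side, not side)
        else:
            loss = (True, True)
        children.append(
            ChildProfile(
                child_id=f"child_{i + 1:03d}",
                right=_draw_ear(Ear.RIGHT, loss[0], config, rng),
                left=_draw_ear(Ear.LEFT, loss[1], config, rng),
                behavior=config.behavior,
            )
        )
    return children


@dataclass(frozen=True)
class ReferenceResult:
    """One ear's conditioned-play-audiometry outcome."""

    child_id: str
    ear: Ear
    measured: EarAudiogram
    pta: float
    category: HearingCategory
    duration_s: float

    def __post_init__(self) -> None:
        if self.category is not classify_hearing_level(self.pta):
            raise ValueError("category inconsistent with PTA")


#: Reference-test duration model (whole-child, both ears): log-normal with
#: median 560 s and log-sd 0.25, spanning the plausible 7-19 minute range of
#: play audiometry with a preschooler.
REFERENCE_DURATION_MEDIAN_S = 560.0
REFERENCE_DURATION_SIGMA = 0.25


def reference_test(
    child: ChildProfile,
    noise_sd: float = 2.5,
    rng: Optional[np.random.Generator] = None,
    duration_median_s: float = REFERENCE_DURATION_MEDIAN_S,
    duration_sigma: float = REFERENCE_DURATION_SIGMA,
) -> tuple[ReferenceResult, ReferenceResult]:
    """Simulate the reference audiometry on both ears.

    noise_sd is the per-frequency test-retest measurement noise in dB;
    measured thresholds are quantized to 5 dB steps before the PTA.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    total_duration = float(rng.lognormal(np.log(duration_median_s), duration_sigma))
    results = []
    for ear in (Ear.RIGHT, Ear.LEFT):
        true_ag = child.audiogram(ear)
        measured = EarAudiogram(
            ear,
            {
                f: float(np.clip(quantize_5db(t + (rng.normal(0.0, noise_sd)
                                                   if noise_sd > 0 else 0.0)),
                                 -10.0, 120.0))
                for f, t in true_ag.thresholds.items()
            },
        )
        pta = pure_tone_average(measured)
        results.append(
            ReferenceResult(
                child_id=child.child_id,
                ear=ear,
                measured=measured,
                pta=pta,
                category=classify_hearing_level(pta),
                duration_s=total_duration / 2.0,
            )
        )
    return tuple(results)


# ---------------------------------------------------------------------------
# Tabular interchange

def cohort_to_frame(children: Sequence[ChildProfile]) -> pd.DataFrame:
    rows = []
    for c in children:
        for ag in (c.right, c.left):
            rows.append(
                {
                    "child_id": c.child_id,
                    "ear": ag.ear.value,
                    **{f"f{str(f).replace('.', '_').rstrip('_0')}": ag.thresholds[f]
                       for f in TEST_FREQUENCIES},
                    "true_pta": pure_tone_average(ag),
                    "true_category": str(classify_hearing_level(pure_tone_average(ag))),
                }
            )
    return pd.DataFrame(rows)


def reference_to_frame(results: Sequence[ReferenceResult]) -> pd.DataFrame:
    rows = [
        {
            "child_id": r.child_id,
            "ear": r.ear.value,
            **{f"f{str(f).replace('.', '_').rstrip('_0')}": r.measured.thresholds[f]
               for f in TEST_FREQUENCIES},
            "pta": r.pta,
            "category": str(r.category),
            "duration_s": round(r.duration_s, 1),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
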