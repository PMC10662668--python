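"""Hearing-level semantics: thresholds, categories, and pure-tone averages.

Category cutoffs follow the American Academy of Audiology childhood
screening convention: a hearing level of <=20 dB HL is normal, >20 and
<=40 dB HL is mild hearing loss, and >40 dB HL is moderate hearing loss.
The same cutoffs apply whether the level is a measured pure-tone average
or the lowest level passed by the adaptive screening descent.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: Audiometric test frequencies in kHz (air conduction).
TEST_FREQUENCIES: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0, 4.0)

#: Screening levels offered by the adaptive protocol, in descent order.
PROTOCOL_LEVELS: tuple[int, ...] = (40, 30, 20)

NORMAL_CUTOFF_DB = 20.0
MILD_CUTOFF_DB = 40.0

#: dB HL range a clinical audiometer can display.
THRESHOLD_MIN_DB = -10.0
THRESHOLD_MAX_DB = 120.0


class HearingCategory(enum.IntEnum):
    """Ordered hearing-level category: NORMAL < MILD < MODERATE."""

    NORMAL = 0
    MILD = 1
    MODERATE = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "HearingCategory":
        try:
            return cls[str(label).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown hearing category {label!r}") from None


class Ear(str, enum.Enum):
    RIGHT = "right"
    LEFT = "left"


@dataclass(frozen=True)
class EarAudiogram:
    """Air-conduction thresholds for one ear at the five test frequencies."""

    ear: Ear
    thresholds: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(TEST_FREQUENCIES) - set(self.thresholds)
        if missing:
            raise ValueError(f"audiogram missing frequencies {sorted(missing)} kHz")
        for f, t in self.thresholds.items():
            if not math.isfinite(t) or not THRESHOLD_MIN_DB <= t <= THRESHOLD_MAX_DB:
                raise ValueError(
                    f"threshold {t!r} dB HL at {f} kHz outside "
                    f"[{THRESHOLD_MIN_DB}, {THRESHOLD_MAX_DB}]"
                )
        object.__setattr__(self, "thresholds", dict(self.thresholds))

    @classmethod
    def flat(cls, ear: Ear | str, level: float) -> "EarAudiogram":
        """Audiogram with the same threshold at every frequency."""
        return cls(Ear(ear), {f: float(level) for f in TEST_FREQUENCIES})


def classify_hearing_level(level: float) -> HearingCategory:
    """Map a hearing level in dB HL to its category.

    <=20 dB HL is normal, >20 and <=40 is mild, >40 is moderate; boundaries
    are inclusive exactly as the guideline states them.
    """
    if not math.isfinite(level):
        raise ValueError(f"hearing level must be finite, got {level!r}")
    if level <= NORMAL_CUTOFF_DB:
        return HearingCategory.NORMAL
    if level <= MILD_CUTOFF_DB:
        return HearingCategory.MILD
    return HearingCategory.MODERATE


def pure_tone_average(
    audiogram: EarAudiogram, frequencies: Optional[Iterable[float]] = None
) -> float:
    """Arithmetic mean threshold over the requested frequencies (all five by default)."""
    freqs = tuple(frequencies) if frequencies is not None else TEST_FREQUENCIES
    if not freqs:
        raise ValueError("pure-tone average needs at least one frequency")
    missing = set(freqs) - set(audiogram.thresholds)
    if missing:
        raise ValueError(f"frequencies {sorted(missing)} kHz not in audiogram")
    return sum(audiogram.thresholds[f] for f in freqs) / len(freqs)


def screened_category(lowest_passed_level: Optional[float]) -> HearingCategory:
    """Category implied by the adaptive descent's outcome.

    Passing 20 dB HL means the screened threshold is <=20 (normal); a lowest
    pass of 30 or 40 puts the threshold in the mild band; failing even
    40 dB HL implies a threshold >40 (moderate).
    """
    if lowest_passed_level is None:
        return HearingCategory.MODERATE
    if lowest_passed_level not in PROTOCOL_LEVELS:
        raise ValueError(
            f"lowest passed level must be one of {PROTOCOL_LEVELS} or None, "
            f"got {lowest_passed_level!r}"
        )
    return classify_hearing_level(lowest_passed_level)


def quantize_5db(level: float) -> float:
    """Round a level to the nearest 5 dB step (standard audiometer resolution)."""
    return 5.0 * round(level / 5.0)


def reference_category(
    audiogram: EarAudiogram,
    frequencies: Optional[Iterable[float]] = None,
    rule: str = "pta",
) -> HearingCategory:
    """Classify an ear the way the reference audiometry does.

    rule="pta" (default) classifies the pure-tone average over ``frequencies``;
    rule="worst" classifies the worst single-frequency threshold, offered for
    sensitivity analyses.
    """
    if rule == "pta":
        return classify_hearing_level(pure_tone_average(audiogram, frequencies))
    if rule == "worst":
        freqs = tuple(frequencies) if frequencies is not None else TEST_FREQUENCIES
        return classify_hearing_level(max(audiogram.thresholds[f] for f in freqs))
    raise ValueError(f"unknown reference rule {rule!r}")


# ---------------------------------------------------------------------------
# CSV interchange: columns child_id, ear, f0_5, f1, f2, f3, f4 (dB HL)

_FREQ_COLUMNS = {"f0_5": 0.5, "f1": 1.0, "f2": 2.0, "f3": 3.0, "f4": 4.0}


def audiograms_to_frame(entries: Sequence[tuple[str, EarAudiogram]]) -> pd.DataFrame:
    rows = []
    for child_id, ag in entries:
        row: dict[str, object] = {"child_id": child_id, "ear": ag.ear.value}
        for col, f in _FREQ_COLUMNS.items():
            row[col] = ag.thresholds[f]
        rows.append(row)
    return pd.DataFrame(rows, columns=["child_id", "ear", *_FREQ_COLUMNS])


def frame_to_audiograms(df: pd.DataFrame) -> list[tuple[str, EarAudiogram]]:
    out = []
    for _, row in df.iterrows():
        thresholds = {f: float(row[col]) for col, f in _FREQ_COLUMNS.items()}
        out.append((str(row["child_id"]), EarAudiogram(Ear(row["ear"]), thresholds)))
    return out


def read_audiograms_csv(path) -> list[tuple[str, EarAudiogram]]:
    return frame_to_audiograms(pd.read_csv(path, comment="#"))


def write_audiograms_csv(path, entries: Sequence[tuple[str, EarAudiogram]]) -> None:
    audiograms_to_frame(entries).to_csv(path, index=False)
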