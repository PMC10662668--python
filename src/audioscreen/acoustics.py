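"""Headphone and stimulus acoustics.

Covers the software-visible part of the calibration chain: RMS
equalization of the spondee word recordings, per-word/per-level
calibration coefficients (the extra gain that makes the tablet's output
match the reference audiometer's dBA peak through a 6cc coupler), and a
simple masking model for the effective presentation level when residual
room noise leaks past the headphone's passive isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .audiogram import PROTOCOL_LEVELS


@dataclass(frozen=True)
class HeadphoneSpec:
    """Transducer datasheet values that matter to the simulation.

    ambient_isolation is the passive attenuation of room noise in dB;
    sensitivity is dB SPL (at 1 mW, 1 kHz where the datasheet states it);
    distortion is total harmonic distortion as a fraction.
    """

    name: str
    impedance_ohm: float
    sensitivity_db_spl: float
    ambient_isolation_db: float
    distortion: float
    frequency_response_note: str = ""

    def __post_init__(self) -> None:
        if self.impedance_ohm <= 0:
            raise ValueError("impedance must be positive")
        if self.ambient_isolation_db < 0:
            raise ValueError("ambient isolation cannot be negative")


#: Named presets for the three headphones under comparison.
HEADPHONE_PRESETS: dict[str, HeadphoneSpec] = {
    "tdh39": HeadphoneSpec(
        name="TDH39 with earmuffs",
        impedance_ohm=10.0,
        sensitivity_db_spl=108.0,
        ambient_isolation_db=30.0,
        distortion=0.01,
        frequency_response_note="100-8000 Hz",
    ),
    "dt770": HeadphoneSpec(
        name="Beyerdynamic DT 770 PRO",
        impedance_ohm=32.0,
        sensitivity_db_spl=96.0,
        ambient_isolation_db=20.0,
        distortion=0.002,
        frequency_response_note="5-35,000 Hz",
    ),
    "generic": HeadphoneSpec(
        name="Generic headphones with earmuffs",
        impedance_ohm=32.0,
        sensitivity_db_spl=90.0,
        ambient_isolation_db=30.0,
        distortion=0.10,
        frequency_response_note="up to 4 kHz, ~10 dB down from max output",
    ),
}


def get_headphone(key: str) -> HeadphoneSpec:
    try:
        return HEADPHONE_PRESETS[key.lower()]
    except KeyError:
        raise ValueError(
            f"unknown headphone {key!r}; presets: {sorted(HEADPHONE_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class Waveform:
    """Mono waveform: float samples plus sample rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("waveform must be a non-empty 1-D sample array")
        if self.rate <= 0:
            raise ValueError("sample rate must be positive")
        object.__setattr__(self, "samples", samples)


def rms(w: Waveform) -> float:
    """Root mean square amplitude of the waveform."""
    return float(np.sqrt(np.mean(np.square(w.samples))))


def equalize_rms(w: Waveform, target: float) -> Waveform:
    """Scale a waveform by a single gain so its RMS equals ``target``.

    All word recordings are equalized to a common RMS before calibration so
    each word's nominal dB HL means the same physical level.
    """
    if target <= 0:
        raise ValueError("target RMS must be positive")
    current = rms(w)
    if current <= 0:
        raise ValueError("cannot equalize a silent waveform")
    return replace(w, samples=w.samples * (target / current))


def calibration_coefficient(reference_dba: float, device_dba: float) -> float:
    """Gain (dB) that makes the device's measured dBA peak match the reference."""
    if not (math.isfinite(reference_dba) and math.isfinite(device_dba)):
        raise ValueError("dBA readings must be finite")
    return reference_dba - device_dba


class CalibrationTable:
    """Per-(word, nominal level) calibration coefficients in dB.

    Every protocol word x level pair must be present; a table built from
    measurements that missed a point is rejected up front.
    """

    def __init__(
        self,
        entries: Mapping[tuple[str, int], float],
        words: tuple[str, ...] | None = None,
    ) -> None:
        entries = {(w, int(lv)): float(g) for (w, lv), g in entries.items()}
        words = words or tuple(sorted({w for w, _ in entries}))
        for w in words:
            for lv in PROTOCOL_LEVELS:
                if (w, lv) not in entries:
                    raise ValueError(f"calibration missing word {w!r} at {lv} dB HL")
                if not math.isfinite(entries[(w, lv)]):
                    raise ValueError(f"non-finite coefficient for {w!r} at {lv} dB HL")
        self.entries = entries
        self.words = words

    def coefficient(self, word: str, level: int) -> float:
        return self.entries[(word, int(level))]

    @classmethod
    def perfect(cls, words: tuple[str, ...]) -> "CalibrationTable":
        """All-zero table: the device already matches the reference everywhere."""
        return cls({(w, lv): 0.0 for w in words for lv in PROTOCOL_LEVELS}, words)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"word": w, "level_dB_HL": lv, "coefficient_dB": g}
            for (w, lv), g in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows, columns=["word", "level_dB_HL", "coefficient_dB"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationTable":
        df = pd.read_csv(path, comment="#")
        entries = {
            (str(r["word"]), int(r["level_dB_HL"])): float(r["coefficient_dB"])
            for _, r in df.iterrows()
        }
        return cls(entries)


def effective_level(
    nominal: float,
    cal_error: float,
    ambient_noise_dba: float,
    spec: HeadphoneSpec,
    masking_offset: float = 10.0,
) -> float:
    """Sensation level actually delivered under residual room noise.

    Residual noise under the cup is ambient minus the passive isolation;
    noise more than ``masking_offset`` dB below the signal is assumed not to
    mask at all, and any excess elevates the effective threshold dB-for-dB:

        effective = nominal + cal_error - max(0, ambient - isolation - offset)
    """
    if nominal not in PROTOCOL_LEVELS:
        raise ValueError(f"nominal level must be one of {PROTOCOL_LEVELS}")
    residual = max(0.0, ambient_noise_dba - spec.ambient_isolation_db - masking_offset)
    return nominal + cal_error - residual


# ---------------------------------------------------------------------------
# WAV I/O (mono, any numeric subtype; normalized to float in [-1, 1])

_PCM_SCALE = {np.dtype("int16"): 2**15, np.dtype("int32"): 2**31, np.dtype("uint8"): 2**7}


def read_wav(path) -> Waveform:
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected a mono WAV file")
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        if data.dtype == np.dtype("uint8"):
            data = data.astype(float) - 128.0
        data = np.asarray(data, dtype=float) / scale
    return Waveform(np.asarray(data, dtype=float), int(rate))


def write_wav(path, w: Waveform) -> None:
    wavfile.write(path, w.rate, w.samples.astype(np.float32))
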