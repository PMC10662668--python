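"""End-to-end simulated diagnostic study.

Reproduces the design of the validation study in software: one cohort of
children, three app screenings with different headphones plus one
reference audiometry per child in randomized order, then per-headphone
agreement/kappa/sensitivity/specificity tables, McNemar comparisons
against the reference headphone, and the paired duration comparison.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .audiogram import Ear, HearingCategory
from .cohort import (
    CohortConfig,
    ReferenceResult,
    cohort_to_frame,
    generate_cohort,
    reference_test,
    reference_to_frame,
)
from .screening import (
    HeadphoneContext,
    ProtocolConfig,
    ScreeningResult,
    results_to_frame,
    run_screening,
)
from .stats import (
    DegenerateTableError,
    cohens_kappa,
    confusion,
    mcnemar_exact,
    paired_t,
    percent_agreement,
    sens_spec,
)

DEFAULT_HEADPHONES = ("tdh39", "dt770", "generic")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulated study from a seed."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    headphones: tuple[str, ...] = DEFAULT_HEADPHONES
    reference_headphone: str = "tdh39"
    ambient_noise_dba: float = 35.0
    masking_offset_db: float = 10.0
    reference_noise_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.reference_headphone not in self.headphones:
            raise ValueError("reference headphone must be among the headphones tested")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class StudyReport:
    config: RunConfig
    cohort_frame: pd.DataFrame
    reference_frame: pd.DataFrame
    screening_frames: dict[str, pd.DataFrame]
    evaluation: pd.DataFrame
    durations: pd.DataFrame
    duration_tests: pd.DataFrame
    test_order: dict[str, list[str]]


def _ear_key(r) -> tuple[str, str]:
    return (r.child_id, r.ear.value)


def evaluate_headphone(
    app_results: Sequence[ScreeningResult],
    ref_results: Sequence[ReferenceResult],
    headphone: str,
) -> pd.DataFrame:
    """Per-category one-vs-rest agreement table for one headphone."""
    ref_by_ear = {_ear_key(r): r.category for r in ref_results}
    pairs = [(r.category, ref_by_ear[_ear_key(r)]) for r in app_results]
    app_cats = [p[0] for p in pairs]
    ref_cats = [p[1] for p in pairs]
    rows = []
    for cat in HearingCategory:
        t = confusion(app_cats, ref_cats, positive=cat)
        row: dict[str, object] = {
            "headphone": headphone,
            "category": str(cat),
            "n_app_positive": t.test_positive,
            "n_ref_positive": t.ref_positive,
            "a": t.a, "b": t.b, "c": t.c, "d": t.d,
            "agreement_pct": percent_agreement(t),
        }
        try:
            kr = cohens_kappa(t)
            row.update(kappa=kr.kappa, kappa_p=kr.p_value)
        except DegenerateTableError:
            row.update(kappa=np.nan, kappa_p=np.nan)
        try:
            ds = sens_spec(t)
            row.update(
                sensitivity_pct=ds.sensitivity,
                sens_ci_lo=ds.sensitivity_ci[0], sens_ci_hi=ds.sensitivity_ci[1],
                specificity_pct=ds.specificity,
                spec_ci_lo=ds.specificity_ci[0], spec_ci_hi=ds.specificity_ci[1],
            )
        except DegenerateTableError:
            row.update(sensitivity_pct=np.nan, sens_ci_lo=np.nan, sens_ci_hi=np.nan,
                       specificity_pct=np.nan, spec_ci_lo=np.nan, spec_ci_hi=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _mcnemar_vs_reference(
    screenings: dict[str, list[ScreeningResult]], reference_headphone: str
) -> dict[tuple[str, HearingCategory], float]:
    """Exact McNemar p for each non-reference headphone vs the reference one."""
    ref_app = {_ear_key(r): r.category for r in screenings[reference_headphone]}
    out: dict[tuple[str, HearingCategory], float] = {}
    for hp, results in screenings.items():
        if hp == reference_headphone:
            continue
        for cat in HearingCategory:
            b = sum(1 for r in results
                    if r.category == cat and ref_app[_ear_key(r)] != cat)
            c = sum(1 for r in results
                    if r.category != cat and ref_app[_ear_key(r)] == cat)
            out[(hp, cat)] = mcnemar_exact(b, c)
    return out


def run_study(config: Optional[RunConfig] = None,
              rng: Optional[np.random.Generator] = None) -> StudyReport:
    """Simulate the whole study once; fully reproducible from config.seed."""
    config = config or RunConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    children = generate_cohort(config.cohort, rng=rng)

    contexts = {
        hp: HeadphoneContext.preset(
            hp,
            ambient_noise_dba=config.ambient_noise_dba,
            masking_offset_db=config.masking_offset_db,
        )
        for hp in config.headphones
    }
    screenings: dict[str, list[ScreeningResult]] = {hp: [] for hp in config.headphones}
    ref_results: list[ReferenceResult] = []
    test_order: dict[str, list[str]] = {}

    tests = list(config.headphones) + ["reference"]
    for child in children:
        child_rng = rng.spawn(1)[0]
        order = [tests[i] for i in child_rng.permutation(len(tests))]
        test_order[child.child_id] = order
        streams = child_rng.spawn(len(tests))
        for test, stream in zip(order, streams):
            if test == "reference":
                ref_results.extend(
                    reference_test(child, noise_sd=config.reference_noise_sd, rng=stream)
                )
            else:
                screenings[test].extend(
                    run_screening(child, contexts[test], config.protocol, rng=stream)
                )

    evaluation = pd.concat(
        [evaluate_headphone(screenings[hp], ref_results, hp)
         for hp in config.headphones],
        ignore_index=True,
    )
    mcn = _mcnemar_vs_reference(screenings, config.reference_headphone)
    evaluation["mcnemar_p_vs_reference"] = [
        mcn.get((row.headphone, HearingCategory.from_label(row.category)), np.nan)
        for row in evaluation.itertuples()
    ]

    # per-child total durations (both ears) and app-vs-reference paired t
    ref_dur = {}
    for r in ref_results:
        ref_dur[r.child_id] = ref_dur.get(r.child_id, 0.0) + r.duration_s
    dur_rows = []
    for child in children:
        row = {"child_id": child.child_id, "reference_s": round(ref_dur[child.child_id], 1)}
        for hp in config.headphones:
            row[f"{hp}_s"] = round(
                sum(r.duration_s for r in screenings[hp]
                    if r.child_id == child.child_id), 1)
        dur_rows.append(row)
    durations = pd.DataFrame(dur_rows)
    ttest_rows = []
    for hp in config.headphones:
        t, p = paired_t(durations[f"{hp}_s"], durations["reference_s"])
        ttest_rows.append({
            "headphone": hp,
            "mean_app_s": float(durations[f"{hp}_s"].mean()),
            "mean_reference_s": float(durations["reference_s"].mean()),
            "t": t, "p": p,
        })

    return StudyReport(
        config=config,
        cohort_frame=cohort_to_frame(children),
        reference_frame=reference_to_frame(ref_results),
        screening_frames={hp: results_to_frame(screenings[hp])
                          for hp in config.headphones},
        evaluation=evaluation,
        durations=durations,
        duration_tests=pd.DataFrame(ttest_rows),
        test_order=test_order,
    )


def _write_csv(path: Path, df: pd.DataFrame, config: RunConfig) -> None:
    header = (f"# audioscreen v{__version__} seed={config.seed} "
              f"config_hash={config.config_hash()}\n")
    with open(path, "w", newline="") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_report(report: StudyReport, out_dir) -> list[Path]:
    """Write the full report bundle; every file carries version/seed/hash."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    written = []
    for name, df in [
        ("cohort.csv", report.cohort_frame),
        ("reference.csv", report.reference_frame),
        *[(f"screening_{hp}.csv", f) for hp, f in report.screening_frames.items()],
        ("evaluation.csv", report.evaluation),
        ("durations.csv", report.durations),
        ("duration_tests.csv", report.duration_tests),
    ]:
        path = out / name
        _write_csv(path, df, cfg)
        written.append(path)
    meta = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "config": asdict(cfg),
        "test_order": report.test_order,
    }
    meta_path = out / "study_log.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1, default=str)
    written.append(meta_path)
    return written
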