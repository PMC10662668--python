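"""Diagnostic-accuracy statistics for paired per-ear screening outcomes.

Everything operates on 2x2 tables cross-classifying ears as app-positive /
reference-positive under a one-vs-rest dichotomy per hearing category:

                 reference +   reference -
    app +            a             b
    app -            c             d

Provides percent agreement, Cohen's kappa (with the Fleiss large-sample
z test of kappa = 0), sensitivity/specificity with Clopper-Pearson exact
binomial CIs, the exact McNemar test, a paired t test for durations, a
kappa-paradox diagnostic (prevalence/bias indices and PABAK), and the
inversion of printed summary statistics (percent + exact CI + margins)
back into the unique integer table that produced them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .audiogram import HearingCategory

__all__ = [
    "TwoByTwo",
    "KappaResult",
    "DiagnosticSummary",
    "KappaParadoxReport",
    "DegenerateTableError",
    "ReconstructionError",
    "confusion",
    "percent_agreement",
    "cohens_kappa",
    "clopper_pearson",
    "sens_spec",
    "mcnemar_exact",
    "paired_t",
    "reconstruct_from_summaries",
    "kappa_paradox_report",
    "round_half_up",
]


class DegenerateTableError(ValueError):
    """Raised when a statistic is undefined on the given table (e.g. pe = 1)."""


class ReconstructionError(ValueError):
    """Raised when printed summaries invert to no table, or to more than one."""

    def __init__(self, message: str, solutions: Optional[list] = None) -> None:
        super().__init__(message)
        self.solutions = solutions or []


@dataclass(frozen=True)
class TwoByTwo:
    """Counts a=(test+,ref+), b=(test+,ref-), c=(test-,ref+), d=(test-,ref-)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def test_positive(self) -> int:
        return self.a + self.b

    @property
    def ref_positive(self) -> int:
        return self.a + self.c

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: float
    se0: float
    z: float
    p_value: float


@dataclass(frozen=True)
class DiagnosticSummary:
    """Sensitivity/specificity (percent) with exact 95% CIs, plus agreement."""

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    agreement: float
    table: TwoByTwo


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero, matching how results tables are printed."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion(
    test_categories: Sequence[HearingCategory],
    ref_categories: Sequence[HearingCategory],
    positive: HearingCategory,
) -> TwoByTwo:
    """Cross-classify paired per-ear categories under a one-vs-rest dichotomy."""
    if len(test_categories) != len(ref_categories):
        raise ValueError(
            f"paired sequences differ in length: "
            f"{len(test_categories)} vs {len(ref_categories)}"
        )
    a = b = c = d = 0
    for t, r in zip(test_categories, ref_categories):
        tp, rp = t == positive, r == positive
        if tp and rp:
            a += 1
        elif tp:
            b += 1
        elif rp:
            c += 1
        else:
            d += 1
    return TwoByTwo(a, b, c, d)


def percent_agreement(t: TwoByTwo) -> float:
    """Observed agreement as a percentage: 100 (a + d) / N."""
    return 100.0 * (t.a + t.d) / t.n


def cohens_kappa(t: TwoByTwo) -> KappaResult:
    """Unweighted Cohen's kappa with the large-sample z test of kappa = 0.

    pe is the chance agreement from the margins; the null standard error is
    Fleiss's SE0 = sqrt(pe + pe^2 - sum_i p_i+ p+_i (p_i+ + p+_i)) /
    ((1 - pe) sqrt(N)), the form used by the major stats packages for the
    one-degree z test.
    """
    n = t.n
    po = (t.a + t.d) / n
    row = (t.test_positive / n, (t.c + t.d) / n)
    col = (t.ref_positive / n, (t.b + t.d) / n)
    pe = row[0] * col[0] + row[1] * col[1]
    if pe >= 1.0:
        raise DegenerateTableError(
            "chance agreement pe = 1 (all observations in one category); "
            "kappa is undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    inner = pe + pe**2 - sum(r * c * (r + c) for r, c in zip(row, col))
    se0 = math.sqrt(max(inner, 0.0)) / ((1.0 - pe) * math.sqrt(n))
    if se0 > 0:
        z = kappa / se0
        p = 2.0 * sps.norm.sf(abs(z))
    else:  # perfectly balanced degenerate margins
        z, p = math.inf if kappa > 0 else 0.0, 0.0 if kappa > 0 else 1.0
    return KappaResult(po=po, pe=pe, kappa=kappa, se0=se0, z=z, p_value=p)


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval, returned in percent.

    Endpoints are the beta-quantile form of the binomial tail inversion;
    the lower bound is 0 when x = 0 and the upper is 100 when x = n.
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0.0 < conf < 1.0:
        raise ValueError("confidence level must be in (0, 1)")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2.0, x, n - x + 1))
    hi = 1.0 if x == n else float(sps.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return 100.0 * lo, 100.0 * hi


def sens_spec(t: TwoByTwo, conf: float = 0.95) -> DiagnosticSummary:
    """Sensitivity a/(a+c) and specificity d/(b+d) with exact CIs, in percent."""
    if t.a + t.c == 0:
        raise DegenerateTableError("no reference-positive ears: sensitivity undefined")
    if t.b + t.d == 0:
        raise DegenerateTableError("no reference-negative ears: specificity undefined")
    sens = 100.0 * t.a / (t.a + t.c)
    spec = 100.0 * t.d / (t.b + t.d)
    return DiagnosticSummary(
        sensitivity=sens,
        sensitivity_ci=clopper_pearson(t.a, t.a + t.c, conf),
        specificity=spec,
        specificity_ci=clopper_pearson(t.d, t.b + t.d, conf),
        agreement=percent_agreement(t),
        table=t,
    )


def mcnemar_exact(b_discordant: int, c_discordant: int) -> float:
    """Exact two-sided McNemar test on the discordant pairs.

    Under the null the b discordant pairs are Binomial(b + c, 1/2); with no
    discordant pairs the test carries no evidence and p = 1.
    """
    if b_discordant < 0 or c_discordant < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b_discordant + c_discordant
    if n == 0:
        return 1.0
    return float(sps.binomtest(b_discordant, n, 0.5).pvalue)


def paired_t(
    durations_a: Sequence[float], durations_b: Sequence[float]
) -> tuple[float, float]:
    """Paired t test on per-child differences; rejects degenerate inputs."""
    a = np.asarray(durations_a, dtype=float)
    b = np.asarray(durations_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    if np.var(a - b) == 0:
        raise DegenerateTableError("zero variance of paired differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def _printed_decimals(value: float) -> int:
    exp = Decimal(repr(float(value))).normalize().as_tuple().exponent
    return max(0, -int(exp))


def _matches_printed(computed: float, printed: float) -> bool:
    return round_half_up(computed, _printed_decimals(printed)) == float(printed)


def reconstruct_from_summaries(
    sens_pct: float,
    sens_ci: tuple[float, float],
    test_positive_n: int,
    n_total: int,
    conf: float = 0.95,
) -> TwoByTwo:
    """Invert a printed sensitivity summary into the unique 2x2 integer table.

    Searches all (x, m) with x true positives among m reference-positive
    ears such that 100 x / m and the exact CI of x/m both round, half-up at
    each printed value's own precision, to the printed numbers; the
    remaining cells follow from the app-positive margin and N. Raises
    ReconstructionError if no table, or more than one, is consistent.
    """
    if n_total < test_positive_n or test_positive_n < 0:
        raise ValueError("need 0 <= test_positive_n <= n_total")
    lo_p, hi_p = sens_ci
    # cheap float prefilter before the exact printed-precision match
    sens_slack = 0.5001 * 10.0 ** (-_printed_decimals(sens_pct))
    solutions: list[TwoByTwo] = []
    for m in range(1, n_total + 1):
        for x in range(0, min(m, test_positive_n) + 1):
            b = test_positive_n - x
            d = n_total - m - b
            if d < 0:
                continue
            if abs(100.0 * x / m - sens_pct) > sens_slack:
                continue
            if not _matches_printed(100.0 * x / m, sens_pct):
                continue
            lo, hi = clopper_pearson(x, m, conf)
            if _matches_printed(lo, lo_p) and _matches_printed(hi, hi_p):
                solutions.append(TwoByTwo(a=x, b=b, c=m - x, d=d))
    if not solutions:
        raise ReconstructionError(
            f"no 2x2 table with N={n_total}, test-positive={test_positive_n} "
            f"reproduces sensitivity {sens_pct} (CI {sens_ci})"
        )
    if len(solutions) > 1:
        raise ReconstructionError(
            f"{len(solutions)} tables reproduce the printed summary; "
            "inversion is not unique",
            solutions=solutions,
        )
    return solutions[0]


@dataclass(frozen=True)
class KappaParadoxReport:
    """Why a table with high raw agreement can still have low kappa.

    prevalence_index (a - d)/N measures how lopsided the concordant cells
    are; bias_index (b - c)/N measures disagreement asymmetry between the
    raters. PABAK = 2 po - 1 is what kappa would be with balanced margins;
    a large PABAK - kappa gap with a large |prevalence index| is the
    classic skewed-prevalence paradox.
    """

    table: TwoByTwo
    po: float
    pe: float
    kappa: float
    prevalence_index: float
    bias_index: float
    pabak: float
    paradox_flag: bool


def kappa_paradox_report(
    t: TwoByTwo, gap_threshold: float = 0.2
) -> KappaParadoxReport:
    po = (t.a + t.d) / t.n
    pabak = 2.0 * po - 1.0
    kr = cohens_kappa(t)  # raises DegenerateTableError when pe = 1
    return KappaParadoxReport(
        table=t,
        po=kr.po,
        pe=kr.pe,
        kappa=kr.kappa,
        prevalence_index=(t.a - t.d) / t.n,
        bias_index=(t.b - t.c) / t.n,
        pabak=pabak,
        paradox_flag=(pabak - kr.kappa) >= gap_threshold,
    )
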