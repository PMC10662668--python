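"""Agreement statistics: kappa, exact CIs, McNemar, reconstruction, paradox."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from audioscreen import (
    DegenerateTableError,
    HearingCategory,
    ReconstructionError,
    TwoByTwo,
    clopper_pearson,
    cohens_kappa,
    confusion,
    kappa_paradox_report,
    mcnemar_exact,
    paired_t,
    percent_agreement,
    reconstruct_from_summaries,
    round_half_up,
    sens_spec,
)

cells = st.integers(min_value=0, max_value=40)
tables = st.tuples(cells, cells, cells, cells).filter(lambda t: sum(t) > 0)


# ---------------------------------------------------------------------------
# independent oracles

def kappa_enumeration_oracle(t: TwoByTwo) -> float:
    """Observed and chance agreement by explicit enumeration of rating pairs."""
    test = np.repeat([1, 1, 0, 0], [t.a, t.b, t.c, t.d])
    ref = np.repeat([1, 0, 1, 0], [t.a, t.b, t.c, t.d])
    po = float(np.mean(test == ref))
    pe = float(np.mean(test[:, None] == ref[None, :]))  # all N^2 pairings
    return (po - pe) / (1 - pe)


def cp_tail_inversion_oracle(x: int, n: int, alpha: float = 0.05):
    """Clopper-Pearson endpoints by bisecting the explicit binomial tail sums."""

    def upper_tail(p):  # P(X >= x)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(x, n + 1))

    def lower_tail(p):  # P(X <= x)
        return sum(math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(0, x + 1))

    def bisect(f, target):
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if f(mid) < target:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lo = 0.0 if x == 0 else bisect(upper_tail, alpha / 2)
    hi = 1.0 if x == n else 1.0 - bisect(lambda p: lower_tail(1 - p), alpha / 2)
    return 100 * lo, 100 * hi


# ---------------------------------------------------------------------------

class TestConfusion:
    def test_perfect_agreement(self):
        cats = [HearingCategory.MODERATE] * 3 + [HearingCategory.NORMAL] * 7
        t = confusion(cats, cats, positive=HearingCategory.MODERATE)
        assert (t.a, t.b, t.c, t.d) == (3, 0, 0, 7)

    def test_all_negative_test(self):
        test = [HearingCategory.NORMAL] * 5
        ref = [HearingCategory.MILD, *[HearingCategory.NORMAL] * 4]
        t = confusion(test, ref, positive=HearingCategory.MILD)
        assert t.a == t.b == 0 and t.c == 1 and t.d == 4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([HearingCategory.NORMAL], [], HearingCategory.NORMAL)


class TestAgreementAndKappa:
    @pytest.mark.parametrize(
        "table,expected",
        [((1, 7, 0, 80), 92.05), ((1, 5, 0, 82), 94.32), ((0, 0, 0, 10), 100.0)],
    )
    def test_percent_agreement(self, table, expected):
        assert round_half_up(percent_agreement(TwoByTwo(*table)), 2) == expected

    def test_kappa_on_study_moderate_table(self):
        kr = cohens_kappa(TwoByTwo(1, 7, 0, 80))
        assert round_half_up(kr.kappa, 3) == 0.206
        assert kr.p_value == pytest.approx(0.0015, abs=1e-3)

    def test_perfect_agreement_kappa_one(self):
        assert cohens_kappa(TwoByTwo(5, 0, 0, 5)).kappa == pytest.approx(1.0)

    def test_independent_margins_kappa_zero(self):
        assert cohens_kappa(TwoByTwo(4, 16, 16, 64)).kappa == pytest.approx(0.0)

    def test_degenerate_single_category(self):
        with pytest.raises(DegenerateTableError):
            cohens_kappa(TwoByTwo(0, 0, 0, 12))

    def test_kappa_against_enumeration_oracle_bulk(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 1000:
            a, b, c, d = rng.integers(0, 30, size=4)
            t_cells = int(a), int(b), int(c), int(d)
            if sum(t_cells) == 0:
                continue
            t = TwoByTwo(*t_cells)
            try:
                got = cohens_kappa(t).kappa
            except DegenerateTableError:
                continue
            assert got == pytest.approx(kappa_enumeration_oracle(t), abs=1e-12)
            checked += 1

    @given(tables)
    def test_label_swap_invariance(self, t_cells):
        a, b, c, d = t_cells
        t, swapped = TwoByTwo(a, b, c, d), TwoByTwo(d, c, b, a)
        assert percent_agreement(t) == pytest.approx(percent_agreement(swapped))
        try:
            k1 = cohens_kappa(t).kappa
        except DegenerateTableError:
            return
        assert k1 == pytest.approx(cohens_kappa(swapped).kappa)


class TestClopperPearson:
    @pytest.mark.parametrize(
        "x,n,expected",
        [
            (1, 1, (2.5, 100.0)),
            (2, 4, (6.76, 93.24)),
            (0, 10, (0.0, 30.85)),
        ],
    )
    def test_printed_endpoints(self, x, n, expected):
        lo, hi = clopper_pearson(x, n)
        assert round_half_up(lo, 2) == pytest.approx(expected[0], abs=0.005)
        assert round_half_up(hi, 2) == pytest.approx(expected[1], abs=0.005)

    def test_invalid_counts_rejected(self):
        for x, n in [(-1, 5), (6, 5), (0, 0)]:
            with pytest.raises(ValueError):
                clopper_pearson(x, n)

    def test_against_tail_inversion_all_small_n(self):
        for n in range(1, 31):
            for x in range(0, n + 1):
                got = clopper_pearson(x, n)
                want = cp_tail_inversion_oracle(x, n)
                assert got[0] == pytest.approx(want[0], abs=1e-6)
                assert got[1] == pytest.approx(want[1], abs=1e-6)


class TestSensSpec:
    def test_study_moderate_row(self):
        ds = sens_spec(TwoByTwo(1, 7, 0, 80))
        assert ds.sensitivity == 100.0
        assert round_half_up(ds.specificity, 1) == 92.0
        assert ds.sensitivity_ci == pytest.approx((2.5, 100.0), abs=0.005)
        assert round_half_up(ds.specificity_ci[0], 1) == 84.1

    def test_degenerate_edges(self):
        ds = sens_spec(TwoByTwo(0, 0, 5, 5))
        assert (ds.sensitivity, ds.specificity) == (0.0, 100.0)
        with pytest.raises(DegenerateTableError):
            sens_spec(TwoByTwo(0, 3, 0, 7))  # no reference positives

    @given(tables)
    def test_cis_bracket_estimates(self, t_cells):
        t = TwoByTwo(*t_cells)
        if t.a + t.c == 0 or t.b + t.d == 0:
            return
        ds = sens_spec(t)
        assert ds.sensitivity_ci[0] - 1e-9 <= ds.sensitivity <= ds.sensitivity_ci[1] + 1e-9
        assert ds.specificity_ci[0] - 1e-9 <= ds.specificity <= ds.specificity_ci[1] + 1e-9


class TestMcNemarAndPairedT:
    @pytest.mark.parametrize("b,c,expected", [(3, 3, 1.0), (0, 0, 1.0), (5, 0, 0.0625)])
    def test_exact_p(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected)

    def test_shift_detected(self):
        rng = np.random.default_rng(8)
        a = rng.normal(60, 5, size=40)
        b = a + 10 + rng.normal(0, 1, size=40)  # a pure shift is zero-variance
        t, p = paired_t(a, b)
        assert p < 1e-10 and t < 0

    def test_degenerate_differences(self):
        with pytest.raises(DegenerateTableError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])  # constant difference

    def test_simulated_app_vs_reference_durations(self):
        from audioscreen import RunConfig, run_study

        rep = run_study(RunConfig(seed=3))
        assert (rep.duration_tests["p"] < 0.001).all()


class TestReconstruction:
    def test_moderate_row_inversion(self, moderate_tables):
        t = reconstruct_from_summaries(100, (2.5, 100), 8, 88)
        assert t == moderate_tables["tdh39"]

    def test_mild_row_reference_margin(self):
        """The printed 50 (6.76-93.2) CI is the exact-binomial signature of 2/4."""
        t = reconstruct_from_summaries(50, (6.76, 93.2), 4, 88)
        assert (t.a, t.a + t.c) == (2, 4)

    def test_inconsistent_summary_raises(self):
        with pytest.raises(ReconstructionError):
            reconstruct_from_summaries(100, (50.0, 100), 8, 88)

    def test_ambiguous_summary_raises_with_solutions(self):
        # at integer precision several large margins print identically;
        # the inversion must flag this rather than guess
        with pytest.raises(ReconstructionError) as exc:
            reconstruct_from_summaries(92, (84.0, 97.0), 85, 100)
        assert len(exc.value.solutions) > 1

    @given(tables)
    def test_round_trip_identity(self, t_cells):
        t = TwoByTwo(*t_cells)
        if t.a + t.c == 0 or t.b + t.d == 0:
            return
        ds = sens_spec(t)
        printed = (
            round_half_up(ds.sensitivity, 4),
            (round_half_up(ds.sensitivity_ci[0], 4), round_half_up(ds.sensitivity_ci[1], 4)),
        )
        try:
            back = reconstruct_from_summaries(printed[0], printed[1], t.test_positive, t.n)
        except ReconstructionError as exc:
            assert t in exc.value.solutions  # non-unique, but truth among them
            return
        assert back == t


class TestKappaParadox:
    def test_skewed_prevalence_flagged(self):
        rep = kappa_paradox_report(TwoByTwo(1, 7, 0, 80))
        assert round_half_up(rep.po * 100, 2) == 92.05
        assert round_half_up(rep.kappa, 3) == 0.206
        assert rep.pabak == pytest.approx(2 * (81 / 88) - 1)
        assert rep.paradox_flag
        assert abs(rep.prevalence_index) > 0.5

    def test_balanced_table_not_flagged(self):
        rep = kappa_paradox_report(TwoByTwo(20, 5, 5, 20))
        assert rep.kappa == pytest.approx(0.6)
        assert rep.pabak == pytest.approx(0.6)
        assert not rep.paradox_flag

    def test_single_category_table_surfaced(self):
        with pytest.raises(DegenerateTableError):
            kappa_paradox_report(TwoByTwo(0, 0, 0, 9))
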