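"""ROR statistics: closed-form oracles, invariances, and replication values."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvdispro.cohorts import ExposureCohorts
from pvdispro.disproportionality import (
    ContingencyTable,
    DegenerateCohortError,
    ZeroCellError,
    ZeroCellPolicy,
    analyze_by_soc,
    analyze_mr_pts,
    build_contingency,
    ror,
)
from pvdispro.icsr import ICSR, Reaction


def oracle_ror(a, b, c, d, z=1.959963984540054):
    """Independent brute-force Woolf computation (plain math module)."""
    estimate = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return estimate, estimate * math.exp(-z * se), estimate * math.exp(z * se)


def oracle_chi2(a, b, c, d):
    """Textbook Pearson chi-squared via the sum over observed/expected cells."""
    n = a + b + c + d
    obs = [[a, b], [c, d]]
    rows = [a + b, c + d]
    cols = [a + c, b + d]
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = rows[i] * cols[j] / n
            stat += (obs[i][j] - expected) ** 2 / expected
    return stat


cells = st.integers(min_value=1, max_value=500)


@settings(max_examples=200, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_matches_brute_force_oracle(a, b, c, d):
    result = ror(ContingencyTable(a, b, c, d))
    est, lo, hi = oracle_ror(a, b, c, d)
    assert result.ror == pytest.approx(est, abs=1e-12, rel=1e-12)
    assert result.ci_low == pytest.approx(lo, abs=1e-12, rel=1e-12)
    assert result.ci_high == pytest.approx(hi, abs=1e-12, rel=1e-12)
    assert result.chi2 == pytest.approx(oracle_chi2(a, b, c, d), rel=1e-9)


@settings(max_examples=100, deadline=None)
@given(a=cells, b=cells, c=cells, d=cells)
def test_exchange_symmetry(a, b, c, d):
    table = ContingencyTable(a, b, c, d)
    forward = ror(table)
    backward = ror(table.swapped())
    assert backward.ror == pytest.approx(1.0 / forward.ror, rel=1e-12)
    assert backward.ci_low == pytest.approx(1.0 / forward.ci_high, rel=1e-12)
    assert backward.ci_high == pytest.approx(1.0 / forward.ci_low, rel=1e-12)
    assert backward.chi2 == pytest.approx(forward.chi2, rel=1e-12)


@settings(max_examples=100, deadline=None)
@given(a=st.integers(1, 200), b=cells, c=cells, d=cells)
def test_monotone_in_a(a, b, c, d):
    lower = ror(ContingencyTable(a, b, c, d))
    higher = ror(ContingencyTable(a + 1, b, c, d))
    assert higher.ror > lower.ror


def test_agrees_with_statsmodels_table2x2():
    statsmodels = pytest.importorskip("statsmodels.api")
    table = ContingencyTable(1251, 1416, 21474, 54663)
    result = ror(table)
    sm_table = statsmodels.stats.Table2x2(
        np.array([[table.a, table.b], [table.c, table.d]])
    )
    assert result.ror == pytest.approx(sm_table.oddsratio, rel=1e-12)
    lo, hi = sm_table.oddsratio_confint(0.05)
    assert result.ci_low == pytest.approx(lo, rel=1e-9)
    assert result.ci_high == pytest.approx(hi, rel=1e-9)


def test_balanced_table_is_exactly_null():
    result = ror(ContingencyTable(10, 10, 10, 10))
    assert result.ror == pytest.approx(1.0)
    assert result.ci_low == pytest.approx(1.0 / result.ci_high, rel=1e-12)
    assert result.chi2 == pytest.approx(0.0)
    assert not result.significant


def test_ci_bounds_bracket_estimate():
    result = ror(ContingencyTable(5, 100, 7, 93))
    assert result.ci_low <= result.ror <= result.ci_high


@pytest.mark.parametrize(
    "a, c, expected_ror, expected_ci",
    [
        # Musculoskeletal SOC and headline muscle PTs, target N=2,667 vs
        # comparator N=76,137 — published point estimates and 95% CIs.
        (1251, 21474, 2.25, (2.08, 2.43)),
        (631, 10615, 1.91, (1.75, 2.10)),
        (44, 200, 6.37, (4.58, 8.85)),
        (7, 3822, 0.05, (0.02, 0.10)),
    ],
)
def test_replicates_published_estimates(a, c, expected_ror, expected_ci):
    result = ror(ContingencyTable(a, 2667 - a, c, 76137 - c))
    assert round(result.ror, 2) == expected_ror
    assert (round(result.ci_low, 2), round(result.ci_high, 2)) == expected_ci
    assert result.p_value < 0.001


def test_zero_cell_haldane_correction():
    # No target reports of the event: finite ROR below 1, flagged.
    table = ContingencyTable(0, 2667, 531, 75606)
    result = ror(table)
    assert result.zero_cell_corrected
    assert result.low_count_flag
    a, b, c, d = 0.5, 2667.5, 531.5, 75606.5
    est, lo, hi = oracle_ror(a, b, c, d)
    assert result.ror == pytest.approx(est, rel=1e-12)
    assert result.ci_low == pytest.approx(lo, rel=1e-12)
    assert result.ci_high == pytest.approx(hi, rel=1e-12)
    assert 0 < result.ror < 1


def test_zero_cell_error_policy():
    with pytest.raises(ZeroCellError):
        ror(ContingencyTable(0, 10, 5, 5), zero_cell_policy=ZeroCellPolicy.ERROR)


def test_empty_cohort_is_degenerate():
    with pytest.raises(DegenerateCohortError):
        ror(ContingencyTable(0, 0, 5, 5))
    with pytest.raises(DegenerateCohortError):
        build_contingency([], [ICSR(case_id="X", reactions=[Reaction(pt="Myalgia")])], lambda r: True)


def test_contingency_rejects_negative_cells():
    with pytest.raises(ValueError):
        ContingencyTable(-1, 2, 3, 4)


def _cohorts(target, comparator):
    return ExposureCohorts(target_only=target, comparator_only=comparator)


def _report(case_id, *pts):
    return ICSR(
        case_id=case_id,
        suspect_drugs=[frozenset({"x"})],
        reactions=[Reaction(pt=pt) for pt in pts],
    )


def test_build_contingency_degenerate_predicates():
    exposed = [_report(f"T{i}", "Myalgia") for i in range(4)]
    reference = [_report(f"C{i}", "Nausea") for i in range(6)]
    always_false = build_contingency(exposed, reference, lambda r: False)
    assert (always_false.a, always_false.c) == (0, 0)
    assert (always_false.b, always_false.d) == (4, 6)
    always_true = build_contingency(exposed, reference, lambda r: True)
    assert (always_true.b, always_true.d) == (0, 0)


def test_analyze_by_soc_sorted_descending(reference_cohorts, meddra):
    results = analyze_by_soc(reference_cohorts, meddra)
    rors = [r.ror for r in results]
    assert rors == sorted(rors, reverse=True)


def test_analyze_by_soc_single_shared_soc(meddra):
    cohorts = _cohorts(
        [_report("T1", "Myalgia"), _report("T2", "Myalgia")],
        [_report("C1", "Myalgia"), _report("C2", "Myalgia")],
    )
    results = analyze_by_soc(cohorts, meddra)
    assert len(results) == 1
    assert results[0].ror == pytest.approx(1.0)


def test_analyze_mr_pts_spelling_variant_counts(mrpts):
    cohorts = _cohorts(
        [_report("T1", "Necrotizing myositis"), _report("T2", "Nausea")],
        [_report("C1", "Necrotising myositis"), _report("C2", "Nausea")],
    )
    results = analyze_mr_pts(cohorts, mrpts)
    assert len(results) == 1
    assert results[0].table.a == 1 and results[0].table.c == 1


def test_analyze_mr_pts_omits_absent_pts(reference_cohorts, mrpts):
    results = analyze_mr_pts(reference_cohorts, mrpts)
    # All 13 muscle PTs have events somewhere in the reference data.
    assert len(results) == 13
    corrected = {r.event_label for r in results if r.zero_cell_corrected}
    assert corrected == {"myositis", "necrotising myositis"}
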