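"""Balance worksheet and cutoff selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_cohort
from ipmn_balance import (
    BalanceTable,
    balance_product,
    build_balance_table,
    count_errors,
    select_cutoff,
)
from ipmn_balance.cohort import PD_RATES, SEVERITY_THRESHOLDS, ComplicationRateSet

HALF_RATES = ComplicationRateSet("PD", {s: 0.5 for s in SEVERITY_THRESHOLDS})


def test_count_errors_on_hand_counted_toy(toy4):
    labels, mp = toy4
    assert count_errors(labels, mp, 25) == (1, 1)


def test_count_errors_at_grid_extremes(toy4):
    labels, mp = toy4
    fp, fn = count_errors(labels, mp, 5)  # below every score
    assert (fp, fn) == (2, 0)
    fp, fn = count_errors(labels, mp, 45)  # above every score
    assert (fp, fn) == (0, 2)


def test_count_errors_treats_score_at_cutoff_as_operated(toy4):
    labels, mp = toy4
    fp, fn = count_errors(labels, mp, 30)  # benign patient sits exactly at 30%
    assert fp == 1 and fn == 1


def test_count_errors_rejects_bad_input(toy4):
    labels, mp = toy4
    with pytest.raises(ValueError, match="empty"):
        count_errors([], [], 20)
    with pytest.raises(ValueError, match="probabilities"):
        count_errors(labels, mp * 10, 20)


def test_balance_product_matches_published_worksheet_entries():
    assert balance_product(274, 0.024) == pytest.approx(6.576, abs=1e-9)
    assert balance_product(127, 0.304) == pytest.approx(38.608, abs=1e-9)
    assert balance_product(0, 0.433) == 0.0


def test_build_balance_table_single_row_toy(toy4):
    labels, mp = toy4
    table = build_balance_table(labels, mp, [50], HALF_RATES)
    (row,) = table.rows
    assert (row.fp, row.fn) == (0, 2)
    assert row.weighted_fp == {s: 0.0 for s in SEVERITY_THRESHOLDS}


def test_low_cutoff_row_has_no_false_negatives(toy4):
    labels, mp = toy4
    table = build_balance_table(labels, mp, [1, 50], HALF_RATES)
    assert table.rows[0].fn == 0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_fp_decreasing_fn_increasing_across_any_grid(seed):
    """FP weakly falls and FN weakly rises as the cutoff rises; together
    they never exceed the cohort size."""
    labels, mp = random_cohort(np.random.default_rng(seed))
    table = build_balance_table(labels, mp, range(1, 100), PD_RATES)
    fp = [r.fp for r in table.rows]
    fn = [r.fn for r in table.rows]
    assert all(a >= b for a, b in zip(fp, fp[1:]))
    assert all(a <= b for a, b in zip(fn, fn[1:]))
    assert all(r.fp + r.fn <= labels.size for r in table.rows)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_select_cutoff_agrees_with_exhaustive_oracle_on_small_cohorts(seed):
    rng = np.random.default_rng(seed)
    labels, mp = random_cohort(rng, n=int(rng.integers(4, 30)))
    table = build_balance_table(labels, mp, range(1, 100), PD_RATES)
    for sev in SEVERITY_THRESHOLDS:
        rate = PD_RATES.rate_ge[sev]
        # independent exhaustive recount over the same grid
        best, best_val = None, float("inf")
        for c in range(1, 100):
            fp = sum(1 for l, p in zip(labels, mp) if not l and p * 100 >= c)
            fn = sum(1 for l, p in zip(labels, mp) if l and p * 100 < c)
            val = abs(fn - fp * rate)
            if val < best_val:
                best, best_val = c, val
        sel = select_cutoff(table, sev)
        assert sel.cutoff == best
        assert sel.residual == pytest.approx(best_val, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_selected_cutoff_weakly_increases_with_complication_rate(seed):
    """Riskier surgery -> higher bar: the balance cutoff is weakly
    monotone in the complication rate for a fixed cohort."""
    labels, mp = random_cohort(np.random.default_rng(seed))
    rates = sorted(np.random.default_rng(seed + 1).uniform(0.01, 0.9, size=4))
    rate_set = ComplicationRateSet(
        "PD", dict(zip(SEVERITY_THRESHOLDS, rates[::-1]))
    )  # severities map high->low rate
    table = build_balance_table(labels, mp, range(1, 100), rate_set)
    cutoffs = [select_cutoff(table, s).cutoff for s in SEVERITY_THRESHOLDS]
    # SEVERITY_THRESHOLDS runs II -> IV with decreasing rate, so cutoffs fall
    assert all(a >= b for a, b in zip(cutoffs, cutoffs[1:]))


def test_published_worksheets_show_monotone_cutoff_in_rate(pd_table, dp_table):
    for table in (pd_table, dp_table):
        sel = table.select_all()
        ordered = [sel[s].cutoff for s in ("IV", "IIIb", "IIIa", "II")]
        assert ordered == sorted(ordered)


def test_pd_worksheet_major_complication_cutoff(pd_table):
    sel = select_cutoff(pd_table, "IIIa")
    assert sel.cutoff == 32
    assert not sel.at_boundary


def test_boundary_flag_when_balance_point_is_not_bracketed():
    table = BalanceTable.from_counts("PD", [(10, 2, 5), (20, 1, 6), (30, 0, 7)], PD_RATES)
    sel = select_cutoff(table, "IV")  # fn > fp*rate everywhere -> first row
    assert sel.cutoff == 10
    assert sel.at_boundary


def test_weighted_columns_reconstruct_from_counts(pd_table):
    for row in pd_table.rows:
        for sev in SEVERITY_THRESHOLDS:
            assert row.weighted_fp[sev] == row.fp * PD_RATES.rate_ge[sev]


def test_table_frame_round_trip(pd_table):
    frame = pd_table.to_frame()
    rebuilt = BalanceTable.from_counts(
        "PD", list(zip(frame["cutoff"], frame["fp"], frame["fn"])), PD_RATES
    )
    assert rebuilt.to_frame().equals(frame)
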