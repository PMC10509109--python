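"""Agreement statistics: kappa, tau-b, reclassification, Bland-Altman, ICC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacsim import (
    PairedScores,
    RiskContingencyTable,
    agreement_report,
    bland_altman,
    cohen_kappa,
    cross_tabulate,
    icc_absolute,
    kendall_tau_b,
    reclassification_summary,
    study_tables,
)
from cacsim.study_data import PRINTED_AGREEMENT, RISK_CLASS_COUNTS


# ------------------------------------------------------- embedded fixtures

def test_embedded_tables_have_study_marginals():
    for table in study_tables().values():
        assert table.total == 169
        np.testing.assert_array_equal(table.col_margins, RISK_CLASS_COUNTS)


def test_reader_table_trace():
    assert study_tables()["reader2_vs_reader1"].trace == 162


@pytest.mark.parametrize("key", sorted(PRINTED_AGREEMENT))
def test_embedded_tables_reproduce_published_statistics(key):
    table = study_tables()[key]
    printed = PRINTED_AGREEMENT[key]
    assert cohen_kappa(table) == pytest.approx(printed["kappa"], abs=1e-3)
    assert kendall_tau_b(table) == pytest.approx(printed["tau_b"], abs=1e-3)
    n_re, rate, _, _ = reclassification_summary(table)
    assert n_re == printed["n_reclassified"]
    assert 100 * rate == pytest.approx(printed["rate_pct"], abs=0.05)


def test_reclassification_direction_of_low_kvp_tables():
    # all low-kVp reclassifications move down except the single upward move
    tabs = study_tables()
    _, _, up80, down80 = reclassification_summary(tabs["80_vs_120"])
    _, _, up70, down70 = reclassification_summary(tabs["70_vs_120"])
    assert (up80, down80) == (0, 12)
    assert (up70, down70) == (1, 28)


# --------------------------------------------------------- cross-tabulation

def test_cross_tabulate_round_trips_study_table():
    table = study_tables()["80_vs_120"]
    comp, ref = table.to_pairs()
    again = cross_tabulate(comp, ref)
    np.testing.assert_array_equal(again.counts, table.counts)


def test_cross_tabulate_empty_and_identical():
    empty = cross_tabulate([], [])
    assert empty.total == 0
    same = cross_tabulate(["0", "1-10", ">400"], ["0", "1-10", ">400"])
    assert same.trace == 3 and same.total == 3


def test_cross_tabulate_rejects_unknown_label():
    with pytest.raises(ValueError, match="unknown"):
        cross_tabulate(["bogus"], ["0"])


def test_column_marginals_conserve_reference_histogram(rng):
    ref = rng.integers(0, 5, size=200)
    comp = rng.integers(0, 5, size=200)
    table = cross_tabulate(comp, ref)
    np.testing.assert_array_equal(table.col_margins, np.bincount(ref, minlength=5))


# ------------------------------------------------------------- kappa / tau

def _random_table(rng, concentration=8.0):
    base = np.eye(5) * concentration + 0.3
    return RiskContingencyTable(rng.poisson(base * 4))


def test_diagonal_table_gives_perfect_agreement():
    diag = RiskContingencyTable(np.diag([10, 5, 8, 4, 3]))
    assert cohen_kappa(diag) == pytest.approx(1.0)
    assert kendall_tau_b(diag) == pytest.approx(1.0)
    n_re, rate, up, down = reclassification_summary(diag)
    assert (n_re, rate, up, down) == (0, 0.0, 0, 0)


def test_kappa_drops_when_subject_moves_off_diagonal():
    counts = np.diag([10, 5, 8, 4, 3])
    moved = counts.copy()
    moved[0, 0] -= 1
    moved[1, 0] += 1
    assert cohen_kappa(RiskContingencyTable(moved)) < 1.0


def test_kappa_matches_sklearn_on_random_tables(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    for _ in range(25):
        table = _random_table(rng)
        if table.total == 0:
            continue
        comp, ref = table.to_pairs()
        expected = sklearn_metrics.cohen_kappa_score(comp, ref)
        assert cohen_kappa(table) == pytest.approx(expected, abs=1e-12)


def test_linear_weighted_kappa_matches_sklearn(rng):
    sklearn_metrics = pytest.importorskip("sklearn.metrics")
    table = _random_table(rng)
    comp, ref = table.to_pairs()
    expected = sklearn_metrics.cohen_kappa_score(comp, ref, weights="linear")
    assert cohen_kappa(table, weights="linear") == pytest.approx(expected, abs=1e-12)


def brute_force_tau_b(comp, ref):
    """Pair-counting oracle: O(n^2) over all subject pairs."""
    n = len(comp)
    P = Q = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = comp[i] - comp[j]
            dy = ref[i] - ref[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                P += 1
            else:
                Q += 1
    import math

    return (P - Q) / math.sqrt((P + Q + tx) * (P + Q + ty))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_tau_b_matches_pair_counting_oracle(seed):
    rng = np.random.default_rng(seed)
    table = _random_table(rng)
    if table.total < 2:
        return
    comp, ref = table.to_pairs()
    try:
        expected = brute_force_tau_b(list(comp), list(ref))
    except ZeroDivisionError:
        return
    assert kendall_tau_b(table) == pytest.approx(expected, abs=1e-12)


def test_tau_b_on_study_tables_matches_oracle():
    for table in study_tables().values():
        comp, ref = table.to_pairs()
        assert kendall_tau_b(table) == pytest.approx(brute_force_tau_b(list(comp), list(ref)), abs=1e-12)


def test_degenerate_tau_signalled():
    counts = np.zeros((5, 5), dtype=int)
    counts[2, :] = [1, 2, 3, 4, 5]  # all comparison mass in one class
    with pytest.raises(ValueError, match="undefined"):
        kendall_tau_b(RiskContingencyTable(counts))


# ----------------------------------------------------------- Bland-Altman

def test_bland_altman_identical_pairs():
    pairs = PairedScores([1.0, 5.0, 9.0], [1.0, 5.0, 9.0])
    ba = bland_altman(pairs)
    assert (ba.bias, ba.loa_low, ba.loa_high) == (0.0, 0.0, 0.0)


def test_bland_altman_constant_offset():
    pairs = PairedScores([1.0, 5.0, 9.0], [6.0, 10.0, 14.0])
    ba = bland_altman(pairs)
    assert ba.bias == pytest.approx(5.0)
    assert ba.loa_low == pytest.approx(5.0)
    assert ba.loa_high == pytest.approx(5.0)


def test_bland_altman_limits_use_sample_sd():
    ref = np.array([5.0, 5.0, 5.0, 5.0])
    comp = np.array([6.0, 4.0, 8.0, 2.0])
    ba = bland_altman(PairedScores(ref, comp))
    d = comp - ref
    assert ba.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))


def test_bland_altman_needs_two_pairs():
    with pytest.raises(ValueError):
        bland_altman(PairedScores([1.0], [2.0]))


# --------------------------------------------------------------------- ICC

def test_icc_perfect_agreement_with_spread():
    vals = np.array([0.0, 10.0, 50.0, 200.0, 500.0, 42.0])
    assert icc_absolute(PairedScores(vals, vals)) == pytest.approx(1.0)


def test_icc_independent_ratings_near_zero(rng):
    a = rng.random(10_000) * 100
    b = rng.random(10_000) * 100
    assert abs(icc_absolute(PairedScores(a, b))) < 0.05


def test_icc_matches_pingouin_two_way_anova():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    ref = np.array([10.0, 40.0, 95.0, 220.0, 310.0, 700.0])
    comp = np.array([12.0, 35.0, 90.0, 200.0, 330.0, 640.0])
    df = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(6), 2),
            "rater": np.tile(["a", "b"], 6),
            "score": np.column_stack([ref, comp]).ravel(),
        }
    )
    icc_table = pingouin.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    row = icc_table[icc_table["Type"].str.contains("A,1|ICC2", regex=True)].iloc[0]
    assert icc_absolute(PairedScores(ref, comp)) == pytest.approx(float(row["ICC"]), abs=1e-9)


def test_icc_six_subject_worked_set_frozen_value():
    # frozen from the independent two-way ANOVA oracle (pingouin ICC2)
    ref = np.array([10.0, 40.0, 95.0, 220.0, 310.0, 700.0])
    comp = np.array([12.0, 35.0, 90.0, 200.0, 330.0, 640.0])
    assert icc_absolute(PairedScores(ref, comp)) == pytest.approx(0.993949, abs=1e-4)


def test_agreement_report_consistency():
    table = study_tables()["70_vs_120"]
    rep = agreement_report(table)
    assert rep.n_reclassified == rep.n_upward + rep.n_downward == table.total - table.trace


def test_table_csv_round_trip(tmp_path):
    table = study_tables()["80_vs_120"]
    path = tmp_path / "t.csv"
    table.to_csv(path)
    again = RiskContingencyTable.from_csv(path)
    np.testing.assert_array_equal(again.counts, table.counts)
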