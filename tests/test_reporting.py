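"""Percent change, ANOVA, Sidak adjustment, star codes, report assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nucarch.errors import MissingDataError
from nucarch.reporting import (
    anova_oneway,
    build_report,
    ci95,
    percent_change,
    round_half_away,
    sidak_adjust,
    star_code,
)


@pytest.mark.parametrize(
    "baseline,value,decimals,reported",
    [
        (1.72, 2.43, 0, 41.0),    # nucleolin 24 h
        (1.72, 2.65, 0, 54.0),    # nucleolin 48 h
        (1.51, 1.97, 0, 30.0),    # fibrillarin 24 h
        (1.88, 2.19, 0, 16.0),    # the weaker variant's nucleolin shift
        (1.38, 1.73, 0, 25.0),
        (823.0, 773.3, 1, -6.0),  # nuclear volume 48 h
    ],
)
def test_percent_change_reproduces_printed_values(baseline, value, decimals, reported):
    assert round_half_away(percent_change(baseline, value), decimals) == reported


def test_percent_change_basics():
    assert percent_change(5.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        percent_change(0.0, 1.0)
    assert round_half_away(2.5) == 3.0
    assert round_half_away(-2.5) == -3.0
    assert round_half_away(41.28, 0) == 41.0


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.floats(0.1, 1e4), st.floats(0.1, 1e4), st.floats(1e-3, 1e3))
def test_percent_change_is_unit_invariant(baseline, value, unit):
    assert percent_change(baseline * unit, value * unit) == pytest.approx(
        percent_change(baseline, value), rel=1e-9
    )


def test_anova_identical_groups():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    f, p = anova_oneway([g, g.copy(), g.copy()])
    assert f == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_anova_two_groups_equals_t_squared(rng):
    a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
    f, p_f = anova_oneway([a, b])
    t, p_t = stats.ttest_ind(a, b)
    assert f == pytest.approx(t**2, rel=1e-10)
    assert p_f == pytest.approx(p_t, rel=1e-10)


def test_anova_matches_sum_of_squares_oracle(rng):
    groups = [rng.normal(m, 1.3, 10) for m in (0.0, 0.4, -0.2)]
    f, p = anova_oneway(groups)
    # independent oracle: explicit between/within sum-of-squares arithmetic
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, len(allv) - len(groups)
    f_oracle = (ss_between / df_b) / (ss_within / df_w)
    p_oracle = stats.f.sf(f_oracle, df_b, df_w)
    assert f == pytest.approx(f_oracle, abs=1e-10)
    assert p == pytest.approx(p_oracle, abs=1e-10)
    with pytest.raises(ValueError):
        anova_oneway([np.array([1.0]), np.array([1.0, 2.0])])


def test_sidak_closed_form_and_monotonicity():
    assert sidak_adjust(0.03, 1) == pytest.approx(0.03)
    assert sidak_adjust(0.01, 3) == pytest.approx(1 - 0.99**3)
    assert sidak_adjust(0.01, 3) == pytest.approx(0.029701)
    adj = [sidak_adjust(0.02, m) for m in range(1, 10)]
    assert all(a <= b for a, b in zip(adj, adj[1:]))
    with pytest.raises(ValueError):
        sidak_adjust(0.01, 0)


def test_sidak_never_exceeds_bonferroni_on_grid():
    for p in np.linspace(0.0, 1.0, 101):
        for m in (1, 2, 3, 5, 10, 50):
            assert sidak_adjust(float(p), m) <= min(1.0, m * p) + 1e-12


@pytest.mark.parametrize(
    "p,stars",
    [
        (0.2, "n.s."), (0.05, "n.s."), (0.049, "*"), (0.011, "*"),
        (0.009, "**"), (0.0005, "***"), (1e-6, "****"), (1e-4, "***"),
    ],
)
def test_star_codes(p, stars):
    assert star_code(p) == stars


def _samples(groups):
    rows = []
    for (cond, tp, metric), values in groups.items():
        rows += [(cond, tp, metric, v) for v in values]
    return pd.DataFrame(rows, columns=["condition", "timepoint_h", "metric",
                                       "value"])


def test_build_report_two_timepoints_adjusted_equals_raw(rng):
    a, b = rng.normal(10, 2, 30), rng.normal(11, 2, 30)
    report = build_report(_samples({("c", 0, "m"): a, ("c", 24, "m"): b}))
    row = report[report.timepoint_h == 24].iloc[0]
    # m = 1 comparison: Sidak is the identity, and with two groups the
    # pooled-variance contrast is the classical two-sample t test
    _, p_raw = stats.ttest_ind(b, a)
    assert row.p_adj == pytest.approx(p_raw, rel=1e-10)
    assert row.pct_change_vs_0h == pytest.approx(
        percent_change(a.mean(), b.mean()))
    lo, hi = ci95(b)
    assert lo < row["mean"] < hi
    assert (row.ci95_low, row.ci95_high) == pytest.approx((lo, hi))


def test_build_report_requires_baseline(rng):
    with pytest.raises(MissingDataError, match="G12D.*area"):
        build_report(_samples({("G12D", 24, "area"): rng.normal(1, 1, 5)}))


def test_build_report_power_on_nucleolar_size_shift(rng):
    """A +41 % mean-area shift at published dispersion (1.72 ± 1.32 µm²,
    n = 400) is detected (p_adj < 0.05) in >= 90 % of simulations and
    the reported percent change is unbiased (mean within 5 points)."""

    def lognormal(mean, sd, n):
        s2 = np.log(1 + (sd / mean) ** 2)
        return rng.lognormal(np.log(mean) - s2 / 2, np.sqrt(s2), n)

    pcts, hits = [], 0
    n_runs = 200
    for _ in range(n_runs):
        base = lognormal(1.72, 1.32, 400)
        late = lognormal(2.43, 1.865, 400)  # same coefficient of variation
        report = build_report(_samples({("G12D", 0, "a"): base,
                                        ("G12D", 24, "a"): late}))
        row = report[report.timepoint_h == 24].iloc[0]
        pcts.append(row.pct_change_vs_0h)
        hits += row.p_adj < 0.05
    assert abs(np.mean(pcts) - 41.28) < 5.0
    assert hits / n_runs >= 0.90


def test_build_report_sidak_m_counts_nonbaseline_timepoints(rng):
    groups = {("c", t, "m"): rng.normal(0, 1, 25) for t in (0, 24, 48)}
    report = build_report(_samples(groups))
    assert len(report) == 3
    base = report[report.timepoint_h == 0].iloc[0]
    assert np.isnan(base.p_adj) and base.stars == ""
    for _, row in report[report.timepoint_h > 0].iterrows():
        assert 0 <= row.p_adj <= 1
        assert row.stars in {"n.s.", "*", "**", "***", "****"}
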