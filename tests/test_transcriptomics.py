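"""DE filtering, nuclear panels, NTRS, and sign concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nucarch.errors import MissingDataError
from nucarch.synthdata import DEEffectModel, DESimSpec, generate_de_table
from nucarch.transcriptomics import (
    build_panel,
    compute_ntrs,
    filter_de,
    ntrs_report,
    sign_concordance,
)


def _table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "condition", "log2fc", "fdr",
                                       "go_category"])


def test_filter_boundaries_follow_strict_fdr_and_inclusive_lfc():
    table = _table([
        ("A", "c", 0.75, 0.04, "nucleolus"),    # kept: fdr < 0.05, |lfc| >= 0.75
        ("B", "c", 2.00, 0.05, "nucleolus"),    # dropped: fdr not strictly below
        ("C", "c", -0.74, 0.01, "nucleolus"),   # dropped: |lfc| below threshold
        ("D", "c", -0.75, 0.049, "other"),      # kept
    ])
    kept = filter_de(table)
    assert sorted(kept.gene_id) == ["A", "D"]


def test_nonfinite_log2fc_rejected_with_warning():
    table = _table([
        ("A", "c", np.nan, 0.01, "nucleolus"),
        ("B", "c", np.inf, 0.01, "nucleolus"),
        ("C", "c", 1.0, 0.01, "nucleolus"),
    ])
    with pytest.warns(UserWarning, match="non-finite"):
        kept = filter_de(table)
    assert list(kept.gene_id) == ["C"]


def test_filter_matches_brute_force_scan(rng):
    n = 1000
    table = _table([
        (f"G{i}", "c", rng.normal(0, 1.2), rng.uniform(), "nucleolus")
        for i in range(n)
    ])
    kept = set(filter_de(table).gene_id)
    brute = {
        r.gene_id for r in table.itertuples()
        if r.fdr < 0.05 and abs(r.log2fc) >= 0.75
    }
    assert kept == brute


def test_threshold_relaxation_never_shrinks_kept_set(rng):
    table = _table([
        (f"G{i}", "c", rng.normal(0, 1.2), rng.uniform(), "nucleolus")
        for i in range(500)
    ])
    tight = set(filter_de(table, 0.05, 0.75).gene_id)
    assert tight <= set(filter_de(table, 0.10, 0.75).gene_id)
    assert tight <= set(filter_de(table, 0.05, 0.50).gene_id)


def test_panel_subsets_by_category():
    table = _table([
        ("A", "c", 1.0, 0.01, "other"),
        ("B", "c", 1.0, 0.01, "nucleolus"),
        ("C", "c", 1.0, 0.01, "chromatin_remodeling"),
        ("D", "c", 1.0, 0.01, "nuclear_membrane"),
    ])
    assert len(build_panel(table, {"nucleolus"})) == 1
    assert len(build_panel(table)) == 3
    all_other = build_panel(_table([("A", "c", 1.0, 0.01, "other")]))
    assert len(all_other) == 0
    # union identity over the three nuclear categories
    union = pd.concat([
        build_panel(table, {c})
        for c in ("chromatin_remodeling", "nuclear_membrane", "nucleolus")
    ])
    assert set(union.gene_id) == set(build_panel(table).gene_id)


def test_ntrs_simple_and_printed_values():
    panel = _table([
        ("A", "c", 1.0, 0.01, "nucleolus"),
        ("B", "c", 3.0, 0.01, "nucleolus"),
        ("C", "c", -2.0, 0.01, "nucleolus"),
    ])
    res = compute_ntrs(panel)
    assert res.ntrs_pos == pytest.approx(2.0)
    assert res.ntrs_neg == pytest.approx(-2.0)
    # the published G12R six-gene worked subset: hand summation gives
    # (0.85 + 0.84 + 0.30 + 0.16 + 0.03) / 5 = 0.436 and -0.05
    six = _table([
        ("SOX9", "G12R", 0.85, 0.01, "chromatin_remodeling"),
        ("NOS1AP", "G12R", 0.84, 0.01, "nuclear_membrane"),
        ("CCD86", "G12R", 0.30, 0.01, "nucleolus"),
        ("HDAC5", "G12R", 0.16, 0.01, "chromatin_remodeling"),
        ("ABTB1", "G12R", 0.03, 0.01, "nucleolus"),
        ("SATB1", "G12R", -0.05, 0.01, "chromatin_remodeling"),
    ])
    res = compute_ntrs(six)
    assert res.ntrs_pos == pytest.approx(0.436)
    assert res.ntrs_neg == pytest.approx(-0.05)
    assert (res.n_pos, res.n_neg) == (5, 1)


def test_empty_directions_are_undefined_not_zero():
    allneg = _table([("A", "c", -1.0, 0.01, "nucleolus")])
    res = compute_ntrs(allneg)
    assert res.ntrs_pos is None and res.n_pos == 0
    assert res.ntrs_neg == pytest.approx(-1.0)
    empty = compute_ntrs(_table([]))
    assert empty.ntrs_pos is None and empty.ntrs_neg is None
    # log2fc exactly zero contributes to neither direction
    with_zero = _table([
        ("A", "c", 0.0, 0.01, "nucleolus"),
        ("B", "c", 2.0, 0.01, "nucleolus"),
    ])
    res = compute_ntrs(with_zero)
    assert (res.n_pos, res.n_neg) == (1, 0)


@settings(deadline=None, max_examples=100, derandomize=True)
@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=0, max_size=40))
def test_ntrs_equals_brute_force_mean(values):
    panel = _table([
        (f"G{i}", "c", v, 0.01, "nucleolus") for i, v in enumerate(values)
    ])
    res = compute_ntrs(panel)
    pos = [v for v in values if v > 0]
    neg = [v for v in values if v < 0]
    if pos:
        assert res.ntrs_pos == pytest.approx(sum(pos) / len(pos))
    else:
        assert res.ntrs_pos is None
    if neg:
        assert res.ntrs_neg == pytest.approx(sum(neg) / len(neg))
    else:
        assert res.ntrs_neg is None


def test_ntrs_is_permutation_invariant(rng):
    panel = _table([
        (f"G{i}", "c", rng.normal(), 0.01, "nucleolus") for i in range(50)
    ])
    shuffled = panel.sample(frac=1.0, random_state=3).reset_index(drop=True)
    a, b = compute_ntrs(panel), compute_ntrs(shuffled)
    assert a.ntrs_pos == pytest.approx(b.ntrs_pos)
    assert a.ntrs_neg == pytest.approx(b.ntrs_neg)
    assert build_panel(panel).gene_id.tolist() == build_panel(shuffled).gene_id.tolist()


def test_concordance_identity_and_inversion():
    panel = _table([
        ("A", "x", 1.0, 0.01, "nucleolus"),
        ("B", "x", -2.0, 0.01, "nucleolus"),
        ("C", "x", 0.5, 0.01, "nucleolus"),
    ])
    flipped = panel.assign(log2fc=-panel.log2fc)
    assert sign_concordance(panel, panel) == 1.0
    assert sign_concordance(panel, flipped) == -1.0
    disjoint = _table([("Z", "y", 1.0, 0.01, "nucleolus")])
    with pytest.raises(MissingDataError):
        sign_concordance(panel, disjoint)


def test_ntrs_recovery_of_injected_effects():
    """Injected ±0.6-magnitude nuclear effects: the score matches the
    mean of the injected values that survive the filter, within 3 SE."""
    spec = DESimSpec(
        n_genes=6000,
        category_fractions={"chromatin_remodeling": 0.1, "nuclear_membrane": 0.1,
                            "nucleolus": 0.1, "other": 0.7},
        effects={"G12D": DEEffectModel(mean_lfc=0.6, sd_lfc=0.5,
                                       frac_affected=0.6)},
    )
    truth = generate_de_table(spec, ["G12D"], seed=17, return_truth=True)
    table = truth.drop(columns=["is_affected"])
    report = ntrs_report(table)
    row = report[report.condition == "G12D"].iloc[0]
    kept = filter_de(table)
    kept_nuclear = build_panel(kept)
    pos = kept_nuclear.log2fc[kept_nuclear.log2fc > 0]
    neg = kept_nuclear.log2fc[kept_nuclear.log2fc < 0]
    assert row.ntrs_pos == pytest.approx(pos.mean())
    assert row.ntrs_neg == pytest.approx(neg.mean())
    se_pos = pos.std(ddof=1) / np.sqrt(len(pos))
    injected_pos = truth.loc[truth.is_affected & (truth.log2fc >= 0.75), "log2fc"]
    assert abs(row.ntrs_pos - injected_pos.mean()) < 3 * se_pos
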