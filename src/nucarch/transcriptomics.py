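"""Transcriptomic scoring of nuclear remodeling.

Operates on gene-level differential-expression tables (one row per
gene × condition with log2 fold change, FDR and a GO cellular-component
category).  The pipeline is: threshold filtering (FDR strictly below
0.05, |log2FC| ≥ 0.75 by default), subsetting to nuclear-annotated
categories (chromatin remodeling, nuclear membrane, nucleolus), and the
Nuclear Transcriptional Remodeling Score (NTRS): the unweighted
arithmetic mean of log2 fold changes, computed separately over
up-regulated (log2FC > 0) and down-regulated (log2FC < 0) panel genes.
An empty direction is reported as undefined — never as zero, which
would masquerade as a valid score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError
from .synthdata.specs import NUCLEAR_CATEGORIES

DEFAULT_FDR_MAX = 0.05
DEFAULT_MIN_ABS_LFC = 0.75

NTRS_COLUMNS = ["condition", "ntrs_pos", "n_pos", "ntrs_neg", "n_neg"]


def filter_de(
    records: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
) -> pd.DataFrame:
    """Keep records with ``fdr`` strictly below ``fdr_max`` and
    ``|log2fc| >= min_abs_lfc``.

    Records with a non-finite log2 fold change are rejected with a
    warning before thresholding.
    """
    if fdr_max <= 0 or min_abs_lfc <= 0:
        raise ValueError("thresholds must be positive")
    lfc = pd.to_numeric(records["log2fc"], errors="coerce")
    bad = ~np.isfinite(lfc)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} record(s) with non-finite log2fc",
            stacklevel=2,
        )
        records = records.loc[~bad.values]
        lfc = lfc[~bad.values]
    keep = (records["fdr"] < fdr_max) & (lfc.abs() >= min_abs_lfc)
    return records.loc[keep.values].copy()


def build_panel(
    filtered: pd.DataFrame,
    categories: set[str] | tuple[str, ...] = NUCLEAR_CATEGORIES,
) -> pd.DataFrame:
    """Subset filtered records to the given GO categories, ordered
    stably by gene id (then condition)."""
    categories = set(categories)
    if not categories:
        raise ValueError("categories must be non-empty")
    panel = filtered.loc[filtered["go_category"].isin(categories)]
    sort_cols = ["gene_id"] + (["condition"] if "condition" in panel.columns else [])
    return panel.sort_values(sort_cols, kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class NTRSResult:
    """Bidirectional remodeling score for one condition.

    ``ntrs_pos``/``ntrs_neg`` are ``None`` when the respective
    direction has no genes (undefined, not zero).
    """

    condition: str
    ntrs_pos: float | None
    n_pos: int
    ntrs_neg: float | None
    n_neg: int

    def __post_init__(self):
        if self.ntrs_pos is not None and self.ntrs_pos <= 0:
            raise ValueError("ntrs_pos must be positive when defined")
        if self.ntrs_neg is not None and self.ntrs_neg >= 0:
            raise ValueError("ntrs_neg must be negative when defined")


def compute_ntrs(panel: pd.DataFrame, condition: str = "") -> NTRSResult:
    """Mean log2FC of up- and down-regulated panel genes, separately.

    Genes with log2FC exactly zero belong to neither direction — the
    score partitions the panel into strictly positive and strictly
    negative values, each weighted equally with no scaling or ranking.
    """
    if not condition and "condition" in panel.columns and len(panel):
        uniq = panel["condition"].unique()
        if len(uniq) == 1:
            condition = str(uniq[0])
    lfc = panel["log2fc"].to_numpy(dtype=float) if len(panel) else np.empty(0)
    pos = lfc[lfc > 0]
    neg = lfc[lfc < 0]
    return NTRSResult(
        condition=condition,
        ntrs_pos=float(pos.mean()) if pos.size else None,
        n_pos=int(pos.size),
        ntrs_neg=float(neg.mean()) if neg.size else None,
        n_neg=int(neg.size),
    )


def ntrs_report(
    records: pd.DataFrame,
    fdr_max: float = DEFAULT_FDR_MAX,
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
    categories: set[str] | tuple[str, ...] = NUCLEAR_CATEGORIES,
) -> pd.DataFrame:
    """Full chain (filter → panel → NTRS) for every condition present."""
    filtered = filter_de(records, fdr_max, min_abs_lfc)
    rows = []
    for cond in pd.unique(records["condition"]):
        panel = build_panel(filtered.loc[filtered["condition"] == cond], categories)
        res = compute_ntrs(panel, condition=str(cond))
        rows.append(
            dict(
                condition=res.condition,
                ntrs_pos=np.nan if res.ntrs_pos is None else res.ntrs_pos,
                n_pos=res.n_pos,
                ntrs_neg=np.nan if res.ntrs_neg is None else res.ntrs_neg,
                n_neg=res.n_neg,
            )
        )
    return pd.DataFrame(rows, columns=NTRS_COLUMNS)


def sign_concordance(panel_a: pd.DataFrame, panel_b: pd.DataFrame) -> float:
    """Directional agreement between two condition panels, in [−1, 1].

    Over genes present and nonzero in both panels:
    (matching-sign pairs − opposite-sign pairs) / shared-gene count.
    Identical panels give +1; a sign-flipped copy gives −1.  Raises
    :class:`MissingDataError` when no gene is shared.
    """
    a = panel_a.set_index("gene_id")["log2fc"]
    b = panel_b.set_index("gene_id")["log2fc"]
    shared = a.index.intersection(b.index)
    if shared.empty:
        raise MissingDataError("panels share no genes; concordance undefined")
    sa = np.sign(a.loc[shared].to_numpy(dtype=float))
    sb = np.sign(b.loc[shared].to_numpy(dtype=float))
    nonzero = (sa != 0) & (sb != 0)
    if not nonzero.any():
        raise MissingDataError("no shared gene is nonzero in both panels")
    agree = int(np.sum(sa[nonzero] == sb[nonzero]))
    oppose = int(np.sum(sa[nonzero] != sb[nonzero]))
    return (agree - oppose) / int(nonzero.sum())
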