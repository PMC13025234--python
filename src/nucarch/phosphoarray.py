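"""Antibody phospho-array quantification chain.

The chain mirrors standard practice for paired phospho/total antibody
arrays: duplicate spots are summarized per antibody and slide
(average of per-replicate medians), each slide is normalized to its
global median signal, biological replicates are averaged after
normalization, each phospho site's signal is divided by its paired
total-protein signal, and the +doxycycline / −doxycycline fold change
of that ratio is thresholded at |log2FC| ≥ 1 (inclusive) to call sites
up, down or unchanged.  No significance testing is applied — calls are
threshold-based only.

Because the phospho/total ratio is formed within each condition and
the fold change across conditions, the chain is invariant to any
global scale factor per slide; per-slide median normalization removes
the residual slide effects that do not cancel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError, NormalizationError

CALL_COLUMNS = ["target", "site", "condition", "log2fc", "call"]
DEFAULT_THRESHOLD = 1.0


def summarize_spots(records: pd.DataFrame) -> float:
    """Summarize replicate spot signals for one antibody/condition/doxy
    group: the mean over replicates of the per-replicate median spot
    intensity (duplicate spots → mean of the two)."""
    if len(records) == 0:
        raise MissingDataError("no replicate spots to summarize")
    return float(records.groupby("replicate")["signal"].median().mean())


def normalize_global(signals: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Divide every signal on one array by the array-wide median.

    The post-normalization median is exactly 1, which also makes the
    operation idempotent and scale-invariant.
    """
    values = np.asarray(signals, dtype=float)
    if values.size == 0 or not np.any(values > 0):
        raise NormalizationError("cannot normalize an array with no positive signal")
    med = float(np.median(values))
    if med <= 0:
        raise NormalizationError("global median signal is not positive")
    if isinstance(signals, pd.Series):
        return signals / med
    return values / med


def phospho_ratio(phospho_signal: float, total_signal: float) -> float:
    """Phosphorylated / total signal ratio for one site.

    A non-positive total signal makes the site undefined: returns NaN
    with a warning so the site is excluded downstream.
    """
    if total_signal <= 0:
        warnings.warn("non-positive total-protein signal; site undefined", stacklevel=2)
        return float("nan")
    return float(phospho_signal) / float(total_signal)


@dataclass(frozen=True)
class SiteCall:
    target: str
    site: str
    condition: str
    log2fc: float
    call: str  # up | down | unchanged


def call_site(
    plus_doxy_ratio: float,
    minus_doxy_ratio: float,
    threshold: float = DEFAULT_THRESHOLD,
    target: str = "",
    site: str = "",
    condition: str = "",
) -> SiteCall:
    """Fold change of the phospho ratio (+doxy vs −doxy) and its call.

    Thresholds are inclusive: log2FC ≥ threshold → up,
    ≤ −threshold → down, otherwise unchanged.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not (plus_doxy_ratio > 0 and minus_doxy_ratio > 0):
        warnings.warn("non-positive ratio; site undefined", stacklevel=2)
        return SiteCall(target, site, condition, float("nan"), "undefined")
    lfc = float(np.log2(plus_doxy_ratio / minus_doxy_ratio))
    if lfc >= threshold:
        call = "up"
    elif lfc <= -threshold:
        call = "down"
    else:
        call = "unchanged"
    return SiteCall(target, site, condition, lfc, call)


def _normalized_antibody_values(table: pd.DataFrame) -> pd.DataFrame:
    """Per (antibody, condition, doxy): replicate-averaged, per-slide
    median-normalized summarized signal."""
    slide_frames = []
    for (cond, doxy, rep), slide in table.groupby(
        ["condition", "doxy", "replicate"], sort=True
    ):
        summarized = slide.groupby(
            ["antibody_id", "target", "is_phospho", "site"], sort=True
        )["signal"].median()
        normalized = normalize_global(summarized)
        df = normalized.rename("value").reset_index()
        df["condition"] = cond
        df["doxy"] = doxy
        slide_frames.append(df)
    values = pd.concat(slide_frames, ignore_index=True)
    return (
        values.groupby(
            ["antibody_id", "target", "is_phospho", "site", "condition", "doxy"],
            sort=True,
        )["value"]
        .mean()
        .reset_index()
    )


def score_array(
    table: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Run the full chain on a long-format spot table.

    Expects columns ``antibody_id, target, is_phospho, site, condition,
    doxy, replicate, signal`` with ``doxy`` in {"plus", "minus"}.
    Returns one row per (site × condition) with the log2 fold change of
    the phospho/total ratio and its call.  Sites whose paired
    total-protein antibody is absent raise
    :class:`~nucarch.errors.MissingDataError`; sites undefined because
    of non-positive signals are dropped with a warning.
    """
    values = _normalized_antibody_values(table)
    totals = values.loc[~values["is_phospho"]].set_index(["target", "condition", "doxy"])[
        "value"
    ]
    phospho = values.loc[values["is_phospho"]]
    unpaired = set(phospho["target"]) - set(
        values.loc[~values["is_phospho"], "target"]
    )
    if unpaired:
        raise MissingDataError(
            f"phospho antibodies without a paired total-protein antibody: "
            f"{sorted(unpaired)[:5]}"
        )
    rows = []
    n_undefined = 0
    for (target, site, cond), grp in phospho.groupby(
        ["target", "site", "condition"], sort=True
    ):
        vals = grp.set_index("doxy")["value"]
        if "plus" not in vals.index or "minus" not in vals.index:
            n_undefined += 1
            continue
        ratios = {}
        ok = True
        for doxy in ("plus", "minus"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r = phospho_ratio(float(vals[doxy]), float(totals[(target, cond, doxy)]))
            if not np.isfinite(r) or r <= 0:
                ok = False
                break
            ratios[doxy] = r
        if not ok:
            n_undefined += 1
            continue
        sc = call_site(
            ratios["plus"], ratios["minus"], threshold,
            target=target, site=site, condition=cond,
        )
        rows.append(dict(target=target, site=site, condition=cond,
                         log2fc=sc.log2fc, call=sc.call))
    if n_undefined:
        warnings.warn(f"excluded {n_undefined} undefined site(s)", stacklevel=2)
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def score_abundance(
    table: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Total-protein (abundance) layer: fold change of the normalized
    total signal itself, +doxy vs −doxy, without the ratio step."""
    values = _normalized_antibody_values(table)
    totals = values.loc[~values["is_phospho"]]
    rows = []
    for (target, cond), grp in totals.groupby(["target", "condition"], sort=True):
        vals = grp.set_index("doxy")["value"]
        if "plus" not in vals.index or "minus" not in vals.index:
            continue
        sc = call_site(
            float(vals["plus"]), float(vals["minus"]), threshold,
            target=target, site="", condition=cond,
        )
        rows.append(dict(target=target, site="", condition=cond,
                         log2fc=sc.log2fc, call=sc.call))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
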