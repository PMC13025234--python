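"""Synthetic differential-expression and phospho-array tables.

These generators emulate the statistical structure of the omics inputs
the scoring modules consume: a DESeq2-style gene table (log2FC, FDR,
GO cellular-component category per condition) and a long-format
antibody-array spot table with paired phospho/total antibodies,
duplicate spots, biological replicates and per-slide scale factors.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from ..errors import ConfigError
from .specs import (
    GO_CATEGORIES,
    NUCLEAR_CATEGORIES,
    DESimSpec,
    PhosphoSimSpec,
)

DE_COLUMNS = ["gene_id", "condition", "log2fc", "fdr", "go_category"]
ARRAY_COLUMNS = [
    "antibody_id", "target", "is_phospho", "site", "condition", "doxy",
    "replicate", "signal",
]


def generate_de_table(
    spec: DESimSpec,
    conditions: list[str],
    seed: int,
    return_truth: bool = False,
):
    """One row per gene x condition with log2FC, FDR and GO category.

    Gene-level structure is shared across conditions: each gene has a
    fixed GO category, a latent response direction and a responsiveness
    quantile, so a condition with a larger ``frac_affected`` perturbs a
    superset of the genes a weaker condition perturbs.  An ``invert``
    condition flips every responding gene's direction, which makes its
    sign concordance with any non-inverted condition negative by
    construction.
    """
    spec.validate()
    unknown = set(spec.effects) - set(conditions)
    if unknown:
        raise ConfigError("effect model references unknown conditions", sorted(unknown))

    ss = np.random.SeedSequence(int(seed))
    rng_genes, rng_cond = (np.random.default_rng(s) for s in ss.spawn(2))

    n = spec.n_genes
    width = max(4, len(str(n)))
    gene_ids = np.array([f"GENE{i:0{width}d}" for i in range(1, n + 1)])
    fractions = [spec.category_fractions[c] for c in GO_CATEGORIES]
    categories = rng_genes.choice(GO_CATEGORIES, size=n, p=fractions)
    directions = rng_genes.choice([-1.0, 1.0], size=n)
    responsiveness = rng_genes.uniform(size=n)  # shared quantile -> nested affected sets
    nuclear = np.isin(categories, NUCLEAR_CATEGORIES)

    frames = []
    for cond in conditions:
        eff = spec.effects.get(cond)
        lfc = rng_cond.normal(0.0, spec.null_sd, size=n)
        fdr = rng_cond.uniform(size=n)
        affected = np.zeros(n, dtype=bool)
        if eff is not None and eff.frac_affected > 0:
            affected = nuclear & (responsiveness < eff.frac_affected)
            sign = -1.0 if eff.invert else 1.0
            magnitudes = np.abs(rng_cond.normal(eff.mean_lfc, eff.sd_lfc, size=n))
            lfc = np.where(affected, sign * directions * magnitudes, lfc)
            hit = rng_cond.uniform(size=n) < eff.fdr_hit_prob
            fdr_aff = np.where(
                hit,
                rng_cond.uniform(0.0, 0.05, size=n),
                rng_cond.uniform(0.05, 1.0, size=n),
            )
            fdr = np.where(affected, fdr_aff, fdr)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "condition": cond,
                    "log2fc": lfc,
                    "fdr": fdr,
                    "go_category": categories,
                    "is_affected": affected,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    if return_truth:
        return table
    return table.drop(columns=["is_affected"])


def generate_phospho_array(
    spec: PhosphoSimSpec,
    conditions: list[str],
    seed: int,
    return_truth: bool = False,
):
    """Paired ±doxycycline antibody-array spot table.

    Every phospho antibody (one per site) is paired with the
    total-protein antibody of its target; targets are assigned to sites
    round-robin so every total antibody backs at least one site.
    Signals are lognormal around a per-antibody baseline, modulated by
    a per-slide scale factor, per-spot technical noise, and — for
    affected sites in the +doxy state — the injected fold change.
    """
    spec.validate()
    unknown = set(spec.effects) - set(conditions)
    if unknown:
        raise ConfigError("effect model references unknown conditions", sorted(unknown))

    ss = np.random.SeedSequence(int(seed))
    rng_layout, rng_signal = (np.random.default_rng(s) for s in ss.spawn(2))

    n_sites, n_targets = spec.n_sites, spec.n_targets
    targets = np.array([f"PROT{i:04d}" for i in range(1, n_targets + 1)])
    site_target_idx = np.arange(n_sites) % n_targets
    sites = np.array([f"S{100 + i}" for i in range(n_sites)])

    # antibody table: one total per target, one phospho per site
    total_ids = np.array([f"AB-T{i:04d}" for i in range(1, n_targets + 1)])
    phospho_ids = np.array([f"AB-P{i:04d}" for i in range(1, n_sites + 1)])

    log_total = math.log(spec.baseline_median) + rng_layout.normal(
        0.0, spec.baseline_log_sd, size=n_targets
    )
    # site stoichiometry: phospho baseline is a fraction of its total signal
    log_ratio0 = rng_layout.normal(math.log(0.5), 0.4, size=n_sites)
    log_phospho = log_total[site_target_idx] + log_ratio0

    rows = []
    truth_rows = []
    for cond in conditions:
        eff = spec.effects.get(cond)
        affected = np.zeros(n_sites, dtype=bool)
        lfc_sites = np.zeros(n_sites)
        if eff is not None and eff.frac_sites > 0:
            affected = rng_signal.uniform(size=n_sites) < eff.frac_sites
            lfc_sites = np.where(
                affected, rng_signal.normal(eff.mean_lfc, eff.sd_lfc, size=n_sites), 0.0
            )
        for site, tgt_idx, is_aff, lfc in zip(sites, site_target_idx, affected, lfc_sites):
            if is_aff:
                truth_rows.append(
                    dict(condition=cond, target=targets[tgt_idx], site=site, log2fc=lfc)
                )
        for doxy in ("minus", "plus"):
            for rep in range(1, spec.n_replicates + 1):
                slide_scale = rng_signal.normal(0.0, spec.slide_log_sd)
                # totals
                noise_t = rng_signal.normal(
                    0.0, spec.spot_log_sd, size=(n_targets, spec.n_spots)
                )
                sig_t = np.exp(log_total[:, None] + slide_scale + noise_t)
                # phospho (+ injected effect in the +doxy state)
                shift = lfc_sites * math.log(2.0) if doxy == "plus" else np.zeros(n_sites)
                noise_p = rng_signal.normal(
                    0.0, spec.spot_log_sd, size=(n_sites, spec.n_spots)
                )
                sig_p = np.exp(log_phospho[:, None] + shift[:, None] + slide_scale + noise_p)
                for spot in range(spec.n_spots):
                    rows.append(
                        pd.DataFrame(
                            {
                                "antibody_id": total_ids,
                                "target": targets,
                                "is_phospho": False,
                                "site": "",
                                "condition": cond,
                                "doxy": doxy,
                                "replicate": rep,
                                "signal": sig_t[:, spot],
                            }
                        )
                    )
                    rows.append(
                        pd.DataFrame(
                            {
                                "antibody_id": phospho_ids,
                                "target": targets[site_target_idx],
                                "is_phospho": True,
                                "site": sites,
                                "condition": cond,
                                "doxy": doxy,
                                "replicate": rep,
                                "signal": sig_p[:, spot],
                            }
                        )
                    )
    table = pd.concat(rows, ignore_index=True)[ARRAY_COLUMNS]
    if return_truth:
        truth = pd.DataFrame(truth_rows, columns=["condition", "target", "site", "log2fc"])
        return table, truth
    return table
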