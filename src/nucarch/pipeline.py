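"""End-to-end orchestration: simulate → segment → measure → report.

A single YAML configuration describes the cohorts (condition ×
timepoint), the imaging geometry and noise, per-channel segmentation
parameters, and the omics simulation specs.  All randomness flows from
one master seed; every stage derives an independent substream from a
stable hash of the stage name, so reruns are byte-identical and stages
are individually reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import io as nio
from .errors import ConfigError, MissingDataError
from .geometry import ImageGeometry
from .morphometry2d import (
    SegmentationParams,
    assign_compartments,
    freeze_threshold,
    measure_2d,
    segment_2d,
)
from .morphometry3d import measure_3d, segment_3d
from .phosphoarray import score_abundance, score_array
from .reporting import build_report
from .synthdata import (
    CHANNEL_ORDER,
    NUCLEUS,
    CompartmentSpec,
    DEEffectModel,
    DESimSpec,
    NoiseSpec,
    NuclearPhenotypeSpec,
    PhosphoEffectModel,
    PhosphoSimSpec,
    generate_cohort,
    generate_de_table,
    generate_phospho_array,
)
from .transcriptomics import build_panel, filter_de, ntrs_report, sign_concordance

__version__ = "0.1.0"


def derive_seed(master_seed: int, *tokens) -> int:
    """Stable (platform-independent) substream seed below 2**31."""
    digest = hashlib.sha256(
        ":".join([str(master_seed), *map(str, tokens)]).encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# configuration


def _check_keys(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {context}", sorted(unknown))


@dataclass
class CohortConfig:
    condition: str
    timepoint_h: float
    nuclei_2d: NuclearPhenotypeSpec | None = None
    nuclei_3d: NuclearPhenotypeSpec | None = None
    compartments_2d: list[CompartmentSpec] = field(default_factory=list)
    compartments_3d: list[CompartmentSpec] = field(default_factory=list)


@dataclass
class ImagingConfig:
    mode: str = "both"  # 2d | 3d | both
    n_images_2d: int = 3
    n_images_3d: int = 1
    geometry_2d: ImageGeometry = field(
        default_factory=lambda: ImageGeometry((1024, 1024), (0.1, 0.1))
    )
    geometry_3d: ImageGeometry = field(
        default_factory=lambda: ImageGeometry((64, 256, 256), (0.3, 0.35, 0.35))
    )
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    segmentation: dict[str, SegmentationParams] = field(default_factory=dict)
    freeze_thresholds: bool = True
    cohorts: list[CohortConfig] = field(default_factory=list)

    @property
    def dims(self) -> list[int]:
        return {"2d": [2], "3d": [3], "both": [2, 3]}[self.mode]


@dataclass
class OmicsConfig:
    de: DESimSpec | None = None
    de_conditions: list[str] = field(default_factory=list)
    reference_condition: str | None = None
    phospho: PhosphoSimSpec | None = None
    phospho_conditions: list[str] = field(default_factory=list)
    threshold: float = 1.0


@dataclass
class RunConfig:
    seed: int | None = None
    outdir: str | None = None
    report_format: str = "csv"
    imaging: ImagingConfig | None = None
    omics: OmicsConfig | None = None
    raw: dict = field(default_factory=dict)


def _parse_phenotype(d: dict, context: str) -> NuclearPhenotypeSpec:
    _check_keys(
        d,
        {"n_cells", "mean_size", "size_cv", "irregularity_amplitude",
         "irregularity_harmonics", "target_shape"},
        context,
    )
    try:
        spec = NuclearPhenotypeSpec(**d)
        spec.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid nuclei spec in {context}: {exc}") from exc
    return spec


def _parse_compartments(items: list, context: str) -> list[CompartmentSpec]:
    specs = []
    for i, d in enumerate(items):
        _check_keys(
            d, {"marker", "count_mean", "size_mean", "size_sigma", "nesting"},
            f"{context}[{i}]",
        )
        try:
            spec = CompartmentSpec(**d)
            spec.validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid compartment in {context}[{i}]: {exc}") from exc
        specs.append(spec)
    return specs


def _parse_geometry(d: dict, context: str) -> ImageGeometry:
    _check_keys(d, {"shape", "spacing"}, context)
    return ImageGeometry(tuple(d["shape"]), tuple(d["spacing"]))


def _parse_segmentation(d: dict, context: str) -> dict[str, SegmentationParams]:
    params = {}
    for channel, p in d.items():
        if channel not in CHANNEL_ORDER:
            raise ConfigError(f"unknown channel in {context}", [channel])
        _check_keys(
            p, {"smoothing_sigma", "threshold", "min_size", "fill_holes",
                "exclude_border"},
            f"{context}.{channel}",
        )
        try:
            sp = SegmentationParams(**p)
            sp.validate()
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid segmentation in {context}.{channel}: {exc}") from exc
        params[channel] = sp
    return params


def parse_config(data: dict) -> RunConfig:
    """Validate and materialize a configuration mapping.

    Raises :class:`~nucarch.errors.ConfigError` naming every offending
    key on structural problems.
    """
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(
        data, {"seed", "outdir", "report_format", "imaging", "omics"}, "config"
    )
    cfg = RunConfig(
        seed=data.get("seed"),
        outdir=data.get("outdir"),
        report_format=data.get("report_format", "csv"),
        raw=data,
    )
    if cfg.report_format not in ("csv", "json"):
        raise ConfigError("report_format must be csv or json", [cfg.report_format])

    if "imaging" in data:
        d = data["imaging"]
        _check_keys(
            d,
            {"mode", "n_images_2d", "n_images_3d", "geometry_2d", "geometry_3d",
             "noise", "segmentation", "freeze_thresholds", "cohorts"},
            "imaging",
        )
        img = ImagingConfig()
        img.mode = d.get("mode", "both")
        if img.mode not in ("2d", "3d", "both"):
            raise ConfigError("imaging.mode must be 2d, 3d or both", [img.mode])
        img.n_images_2d = int(d.get("n_images_2d", img.n_images_2d))
        img.n_images_3d = int(d.get("n_images_3d", img.n_images_3d))
        if "geometry_2d" in d:
            img.geometry_2d = _parse_geometry(d["geometry_2d"], "imaging.geometry_2d")
        if "geometry_3d" in d:
            img.geometry_3d = _parse_geometry(d["geometry_3d"], "imaging.geometry_3d")
        if "noise" in d:
            _check_keys(
                d["noise"],
                {"background", "psf_sigma", "gaussian_sigma", "photon_scale"},
                "imaging.noise",
            )
            img.noise = NoiseSpec(**d["noise"])
            img.noise.validate()
        if "segmentation" in d:
            img.segmentation = _parse_segmentation(d["segmentation"], "imaging.segmentation")
        img.freeze_thresholds = bool(d.get("freeze_thresholds", True))
        seen = set()
        for i, c in enumerate(d.get("cohorts", [])):
            _check_keys(
                c,
                {"condition", "timepoint_h", "nuclei_2d", "nuclei_3d",
                 "compartments_2d", "compartments_3d"},
                f"imaging.cohorts[{i}]",
            )
            key = (c["condition"], float(c["timepoint_h"]))
            if key in seen:
                raise ConfigError("duplicate cohort (condition, timepoint)", [key])
            seen.add(key)
            img.cohorts.append(
                CohortConfig(
                    condition=str(c["condition"]),
                    timepoint_h=float(c["timepoint_h"]),
                    nuclei_2d=_parse_phenotype(c["nuclei_2d"], f"imaging.cohorts[{i}].nuclei_2d")
                    if "nuclei_2d" in c else None,
                    nuclei_3d=_parse_phenotype(c["nuclei_3d"], f"imaging.cohorts[{i}].nuclei_3d")
                    if "nuclei_3d" in c else None,
                    compartments_2d=_parse_compartments(
                        c.get("compartments_2d", []), f"imaging.cohorts[{i}].compartments_2d"),
                    compartments_3d=_parse_compartments(
                        c.get("compartments_3d", []), f"imaging.cohorts[{i}].compartments_3d"),
                )
            )
        cfg.imaging = img

    if "omics" in data:
        d = data["omics"]
        _check_keys(
            d, {"de", "phospho", "reference_condition", "threshold"}, "omics"
        )
        om = OmicsConfig()
        om.reference_condition = d.get("reference_condition")
        om.threshold = float(d.get("threshold", 1.0))
        if "de" in d:
            de = dict(d["de"])
            conds = de.pop("conditions", {})
            _check_keys(
                de, {"n_genes", "category_fractions", "null_sd"}, "omics.de"
            )
            effects = {}
            order = []
            for cond, eff in conds.items():
                order.append(str(cond))
                if eff:
                    _check_keys(
                        eff,
                        {"mean_lfc", "sd_lfc", "frac_affected", "invert",
                         "fdr_hit_prob"},
                        f"omics.de.conditions.{cond}",
                    )
                    effects[str(cond)] = DEEffectModel(**eff)
            om.de = DESimSpec(effects=effects, **de)
            om.de.validate()
            om.de_conditions = order
        if "phospho" in d:
            ph = dict(d["phospho"])
            conds = ph.pop("conditions", {})
            _check_keys(
                ph,
                {"n_sites", "n_targets", "n_spots", "n_replicates",
                 "baseline_median", "baseline_log_sd", "spot_log_sd",
                 "slide_log_sd"},
                "omics.phospho",
            )
            effects = {}
            order = []
            for cond, eff in conds.items():
                order.append(str(cond))
                if eff:
                    _check_keys(
                        eff, {"mean_lfc", "sd_lfc", "frac_sites"},
                        f"omics.phospho.conditions.{cond}",
                    )
                    effects[str(cond)] = PhosphoEffectModel(**eff)
            om.phospho = PhosphoSimSpec(effects=effects, **ph)
            om.phospho.validate()
            om.phospho_conditions = order
        cfg.omics = om
    return cfg


def load_config(path: str | Path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return parse_config(data or {})


# ---------------------------------------------------------------------------
# manifest


def _config_hash(raw: dict, seed: int) -> str:
    payload = json.dumps({"config": raw, "seed": seed}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def _finalize_manifest(manifest: dict, outdir: Path) -> Path:
    # the content hash excludes the timestamp, so identical runs carry
    # identical hashes even though 'created_utc' differs
    hashable = {k: v for k, v in manifest.items() if k != "created_utc"}
    manifest["content_hash"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True, default=str).encode()
    ).hexdigest()
    return nio.write_json(outdir / "manifest.json", manifest)


def _new_manifest(cfg: RunConfig, seed: int, stage: str) -> dict:
    return {
        "stage": stage,
        "seed": seed,
        "config_hash": _config_hash(cfg.raw, seed),
        "version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "stages": {},
        "files": [],
    }


# ---------------------------------------------------------------------------
# imaging stage

_DEFAULT_SEG_2D = {
    NUCLEUS: SegmentationParams(smoothing_sigma=0.2, min_size=20.0),
    "nucleolin": SegmentationParams(smoothing_sigma=0.1, min_size=0.3,
                                    exclude_border=False),
    "fibrillarin": SegmentationParams(smoothing_sigma=0.1, min_size=0.2,
                                      exclude_border=False),
    "sc35": SegmentationParams(smoothing_sigma=0.1, min_size=0.2,
                               exclude_border=False),
}
_DEFAULT_SEG_3D = {
    NUCLEUS: SegmentationParams(smoothing_sigma=0.3, min_size=100.0),
    "nucleolin": SegmentationParams(smoothing_sigma=0.15, min_size=1.0,
                                    exclude_border=False),
    "fibrillarin": SegmentationParams(smoothing_sigma=0.15, min_size=0.4,
                                      exclude_border=False),
    "sc35": SegmentationParams(smoothing_sigma=0.15, min_size=0.4,
                               exclude_border=False),
}

_PARENT_OF = {"nucleolin": NUCLEUS, "fibrillarin": "nucleolin", "sc35": NUCLEUS}


def _seg_params(cfg: ImagingConfig, dim: int, channel: str) -> SegmentationParams:
    if channel in cfg.segmentation:
        return cfg.segmentation[channel]
    defaults = _DEFAULT_SEG_2D if dim == 2 else _DEFAULT_SEG_3D
    return defaults[channel]


def _measure_image(image, dim: int, params_by_channel) -> pd.DataFrame:
    """Segment + measure every channel of one image; returns the
    per-object table with parent assignments."""
    segment = segment_2d if dim == 2 else segment_3d
    measure = measure_2d if dim == 2 else measure_3d
    labeled = {}
    frames = []
    for channel in CHANNEL_ORDER:
        labeled[channel] = segment(
            image.channels[channel], image.geometry, params_by_channel[channel],
            source_channel=channel,
        )
    for channel in CHANNEL_ORDER:
        metrics = measure(labeled[channel])
        metrics.insert(0, "channel", channel)
        parent = _PARENT_OF.get(channel)
        if parent is None:
            metrics["parent_label"] = 0
        else:
            assignment = assign_compartments(labeled[parent], labeled[channel])
            metrics["parent_label"] = [
                assignment.mapping.get(int(lbl), 0) for lbl in metrics["label"]
            ]
        if len(metrics):
            frames.append(metrics)
    if not frames:
        cols = list(metrics.columns)
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)


_METRIC_OF = {2: ("area_um2", "circularity"), 3: ("volume_um3", "sphericity")}


def _long_rows(per_object: pd.DataFrame, dim: int, condition: str, tp: float):
    """Per-object metric rows for the condition-level report.

    Nuclei contribute size and shape; compartments contribute size and
    shape of each object, restricted to objects assigned to a parent
    (orphans of border-excluded nuclei are dropped).
    """
    size_col, shape_col = _METRIC_OF[dim]
    rows = []
    for channel, grp in per_object.groupby("channel", sort=True):
        if channel != NUCLEUS:
            grp = grp.loc[grp["parent_label"] > 0]
        for _, r in grp.iterrows():
            rows.append((condition, tp, f"{channel}_{size_col}", r[size_col]))
            rows.append((condition, tp, f"{channel}_{shape_col}", r[shape_col]))
    return rows


def run_imaging(cfg: RunConfig, seed: int, outdir: str | Path) -> dict:
    """Simulate, segment, measure and report every imaging cohort."""
    if cfg.imaging is None or not cfg.imaging.cohorts:
        raise ConfigError("configuration has no imaging cohorts")
    img_cfg = cfg.imaging
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _new_manifest(cfg, seed, "imaging")

    for dim in img_cfg.dims:
        tag = f"{dim}d"
        geometry = img_cfg.geometry_2d if dim == 2 else img_cfg.geometry_3d
        n_images = img_cfg.n_images_2d if dim == 2 else img_cfg.n_images_3d
        cohorts = [
            c for c in img_cfg.cohorts
            if (c.nuclei_2d if dim == 2 else c.nuclei_3d) is not None
        ]
        if not cohorts:
            continue
        params_by_channel = {
            ch: _seg_params(img_cfg, dim, ch) for ch in CHANNEL_ORDER
        }
        long_rows = []
        object_frames = []
        conditions = sorted({c.condition for c in cohorts})
        for condition in conditions:
            mine = sorted(
                (c for c in cohorts if c.condition == condition),
                key=lambda c: c.timepoint_h,
            )
            images_by_tp = {}
            for cohort in mine:
                spec = cohort.nuclei_2d if dim == 2 else cohort.nuclei_3d
                comps = cohort.compartments_2d if dim == 2 else cohort.compartments_3d
                cohort_seed = derive_seed(seed, tag, condition, cohort.timepoint_h)
                images = generate_cohort(
                    spec, comps, img_cfg.noise, geometry, cohort_seed, n_images
                )
                images_by_tp[cohort.timepoint_h] = images
                for i, image in enumerate(images):
                    image_id = f"{condition}_{cohort.timepoint_h:g}h_{tag}_{i:02d}"
                    path = nio.write_image(outdir / f"{image_id}.tif", image)
                    manifest["files"].append(path.name)
                    truth = image.truth_metrics.copy()
                    truth.insert(0, "image_id", image_id)
                    tpath = nio.write_table(outdir / f"{image_id}_truth.csv", truth)
                    manifest["files"].append(tpath.name)
            params_local = dict(params_by_channel)
            if img_cfg.freeze_thresholds:
                if 0.0 not in images_by_tp:
                    raise MissingDataError(
                        f"freeze_thresholds requires a 0 h cohort for {condition}"
                    )
                for ch in CHANNEL_ORDER:
                    t = freeze_threshold(
                        [im.channels[ch] for im in images_by_tp[0.0]],
                        geometry,
                        params_local[ch],
                    )
                    params_local[ch] = params_local[ch].with_threshold(t)
            for cohort in mine:
                for i, image in enumerate(images_by_tp[cohort.timepoint_h]):
                    image_id = f"{condition}_{cohort.timepoint_h:g}h_{tag}_{i:02d}"
                    per_object = _measure_image(image, dim, params_local)
                    per_object.insert(0, "image_id", image_id)
                    object_frames.append(per_object)
                    long_rows.extend(
                        _long_rows(per_object, dim, condition, cohort.timepoint_h)
                    )
        objects = pd.concat(object_frames, ignore_index=True)
        opath = nio.write_table(outdir / f"objects_{tag}.csv", objects)
        manifest["files"].append(opath.name)
        measurements = pd.DataFrame(
            long_rows, columns=["condition", "timepoint_h", "metric", "value"]
        )
        mpath = nio.write_table(outdir / f"measurements_{tag}.csv", measurements)
        manifest["files"].append(mpath.name)
        report = build_report(measurements)
        rpath = nio.write_table(outdir / f"report_{tag}.csv", report)
        manifest["files"].append(rpath.name)
        if cfg.report_format == "json":
            jpath = nio.write_json(
                outdir / f"report_{tag}.json",
                {"report": report.to_dict(orient="records")},
            )
            manifest["files"].append(jpath.name)
        manifest["stages"][f"imaging_{tag}"] = "completed"
    _finalize_manifest(manifest, outdir)
    return manifest


def report_from_measurements(measurements_csv: str | Path, out_csv: str | Path) -> Path:
    """Stage isolation: rebuild the condition report from an existing
    long-format measurements table."""
    measurements = nio.read_table(measurements_csv)
    report = build_report(measurements)
    return nio.write_table(out_csv, report)


# ---------------------------------------------------------------------------
# omics stage


def run_omics(cfg: RunConfig, seed: int, outdir: str | Path) -> dict:
    """Simulate omics tables and run the scoring chains."""
    if cfg.omics is None or (cfg.omics.de is None and cfg.omics.phospho is None):
        raise ConfigError("configuration has no omics specs")
    om = cfg.omics
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _new_manifest(cfg, seed, "omics")

    if om.de is not None:
        de_table = generate_de_table(
            om.de, om.de_conditions, derive_seed(seed, "de")
        )
        manifest["files"].append(
            nio.write_table(outdir / "de_table.csv", de_table).name
        )
        ntrs = ntrs_report(de_table)
        manifest["files"].append(nio.write_table(outdir / "ntrs.csv", ntrs).name)
        ref = om.reference_condition or om.de_conditions[0]
        filtered = filter_de(de_table)
        panels = {
            cond: build_panel(filtered.loc[filtered["condition"] == cond])
            for cond in om.de_conditions
        }
        rows = []
        for cond in om.de_conditions:
            if cond == ref:
                continue
            try:
                value = sign_concordance(panels[cond], panels[ref])
                n_shared = len(
                    set(panels[cond]["gene_id"]) & set(panels[ref]["gene_id"])
                )
            except MissingDataError:
                value, n_shared = float("nan"), 0
            rows.append(
                dict(condition=cond, reference=ref, concordance=value,
                     n_shared=n_shared)
            )
        manifest["files"].append(
            nio.write_table(
                outdir / "concordance.csv",
                pd.DataFrame(rows, columns=["condition", "reference",
                                            "concordance", "n_shared"]),
            ).name
        )
        manifest["stages"]["omics_de"] = "completed"

    if om.phospho is not None:
        array = generate_phospho_array(
            om.phospho, om.phospho_conditions, derive_seed(seed, "phospho")
        )
        manifest["files"].append(
            nio.write_table(outdir / "phospho_table.csv", array).name
        )
        calls = score_array(array, threshold=om.threshold)
        manifest["files"].append(
            nio.write_table(outdir / "phospho_calls.csv", calls).name
        )
        abundance = score_abundance(array, threshold=om.threshold)
        manifest["files"].append(
            nio.write_table(outdir / "abundance_calls.csv", abundance).name
        )
        manifest["stages"]["omics_phospho"] = "completed"

    _finalize_manifest(manifest, outdir)
    return manifest


def run_all(cfg: RunConfig, seed: int, outdir: str | Path) -> dict:
    outdir = Path(outdir)
    manifests = {}
    if cfg.imaging is not None and cfg.imaging.cohorts:
        manifests["imaging"] = run_imaging(cfg, seed, outdir / "imaging")
    if cfg.omics is not None and (cfg.omics.de or cfg.omics.phospho):
        manifests["omics"] = run_omics(cfg, seed, outdir / "omics")
    combined = _new_manifest(cfg, seed, "run-all")
    combined["stages"] = {
        name: m["stages"] for name, m in manifests.items()
    }
    combined["files"] = sorted(
        f"{name}/{f}" for name, m in manifests.items() for f in m["files"]
    )
    _finalize_manifest(combined, outdir)
    return combined


# ---------------------------------------------------------------------------
# demo configuration


def demo_config(scale: float = 1.0) -> dict:
    """Configuration emulating the G12D / G12R imaging time course.

    Generator means follow the published condition-level values
    (nucleolar areas 1.72 → 2.43 → 2.65 µm² under G12D, circularity
    0.84 → 0.88, nuclear volume 823 µm³ with sphericity 0.68 → 0.79,
    and the weaker G12R trajectory).  ``scale`` < 1 shrinks cell counts
    for quick smoke runs.
    """

    def n(k):
        return max(4, int(round(k * scale)))

    def cohort(cond, tp, circ, area2d, nucleolin2, fibrillarin2, sc352,
               vol3d, sph, nucleolin3, fibrillarin3, sc353):
        return {
            "condition": cond,
            "timepoint_h": tp,
            "nuclei_2d": {
                "n_cells": n(29), "mean_size": area2d, "size_cv": 0.2,
                "irregularity_harmonics": 4, "target_shape": circ,
            },
            "compartments_2d": [
                {"marker": "nucleolin", "count_mean": 3.0,
                 "size_mean": nucleolin2, "size_sigma": 0.45},
                {"marker": "fibrillarin", "count_mean": 3.0,
                 "size_mean": fibrillarin2, "size_sigma": 0.45,
                 "nesting": "nucleolin"},
                {"marker": "sc35", "count_mean": 12.0,
                 "size_mean": sc352, "size_sigma": 0.4},
            ],
            "nuclei_3d": {
                "n_cells": n(4), "mean_size": vol3d, "size_cv": 0.15,
                "irregularity_harmonics": 0, "target_shape": sph,
            },
            "compartments_3d": [
                {"marker": "nucleolin", "count_mean": 3.0,
                 "size_mean": nucleolin3, "size_sigma": 0.35},
                {"marker": "fibrillarin", "count_mean": 2.0,
                 "size_mean": fibrillarin3, "size_sigma": 0.35,
                 "nesting": "nucleolin"},
                {"marker": "sc35", "count_mean": 8.0,
                 "size_mean": sc353, "size_sigma": 0.35},
            ],
        }

    # fibrillarin foci must nest inside nucleolin-defined nucleoli, so
    # their generator sizes are smaller than the nucleolar areas while
    # following the published fold trajectories (+30 %/+41 % under
    # G12D, +25 % under G12R)
    cohorts = [
        # G12D: nucleolar expansion, nuclear rounding/compaction
        cohort("G12D", 0, 0.84, 160.0, 1.72, 0.60, 1.00, 823.0, 0.68, 6.0, 0.7, 1.0),
        cohort("G12D", 24, 0.88, 160.0, 2.43, 0.78, 1.31, 762.2, 0.71, 10.3, 0.62, 1.60),
        cohort("G12D", 48, 0.88, 134.0, 2.65, 0.85, 1.39, 773.3, 0.79, 11.7, 0.7, 1.71),
        # G12R: limited, delayed remodeling
        cohort("G12R", 0, 0.86, 160.0, 1.88, 0.60, 1.00, 917.9, 0.72, 6.0, 0.7, 1.0),
        cohort("G12R", 24, 0.86, 160.0, 2.19, 0.75, 1.16, 924.0, 0.71, 6.0, 0.8, 1.17),
        cohort("G12R", 48, 0.84, 160.0, 2.19, 0.75, 1.21, 1012.0, 0.72, 6.0, 0.7, 1.12),
    ]
    return {
        "report_format": "csv",
        "imaging": {
            "mode": "both",
            "n_images_2d": 7,
            "n_images_3d": 2,
            "geometry_2d": {"shape": [2560, 2560], "spacing": [0.1, 0.1]},
            "geometry_3d": {"shape": [64, 256, 256], "spacing": [0.3, 0.35, 0.35]},
            "noise": {"background": 200.0, "psf_sigma": 0.15,
                      "gaussian_sigma": 80.0, "photon_scale": 0.0},
            "freeze_thresholds": True,
            "cohorts": cohorts,
        },
        "omics": {
            "reference_condition": "G12D",
            "threshold": 1.0,
            "de": {
                "n_genes": 2000,
                "null_sd": 0.25,
                "conditions": {
                    "Empty": None,
                    "G12D": {"mean_lfc": 1.3, "sd_lfc": 0.4, "frac_affected": 0.5},
                    "G12R": {"mean_lfc": 0.95, "sd_lfc": 0.3, "frac_affected": 0.2},
                    "S17N": {"mean_lfc": 1.3, "sd_lfc": 0.4, "frac_affected": 0.5,
                             "invert": True},
                },
            },
            "phospho": {
                "conditions": {
                    "G12D": {"mean_lfc": 1.3, "sd_lfc": 0.2, "frac_sites": 0.05},
                    "G12R": {"mean_lfc": 0.6, "sd_lfc": 0.2, "frac_sites": 0.02},
                },
            },
        },
    }
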