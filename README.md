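# nucarch

Quantitative analysis of nuclear architecture remodeling, built for
imaging/omics studies that compare oncogene variants (e.g. KRAS G12D
vs G12R in pancreatic ductal epithelial cells) by how strongly they
reorganize the nucleus: nuclear size and shape, nucleolar
sub-compartments (nucleolin, fibrillarin), and spliceosomal speckles
(SC-35), together with matched transcriptomic and phospho-proteomic
scores.

The package provides, as a library plus a `nucarch` command line:

- **Synthetic data with ground truth** — seeded multi-channel 2D
  fields and 3D stacks of nuclei with nested sub-compartments, plus
  differential-expression and antibody-array tables with injected
  effects, so every downstream measurement can be validated against
  known truth.
- **2D morphometry** — segmentation and per-object area, perimeter and
  circularity `4πA/P²` in physical units (1 = perfect circle).
- **3D morphometry** — volume, iso-surface area and sphericity
  `Ψ = π^{1/3}(6V)^{2/3}/SA` (1 = perfect ball), with anisotropic
  voxels.
- **NTRS** — the Nuclear Transcriptional Remodeling Score: after
  filtering differentially expressed genes (FDR < 0.05,
  |log2FC| ≥ 0.75) and subsetting to nuclear GO cellular-component
  categories (chromatin remodeling, nuclear membrane, nucleolus), the
  unweighted mean log2 fold change of up- and down-regulated panel
  genes, reported separately; plus cross-variant sign concordance.
- **Phospho-array scoring** — duplicate-spot summarization, per-slide
  global-median normalization, phospho/total signal ratios,
  ±doxycycline fold changes, and threshold calls (|log2FC| ≥ 1,
  inclusive).
- **Condition reports** — mean ± SD, t-based 95 % CIs, percent change
  vs the 0-h baseline, one-way-ANOVA-pooled contrasts with Sidak
  correction (`p_adj = 1 − (1−p)^m`), and star codes
  (`* p < 0.05 … **** p < 0.0001`).

## Worked example

Simulate a small field of nuclei with target circularity 0.84, segment
and measure it, and evaluate the two scoring helpers:

```python
import pandas as pd
from nucarch import (SegmentationParams, compute_ntrs, measure_2d,
                     percent_change, round_half_away, segment_2d)
from nucarch.geometry import ImageGeometry
from nucarch.synthdata import (CompartmentSpec, NoiseSpec,
                               NuclearPhenotypeSpec, generate_image)

geom = ImageGeometry((1280, 1280), (0.1, 0.1))        # 128 µm field
spec = NuclearPhenotypeSpec(n_cells=8, mean_size=160.0, size_cv=0.2,
                            target_shape=0.84)
nucleoli = CompartmentSpec("nucleolin", count_mean=3.0,
                           size_mean=1.72, size_sigma=0.45)
image = generate_image(spec, [nucleoli], NoiseSpec(), geom, seed=7)

nuclei = segment_2d(image.channels["dna"], geom,
                    SegmentationParams(smoothing_sigma=0.2, min_size=20.0))
metrics = measure_2d(nuclei)
print(f"nuclei: {len(metrics)}  mean area {metrics.area_um2.mean():.1f} um^2  "
      f"mean circularity {metrics.circularity.mean():.3f}")

pct = percent_change(1.72, 2.43)
print(f"nucleolin area 1.72 -> 2.43 um^2: {round_half_away(pct, 0):+.0f}%")

panel = pd.DataFrame({
    "gene_id": ["SOX9", "NOS1AP", "CCD86", "HDAC5", "ABTB1", "SATB1"],
    "condition": "G12R",
    "log2fc": [0.85, 0.84, 0.30, 0.16, 0.03, -0.05],
    "fdr": 0.01, "go_category": "chromatin_remodeling"})
res = compute_ntrs(panel)
print(f"NTRS(G12R six-gene subset): +{res.ntrs_pos:.3f} (n={res.n_pos}), "
      f"{res.ntrs_neg:.2f} (n={res.n_neg})")
```

prints

```
nuclei: 8  mean area 171.8 um^2  mean circularity 0.841
nucleolin area 1.72 -> 2.43 um^2: +41%
NTRS(G12R six-gene subset): +0.436 (n=5), -0.05 (n=1)
```

All eight requested nuclei are recovered; the cohort's measured mean
circularity (0.841) matches the generator target 0.84, while the mean
area (171.8 µm²) scatters around the 160 µm² population mean for a
sample of eight lognormal sizes. The nucleolar example reproduces the
familiar +41 % expansion from a 1.72 → 2.43 µm² shift, and the
six-gene panel's bidirectional score is the hand-checkable
(0.85+0.84+0.30+0.16+0.03)/5 = +0.436 against a single down-regulated
gene at −0.05.

## Command line

The full simulate → segment → measure → score → report chain runs from
one YAML configuration (a built-in demo configuration emulating the
G12D/G12R time course is used when `--config` is omitted):

```sh
nucarch run-all --seed 1 --outdir out/             # everything
nucarch simulate-images --seed 1 --outdir out/img  # imaging chain only
nucarch simulate-omics  --seed 1 --outdir out/om   # NTRS + phospho calls
nucarch segment --image out/img/G12D_0h_2d_00.tif --channel dna --outdir out/seg
nucarch measure --labels out/seg/G12D_0h_2d_00_dna_labels.tif --out out/m.csv
nucarch score-ntrs --de-table out/om/de_table.csv --out out/ntrs.csv
nucarch score-phospho --array out/om/phospho_table.csv --out out/calls.csv --threshold 1.0
nucarch report --measurements out/img/measurements_2d.csv --out out/report.csv
```

Outputs are CSV tables (optionally JSON via `--format json`) plus a
manifest with a config hash; identical `(config, seed)` reproduce
byte-identical reports. Exit codes: 0 success, 2 configuration error,
1 runtime failure.

## Layout

```
src/nucarch/
  synthdata/        image + omics-table generators (specs, shapes, rendering)
  morphometry2d.py  2D segmentation, area/perimeter/circularity
  morphometry3d.py  3D segmentation, volume/surface/sphericity
  transcriptomics.py  DE filter, nuclear panel, NTRS, concordance
  phosphoarray.py   array summarization/normalization/ratio/calls
  reporting.py      percent change, ANOVA + Sidak, stars, reports
  pipeline.py, cli.py, io.py, geometry.py, errors.py
docs/methods.md     model and design notes
```
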