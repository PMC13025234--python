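# Methods

## What the package models

Oncogene-variant imaging studies of nuclear architecture compare, per
condition (variant × induction time), distributions of per-object
measurements: nuclear cross-sectional area and circularity in 2D,
nuclear volume and sphericity in 3D, and the same size/shape
quantities for nucleolar sub-compartments (nucleolin- and
fibrillarin-defined) and spliceosomal speckles (SC-35). `nucarch`
implements that analysis — segmentation, physical-unit morphometry,
condition-level statistics — together with the two omics scores such
studies pair with imaging (a bidirectional mean-log2FC transcriptomic
score and a phospho-array fold-change classification), and a synthetic
data generator that produces inputs with exact ground truth so the
whole chain can be validated quantitatively.

## Synthetic nuclei

**Shape model.** A 2D nucleus is a circle of sampled area whose radius
is modulated as `r(θ) = R(1 + a·f(θ))`, with `f` a random truncated
Fourier series over angular orders 2…(1+K) (order 0 is a size change,
order 1 a translation), normalized to unit maximum so that `a` is
directly the maximum fractional boundary excursion. A 3D nucleus is an
oblate spheroid flattened along the optical axis — the natural
geometry of an adherent epithelial nucleus — optionally modulated by a
random real spherical-harmonic field of degrees ≥ 2. When a target
circularity/sphericity is specified, the generator solves for the
perturbation amplitude (2D) or the flattening ratio (3D) per nucleus
by monotone bisection, so each generated object's *analytic* shape
value equals the target. A peak-normalized profile concentrated in one
narrow bump occasionally cannot reach a low target within the
amplitude bound (0.45); the profile is redrawn (up to 10 times) in
that case.

**Ground truth.** Truth metrics are computed from the analytic
boundary — a 4096-gon in 2D, a 192×384 latitude/longitude triangle
mesh in 3D — never from the raster. Unperturbed shapes short-circuit
to closed forms (circle; sphere; oblate spheroid area via the
eccentricity formula), making their truth exact; the dense polygon and
mesh carry relative errors of about 2·10⁻⁷ and 1·10⁻⁴ respectively.
Compartment objects are discs/balls with closed-form truth.

**Placement.** Nuclei are placed by rejection sampling with a minimum
boundary-to-boundary clearance of one object radius (center distance
≥ rᵢ + rⱼ + max(rᵢ, rⱼ)), 1000 attempts per nucleus, then an explicit
"field too crowded" error; this margin keeps nuclei separable after
PSF blur but caps usable density at roughly 25–30 % disc coverage, so
cohorts of ~200 cells are rendered as several replicate fields (the
demo uses 29 cells × 7 fields of 256 × 256 µm), matching how such data
are actually acquired. In 3D, nuclei form a monolayer: xy placement
follows the same rule and the z-center jitters by ±5 % of stack depth.
Compartments are rejection-placed fully inside their parent (star-shape
containment checked on sampled boundary directions, then enforced
voxel-exactly by intersecting the child raster with the parent
raster); siblings keep a 0.4 µm clearance so blur does not merge them;
an object that cannot fit is shrunk by 20 % up to four times, then
dropped. Fibrillarin foci nest inside nucleolin-defined nucleoli,
everything else inside the nucleus.

**Rendering.** Analytic shape → binary raster (pixel-center test) →
Gaussian PSF blur (default σ 0.15 µm) → constant background (200) →
optional Poisson shot noise → additive Gaussian read noise (default
σ 80 on a foreground of 10 000) → 16-bit clip. With all noise terms
zero the channel equals the rasterized mask exactly. One master seed
spawns independent substreams for shapes, placement, compartments and
noise, so equal (spec, seed) is bit-identical.

**What the generator does not emulate.** Real chromatin texture
(intensity is uniform inside objects), out-of-focus light from other
z-planes in 2D (a single focal plane is rendered, matching widefield
planar measurements), touching/overlapping nuclei (placement enforces
separation, so the segmenter is never tested on under-segmentation),
chromatic aberration or stage drift, and real speckle morphology
(compartments are discs/balls, so their truth circularity is 1 rather
than the ~0.58 of real speckles). Passing tests therefore validate the
measurement chain's accuracy and calibration, not its robustness to
those real-data pathologies.

## Morphometry

All outputs are in µm/µm²/µm³; pixel units are never exposed.

**Segmentation** is Gaussian smoothing (σ in µm), Otsu or fixed
threshold, optional hole filling (per-z-slice then 3D, so meshes are
closed), optional border exclusion, minimum object size in physical
units, 8-/26-connected labelling. A constant image under Otsu yields
zero objects, not an error. For cross-condition comparability a single
threshold can be frozen from pooled baseline (0-h) images and reused
unchanged for all conditions and timepoints
(`freeze_threshold`; the pipeline does this by default). In 3D,
objects touching the first or last z-plane are removed by default
(incomplete volumes bias means downward).

**2D shape.** Area is pixel count × pixel area. The perimeter is the
length of the 0.5-level marching-squares contour of the binary object
after smoothing with σ = 1.5 px. The smoothing scale is a *pixel*
quantity because the artifact it removes — the rasterization
staircase — lives at the pixel scale; 1.5 px suppresses it to < 0.2 %
on discs of radius ≥ 50 px while leaving straight edges essentially
untouched, so both calibration limits hold: a disc measures
circularity ≈ 1.00 and an axis-aligned square ≈ π/4 (0.79 measured).
Direction-limited Crofton estimators cannot do this: the 4-direction
Cauchy mean-width average underestimates an axis-aligned square's
perimeter by ~5 % *by construction*, which would inflate its
circularity to 0.88. Crofton-4 is kept only as a fallback for objects
too small to support a level set after smoothing (< ~4 px across).
Circularity is clipped at 1; pre-clip overshoot on well-resolved discs
is below 2 %.

**3D shape.** Volume is voxel count × voxel volume. Surface area comes
from a marching-cubes iso-surface at level 0.5, with physical spacing
applied, extracted from the binary object smoothed at σ = 0.7 × the
geometric-mean voxel pitch. Raw binary marching cubes overestimates a
sphere's area by ~9 % (45° facet staircase) and voxel-face counting by
up to 50 %, destroying the Ψ → 1 limit; the 0.7-pitch smoothing was
calibrated on closed forms (ball r = 20 vox: +1.1 %; 2:1:1 ellipsoid:
+0.1 %; cube side 50: −2.4 % from corner rounding). Single-voxel
objects have no meaningful iso-surface and are skipped with a warning.
Sphericity is clipped at 1.

**Compartment assignment** maps each child object to the parent
holding the majority of its pixels; a child with < 50 % overlap with
every parent is an orphan; an exact 50/50 tie goes to the lower parent
label (determinism). The pipeline aggregates only assigned children,
so compartments of border-excluded nuclei drop out consistently.

## Transcriptomic scoring

Gene records (gene id, condition, log2FC, FDR, GO cellular-component
category) pass a filter of FDR strictly < 0.05 and |log2FC| ≥ 0.75;
non-finite fold changes are dropped with a warning. The nuclear panel
is the filtered subset annotated to chromatin remodeling, nuclear
membrane or nucleolus (annotation is an input mapping — no ontology
queries). The NTRS is the unweighted arithmetic mean of panel log2FCs,
computed separately over strictly positive and strictly negative
values; zero contributes to neither, and an empty direction is
reported as undefined (None/NaN), never 0, because 0 would masquerade
as a valid score. Sign concordance between two condition panels is
(matching − opposing sign pairs)/shared genes over genes nonzero in
both, +1 for identical and −1 for sign-flipped panels.

Note that this filtered-panel NTRS is by construction ≥ 0.75 in
magnitude whenever defined; published full-panel scores that include
sub-threshold genes are not reproducible from the filtered set, and
the package makes no attempt to — the hand-checkable six-gene subset
(+0.436/−0.05) is the worked reference.

The DE generator gives each gene a fixed category, a latent response
direction and a responsiveness quantile shared across conditions
(so stronger conditions perturb supersets of weaker ones, and an
"inverted" condition — emulating a dominant-negative variant — flips
every responding gene, forcing negative concordance). Responding genes
draw |log2FC| from N(mean, sd) and receive FDR ~ U(0, 0.05) with a
configurable hit probability; null genes draw log2FC ~ N(0, 0.25) and
FDR ~ U(0, 1). Only threshold crossings matter downstream, so these
simple marginals suffice.

## Phospho-array scoring

Per slide (condition × doxycycline state × biological replicate):
duplicate spots are summarized as the per-antibody median (the mean of
the two for duplicates), and the slide is normalized to its global
median signal (post-normalization median is 1 — exactly for odd
antibody counts, to one float ulp for even counts, where the median is
the mean of the central pair). Biological replicates are averaged
after normalization, before fold changes, which minimizes
replicate-scale artifacts. Each site's phospho signal is divided by
its paired total-protein signal within the same state; the fold change
is log2(ratio₊doxy/ratio₋doxy) with inclusive calls at |log2FC| ≥ 1
(up/down/unchanged). Because the ratio is formed within a state and
the fold change across states, any global slide scale factor cancels
exactly, and the whole chain is invariant to per-slide scaling. No
significance testing is applied — calls are threshold-based only. For
total-protein abundance the fold change is computed on the normalized
total signals directly (no ratio step). Sites with non-positive total
signal are flagged undefined and excluded with a warning.

The array generator mirrors a commercial phospho-antibody array: 584
sites across 452 targets, one total-protein antibody per target
(sites assigned round-robin), duplicate spots, three biological
replicates, lognormal baselines (log-SD 0.8), per-spot technical noise
of log-SD 0.10 (~10 % CV, typical array technical variation), and a
random per-slide scale factor (log-SD 0.2) that normalization must
remove. With one spot and one replicate the chain's null log2FC is
exactly Gaussian with SD 2σ/ln 2 — the closed form used to check the
null call rate; at the defaults, an injected +1.3 log2FC site is
called "up" with ≈ 99 % probability.

## Condition reports

Per condition × metric, each timepoint group contributes n, mean, SD
and a t-distribution 95 % CI (exact at small n, converging to
1.96·SE). Percent change vs the 0-h baseline is
(value − baseline)/baseline × 100, with a reporting helper that rounds
half away from zero (2.5 % → 3 %). Each non-baseline timepoint is
contrasted with baseline by a two-sided t test whose error variance is
the one-way-ANOVA pooled mean square across *all* timepoint groups
(df = N − k), and the m = k−1 contrasts are Sidak-adjusted,
p_adj = 1 − (1−p)^m — the standard layout for imaging timecourses
where individual cells are not matched across timepoints (imaging is
destructive, so a literal repeated-measures design is not applicable).
Stars follow strict bins: `*` < 0.05, `**` < 0.01, `***` < 0.001,
`****` < 0.0001; p = 0.05 is n.s. Simulated null timecourses give a
family-wise post-Sidak type-I rate within [0.03, 0.07] (the shared
baseline makes contrasts positively dependent, so Sidak is mildly
conservative).

## Pipeline and reproducibility

One YAML configuration drives everything; unknown keys fail fast with
a ConfigError naming them. All randomness flows from one `--seed`:
each stage derives a substream seed as SHA-256 of
(seed, stage tokens) mod 2³¹, so stages are individually reproducible
and platform-independent. CSV floats are written with the shortest
round-trip representation and read back with exact round-trip parsing,
which is what makes re-derived reports (stage isolation) and reruns
byte-identical; manifests carry a content hash computed over
everything except the timestamp. Images are multi-page TIFF (channel
order: nuclear stain, nucleolin, fibrillarin, SC-35) with a JSON
sidecar holding spacing, channel names and seed.

The built-in demo emulates the two-variant time course at the
published condition values (2D: 160 µm² nuclei at circularity
0.84→0.88 vs 0.86→0.84, nucleolin 1.72→2.43→2.65 µm² vs
1.88→2.19 µm²; 3D: 823 µm³ at sphericity 0.68→0.71→0.79 vs ~920 µm³
flat at ~0.72) with ~200 cells per 2D cohort (29 × 7 fields of
2560² px at 0.1 µm/px) and 8 nuclei per 3D cohort (4 × 2 stacks of
64×256×256 at 0.3/0.35 µm). Acquisition noise levels and the
µm-per-pixel calibration are free parameters of the generator; the
defaults above were chosen once as representative of widefield/
spinning-disk data and are not tuned per analysis. The z spacing
default (0.3 µm) reflects typical confocal sampling; far finer steps
are supported but oversample the PSF without changing the
morphometry. Fibrillarin demo sizes are smaller than the published
per-object areas (while following the published fold trajectories)
because the generator nests fibrillarin foci strictly inside
nucleolin objects, which equal-sized objects cannot satisfy.

## Known limitations

- No watershed splitting: touching nuclei would merge (the generator
  never produces them; real data can).
- Speckle-scale objects (a few pixels across) sit at the resolution
  limit of both the perimeter and surface estimators; their shape
  values are reported but carry large discretization error.
- The "paired" comparison is an unpaired pooled-variance contrast (see
  above); no mixed-effects or per-replicate nesting is modelled.
- Per-slide (not cross-slide) normalization is an assumption; with the
  simulated per-slide scale factors it is also the correct choice.
- GO annotation is taken as given; no ontology resolution.
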