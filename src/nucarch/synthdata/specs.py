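"""Parameter specifications for the synthetic-data generators.

The defaults emulate the study conditions of the imaging experiments
this package analyses: fields of adherent pancreatic ductal epithelial
nuclei (~160 µm² in cross-section, ~800 µm³ in volume) carrying
nucleolar (nucleolin/fibrillarin) and spliceosomal-speckle (SC-35)
compartments, imaged at 0.1 µm/px in 2D and anisotropically in 3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NUCLEUS = "dna"
NUCLEOLIN = "nucleolin"
FIBRILLARIN = "fibrillarin"
SC35 = "sc35"
MARKERS = (NUCLEOLIN, FIBRILLARIN, SC35)
CHANNEL_ORDER = (NUCLEUS, NUCLEOLIN, FIBRILLARIN, SC35)


@dataclass(frozen=True)
class NuclearPhenotypeSpec:
    """Cohort-level nuclear phenotype.

    ``mean_size`` is a cross-sectional area in µm² (2D) or a volume in
    µm³ (3D); sizes are lognormal with coefficient of variation
    ``size_cv``.  Boundary irregularity is a random radial perturbation
    with ``irregularity_harmonics`` angular (2D) or spherical-harmonic
    (3D) modes and maximum fractional excursion
    ``irregularity_amplitude``.  When ``target_shape`` is set, the
    generator calibrates the shape per nucleus so that its analytic
    circularity (2D) or sphericity (3D) equals the target.
    """

    n_cells: int
    mean_size: float
    size_cv: float = 0.2
    irregularity_amplitude: float = 0.0
    irregularity_harmonics: int = 4
    target_shape: float | None = None

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.mean_size <= 0:
            raise ValueError("mean_size must be positive")
        if self.size_cv < 0:
            raise ValueError("size_cv must be >= 0")
        if not 0.0 <= self.irregularity_amplitude <= 0.5:
            raise ValueError("irregularity_amplitude must lie in [0, 0.5]")
        if self.target_shape is not None and not 0.0 < self.target_shape <= 1.0:
            raise ValueError("target_shape must lie in (0, 1]")


@dataclass(frozen=True)
class CompartmentSpec:
    """Subnuclear compartment population for one marker.

    Object counts per parent are Poisson with mean ``count_mean``;
    object sizes (µm² in 2D, µm³ in 3D) are lognormal with mean
    ``size_mean`` and log-standard-deviation ``size_sigma``.
    ``nesting`` names the parent marker (fibrillarin foci sit inside
    nucleolin-defined nucleoli); ``None`` nests directly in the nucleus.
    """

    marker: str
    count_mean: float
    size_mean: float
    size_sigma: float = 0.4
    nesting: str | None = None

    def validate(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if self.count_mean < 0:
            raise ValueError("count_mean must be >= 0")
        if self.size_mean <= 0:
            raise ValueError("size_mean must be positive")
        if self.size_sigma < 0:
            raise ValueError("size_sigma must be >= 0")
        if self.nesting is not None and self.nesting not in MARKERS:
            raise ValueError(f"nesting parent {self.nesting!r} is not a known marker")


@dataclass(frozen=True)
class NoiseSpec:
    """Acquisition model: constant background offset, Gaussian PSF blur
    (µm), additive Gaussian read noise, and optional Poisson shot noise
    (``photon_scale`` counts per intensity unit; 0 disables)."""

    background: float = 200.0
    psf_sigma: float = 0.15
    gaussian_sigma: float = 80.0
    photon_scale: float = 0.0

    def validate(self) -> None:
        for name in ("background", "psf_sigma", "gaussian_sigma", "photon_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(background=0.0, psf_sigma=0.0, gaussian_sigma=0.0, photon_scale=0.0)


# ---------------------------------------------------------------------------
# omics table simulation


GO_CATEGORIES = ("chromatin_remodeling", "nuclear_membrane", "nucleolus", "other")
NUCLEAR_CATEGORIES = ("chromatin_remodeling", "nuclear_membrane", "nucleolus")


@dataclass(frozen=True)
class DEEffectModel:
    """Per-condition differential-expression effect.

    A fraction of nuclear-annotated genes responds with |log2FC| drawn
    from N(``mean_lfc``, ``sd_lfc``) in a gene-intrinsic direction;
    ``invert`` flips every responding gene's direction, emulating a
    dominant-negative condition with an inverse regulatory pattern.
    Responding genes obtain FDR < 0.05 with probability
    ``fdr_hit_prob``.
    """

    mean_lfc: float = 1.0
    sd_lfc: float = 0.3
    frac_affected: float = 0.5
    invert: bool = False
    fdr_hit_prob: float = 0.95

    def validate(self) -> None:
        if self.sd_lfc < 0:
            raise ValueError("sd_lfc must be >= 0")
        if not 0.0 <= self.frac_affected <= 1.0:
            raise ValueError("frac_affected must lie in [0, 1]")
        if not 0.0 <= self.fdr_hit_prob <= 1.0:
            raise ValueError("fdr_hit_prob must lie in [0, 1]")


def _default_fractions() -> dict[str, float]:
    return {
        "chromatin_remodeling": 0.05,
        "nuclear_membrane": 0.05,
        "nucleolus": 0.05,
        "other": 0.85,
    }


@dataclass(frozen=True)
class DESimSpec:
    """Synthetic differential-expression table layout.

    Null (non-responding) genes have log2FC ~ N(0, ``null_sd``) and FDR
    uniform on (0, 1); responding genes' FDR is uniform on (0, 0.05)
    when hit.  Only threshold crossings matter downstream, so the FDR
    marginals are deliberately simple.
    """

    n_genes: int = 2000
    category_fractions: dict[str, float] = field(default_factory=_default_fractions)
    effects: dict[str, DEEffectModel] = field(default_factory=dict)
    null_sd: float = 0.25

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if set(self.category_fractions) != set(GO_CATEGORIES):
            raise ValueError(f"category_fractions must cover exactly {GO_CATEGORIES}")
        total = sum(self.category_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category fractions must sum to 1, got {total}")
        if self.null_sd < 0:
            raise ValueError("null_sd must be >= 0")
        for eff in self.effects.values():
            eff.validate()


@dataclass(frozen=True)
class PhosphoEffectModel:
    """Per-condition injected phosphorylation change: a fraction of
    sites gains log2FC ~ N(``mean_lfc``, ``sd_lfc``) on the phospho
    signal in the +doxycycline state."""

    mean_lfc: float = 1.3
    sd_lfc: float = 0.2
    frac_sites: float = 0.05

    def validate(self) -> None:
        if self.sd_lfc < 0:
            raise ValueError("sd_lfc must be >= 0")
        if not 0.0 <= self.frac_sites <= 1.0:
            raise ValueError("frac_sites must lie in [0, 1]")


@dataclass(frozen=True)
class PhosphoSimSpec:
    """Synthetic antibody-array layout.

    Defaults mirror a commercial phospho-antibody array: 584 phospho
    sites across 452 target proteins, each antibody spotted in
    duplicate, three biological replicates per condition, a paired
    total-protein antibody for every phospho antibody.  ``spot_log_sd``
    is the technical log-noise per spot (~10 % CV); each slide carries
    a random global scale factor that downstream normalization must
    remove.
    """

    n_sites: int = 584
    n_targets: int = 452
    n_spots: int = 2
    n_replicates: int = 3
    baseline_median: float = 1000.0
    baseline_log_sd: float = 0.8
    spot_log_sd: float = 0.10
    slide_log_sd: float = 0.20
    effects: dict[str, PhosphoEffectModel] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_sites < 1 or self.n_targets < 1:
            raise ValueError("n_sites and n_targets must be >= 1")
        if self.n_targets > self.n_sites:
            raise ValueError("n_targets cannot exceed n_sites")
        if self.n_spots < 1 or self.n_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.baseline_median <= 0:
            raise ValueError("baseline_median must be positive")
        for name in ("baseline_log_sd", "spot_log_sd", "slide_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for eff in self.effects.values():
            eff.validate()
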