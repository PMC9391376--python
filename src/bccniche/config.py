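"""Configuration objects for simulation and pipeline runs."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


class DegenerateInputError(ValueError):
    """Raised when an input admits no well-defined answer (e.g. identical pure profiles)."""


@dataclass(frozen=True)
class CNVSegment:
    """A planted copy-number segment.

    ``chrom`` is a 1-based synthetic chromosome index, ``start`` the 0-based
    index of the first affected gene *within that chromosome's position-ordered
    gene list*, ``length`` the number of consecutive genes, ``multiplier`` the
    factor applied to expected tumor-cell counts (>1 gain, <1 loss).
    ``samples`` restricts the segment to tumor cells of those sample indices;
    ``None`` plants it in every sample, which emulates a lineage-wide expression
    effect rather than a genuine genomic change (the shared-change exclusion is
    expected to mask it).
    """

    chrom: int
    start: int
    length: int
    multiplier: float
    samples: Optional[tuple[int, ...]] = None

    def validate(self) -> None:
        if self.chrom < 1 or self.start < 0 or self.length < 1:
            raise ConfigurationError(f"invalid CNV segment {self}")
        if self.multiplier <= 0:
            raise ConfigurationError("CNV multiplier must be > 0")


def _default_cell_numbers() -> dict[str, int]:
    return {
        "tumor": 800,
        "basal_keratinocyte": 300,
        "diff_keratinocyte": 300,
        "fibroblast": 400,
        "t_cell": 400,
    }


def _default_segments() -> tuple[CNVSegment, ...]:
    # the tumor clone carries one gain and one loss in every sample; the cells
    # of all samples are draws from one clone, so there is no sample-specific
    # structure confounding the infiltrative gradient
    return (
        CNVSegment(chrom=1, start=10, length=60, multiplier=2.0),
        CNVSegment(chrom=3, start=10, length=60, multiplier=0.5),
    )


@dataclass
class SimConfig:
    """Generative parameters for the synthetic scRNA-seq + DSP study.

    Defaults emulate the structure of a five-type infiltrative-BCC dissociation
    experiment paired with a two-compartment, two-morphology DSP run: a latent
    nodular→infiltrative coordinate g per tumor cell drives two antagonistic
    epithelial programs, fibroblasts carry an antagonistic ECM/quiescent
    program pair, and DSP areas of interest are contamination mixtures of the
    two compartment profiles.
    """

    # --- scRNA-seq side ---------------------------------------------------
    n_cells_per_type: dict[str, int] = field(default_factory=_default_cell_numbers)
    n_genes: int = 2400
    n_chromosomes: int = 22
    n_samples: int = 3
    baseline_mean: float = 0.5          # counts/gene/cell scale before library factor
    nb_dispersion: float = 0.3          # var = m + dispersion * m^2
    libsize_sigma: float = 0.3          # log-normal per-cell library factor
    n_program_genes: int = 80
    n_marker_genes: int = 10
    program_log2fc: float = 3.0         # amplitude of NOD/INF and ECM/quiescent programs
    marker_log2fc: float = 3.0          # canonical marker boost in the owning type
    driver_log2fc: float = 4.0          # INHBA-like paracrine driver, monotone in g
    program_base_boost: float = 4.0     # baseline boost so program genes are detectable
    compartment_leak: float = 0.05      # off-compartment baseline factor for specific genes
    mito_boost: float = 20.0
    n_mito_genes: int = 10
    n_dissoc_genes: int = 10
    cnv_segments: tuple[CNVSegment, ...] = field(default_factory=_default_segments)
    gradient_beta: tuple[float, float] = (2.0, 2.0)   # latent g ~ Beta(a, b)

    # --- DSP side ---------------------------------------------------------
    n_aoi_per_group: int = 12           # AOIs per (compartment x morphology)
    contamination_beta: tuple[float, float] = (2.0, 18.0)  # c ~ Beta(a, b), mean 0.1
    probes_per_gene: int = 5
    n_negative_probes: int = 10
    n_pools: int = 2
    probe_cv: float = 0.2
    outlier_probe_rate: float = 0.002   # fraction of gene probes planted aberrant (>=8x)
    outlier_multiplier: float = 8.0
    morphology_log2fc: float = 1.0      # planted infiltrative-vs-nodular effect
    aoi_depth: float = 2.0e5
    aoi_depth_sigma: float = 0.2
    negative_mean: float = 10.0

    seed: int = 0

    def validate(self) -> None:
        if not self.n_cells_per_type or any(n <= 0 for n in self.n_cells_per_type.values()):
            raise ConfigurationError("cell counts must be positive")
        required = {"tumor", "fibroblast", "t_cell"}
        if not required.issubset(self.n_cells_per_type):
            raise ConfigurationError(f"cell types must include {sorted(required)}")
        for name in ("n_genes", "n_chromosomes", "n_samples", "n_program_genes",
                     "n_marker_genes", "n_aoi_per_group", "probes_per_gene",
                     "n_negative_probes", "n_pools"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.nb_dispersion <= 0 or self.baseline_mean <= 0:
            raise ConfigurationError("baseline_mean and nb_dispersion must be positive")
        for seg in self.cnv_segments:
            seg.validate()
        a, b = self.gradient_beta
        if a <= 0 or b <= 0:
            raise ConfigurationError("gradient_beta parameters must be positive")
        a, b = self.contamination_beta
        if a <= 0 or b <= 0:
            raise ConfigurationError("contamination_beta parameters must be positive")
        if not 0 <= self.outlier_probe_rate < 1:
            raise ConfigurationError("outlier_probe_rate must be in [0, 1)")
        # the gene universe must accommodate every planted special set
        n_special = (4 * self.n_program_genes
                     + len(self.n_cells_per_type) * self.n_marker_genes
                     + self.n_mito_genes + self.n_dissoc_genes + 3)
        if n_special > self.n_genes:
            raise ConfigurationError(
                f"gene universe ({self.n_genes}) smaller than the "
                f"{n_special} planted program/marker genes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cnv_segments"] = [asdict(s) for s in self.cnv_segments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "cnv_segments" in d:
            segs = []
            for s in d["cnv_segments"]:
                if isinstance(s, dict):
                    s = dict(s)
                    if s.get("samples") is not None:
                        s["samples"] = tuple(s["samples"])
                    segs.append(CNVSegment(**s))
                else:
                    segs.append(s)
            d["cnv_segments"] = tuple(segs)
        for key in ("gradient_beta", "contamination_beta"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class QCParams:
    """Cell-level quality-control bounds (detected genes inclusive, fractions strict)."""

    min_genes: int = 500
    max_genes: int = 6000
    max_mito_frac: float = 0.20
    max_dissoc_frac: float = 0.20
    mito_genes: Sequence[str] = ()
    dissoc_genes: Sequence[str] = ()

    def validate(self) -> None:
        if not 0 < self.min_genes < self.max_genes:
            raise ConfigurationError("need 0 < min_genes < max_genes")
        for frac in (self.max_mito_frac, self.max_dissoc_frac):
            if not 0 < frac <= 1:
                raise ConfigurationError("QC fractions must lie in (0, 1]")
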