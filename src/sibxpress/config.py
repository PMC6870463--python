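"""Configuration objects for the simulation and analysis pipeline.

Every threshold used anywhere in the pipeline lives here with its default,
so a single YAML file fully determines a run. Unknown keys are rejected to
keep threshold provenance auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value or key is invalid."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic F0 x F0 -> F1 sib-mating -> F2 design.

    The defaults emulate the study design this package targets: two
    divergent founder breeds (10 birds each, balanced sexes), 15 F2
    families from F1 brother-sister matings, and macrophage-style
    expression with partial Z dosage compensation, a trans-regulated
    LPS-inducible module, mesenchymal contamination, and multiplicative
    log-normal noise.

    Parameters
    ----------
    n_founders_per_breed
        Founders per breed, alternating sex (M, F, M, ...).
    n_f1_pairs
        Number of F1 brother-sister pairs, i.e. F2 families.
    n_f2_per_family
        Expression-profiled F2 birds per family.
    n_autosomal_genes, n_z_genes, n_w_genes
        Simulated gene counts per chromosome class.
    breed_fixed_fraction
        Fraction of autosomal gene loci whose alternative alleles are
        near-fixed (>= 0.95 vs <= 0.05) in opposite breeds.
    het_null_fraction
        Fraction of autosomal genes carrying a zero-effect (null)
        alternative allele heterozygous in exactly one founder.
    baseline_tpm_range
        Log-uniform range of the homozygous-functional expression level
        (TPM); the per-allele cis effect is half of this.
    dosage_compensation_factor
        Multiplier on single-Z female expression, in [1, 2]; the expected
        male/female Z ratio is 2 / factor (4/3 gives the observed ~1.5).
    lps_up_log2fc, lps_down_log2fc
        (loc, scale) of the normal law of log2 fold changes for planted
        LPS-induced / repressed genes.
    n_lps_induced, n_lps_repressed
        Planted counts of LPS-responsive constitutive genes.
    trans_module_size
        Size of the LPS-inducible module whose induction is scaled by the
        genotype at a single trans-acting locus.
    trans_effect_per_alt_allele
        Multiplicative scalar applied to the module's log2 fold change per
        alternative allele carried at the trans locus.
    mesenchyme_module_size
        Number of genes expressed by the contaminating mesenchymal
        population rather than the macrophages.
    mesenchyme_fraction_range
        Per-sample uniform range of the mesenchymal contamination
        fraction.
    renormalize_tpm
        If True, rescale each sample column to 1e6 (true TPM coupling);
        off by default so planted effects are exactly recoverable.
    noise_sd_log2
        SD of the multiplicative log2-normal measurement noise.
    site_quality_range, genotype_quality_range
        Uniform ranges for simulated variant site quality and per-call
        genotype quality (annotations only; simulated calls are never
        missing).
    seed
        Master seed; all stage streams are derived from it.
    """

    n_founders_per_breed: int = 10
    n_f1_pairs: int = 15
    n_f2_per_family: int = 2
    n_autosomal_genes: int = 300
    n_z_genes: int = 200
    n_w_genes: int = 20
    breed_fixed_fraction: float = 0.3
    het_null_fraction: float = 0.1
    baseline_tpm_range: tuple[float, float] = (25.0, 250.0)
    dosage_compensation_factor: float = 4.0 / 3.0
    lps_up_log2fc: tuple[float, float] = (2.5, 0.5)
    lps_down_log2fc: tuple[float, float] = (-2.5, 0.5)
    n_lps_induced: int = 50
    n_lps_repressed: int = 40
    trans_module_size: int = 40
    trans_effect_per_alt_allele: float = 1.5
    mesenchyme_module_size: int = 30
    mesenchyme_fraction_range: tuple[float, float] = (0.02, 0.5)
    renormalize_tpm: bool = False
    noise_sd_log2: float = 0.2
    site_quality_range: tuple[float, float] = (20.0, 500.0)
    genotype_quality_range: tuple[float, float] = (10.0, 99.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_founders_per_breed": self.n_founders_per_breed,
            "n_f1_pairs": self.n_f1_pairs,
            "n_f2_per_family": self.n_f2_per_family,
            "n_autosomal_genes": self.n_autosomal_genes,
            "n_z_genes": self.n_z_genes,
            "n_w_genes": self.n_w_genes,
            "n_lps_induced": self.n_lps_induced,
            "n_lps_repressed": self.n_lps_repressed,
            "trans_module_size": self.trans_module_size,
            "mesenchyme_module_size": self.mesenchyme_module_size,
        }
        for name, value in counts.items():
            if int(value) != value or value < 0:
                raise ConfigError(f"{name} must be a nonnegative integer, got {value!r}")
        for name, value in (
            ("breed_fixed_fraction", self.breed_fixed_fraction),
            ("het_null_fraction", self.het_null_fraction),
        ):
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value!r}")
        lo, hi = self.mesenchyme_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("mesenchyme_fraction_range must be within [0, 1]")
        lo, hi = self.baseline_tpm_range
        if not (0.0 < lo <= hi):
            raise ConfigError("baseline_tpm_range must be a positive interval")
        if not 1.0 <= self.dosage_compensation_factor <= 2.0:
            raise ConfigError("dosage_compensation_factor must be in [1, 2]")
        if self.noise_sd_log2 < 0:
            raise ConfigError("noise_sd_log2 must be nonnegative")
        if self.n_founders_per_breed < 2:
            raise ConfigError(
                "need at least 2 founders per breed (one of each sex) to form F0 crosses"
            )

    @property
    def n_genes(self) -> int:
        return self.n_autosomal_genes + self.n_z_genes + self.n_w_genes


@dataclass
class FilterCriteria:
    """Variant-panel filtration thresholds (pass at >=, drop above max rate)."""

    min_site_quality: float = 30.0
    min_genotype_quality: float = 15.0
    max_missing_rate: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_rate <= 1.0:
            raise ConfigError("max_missing_rate must be in [0, 1]")


@dataclass
class StatsThresholds:
    """Per-gene expression screening thresholds."""

    min_max_tpm: float = 10.0       # expressed iff max over samples >= 10 TPM
    extreme_max: float = 20.0       # extreme variation iff max > 20 ...
    extreme_min: float = 1.0        # ... and min < 1
    lps_fold: float = 2.0           # induced iff fold > 2, repressed iff < 1/2
    pseudocount: float = 0.5        # TPM added inside fold/log computations
    dosage_group_penalty: float = 1.0  # BIC-style penalty weight per extra group
    null_gap_fold: float = 5.0      # near-zero group separation requirement
    null_max_tpm: float = 1.0       # near-zero group ceiling (TPM)
    bootstrap_reps: int = 1000      # compensated-gene bootstrap replicates


@dataclass
class NetworkParams:
    """Co-expression graph and Markov-clustering parameters."""

    r_min: float = 0.85
    inflation: float = 1.7
    expansion: int = 2
    prune_threshold: float = 1e-5
    tol: float = 1e-6
    max_iter: int = 200
    min_cluster_size: int = 3
    log_transform: bool = False     # correlate log2(TPM+1) instead of raw TPM
    binarize: bool = False          # unit edge weights instead of r

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ConfigError("inflation must be > 1")


@dataclass
class ContrastParams:
    """Group-versus-rest fold-ratio screen thresholds."""

    min_mean: float = 1.0
    ratio_hi: float = 1.5
    ratio_lo: float = 0.67

    def __post_init__(self) -> None:
        if not self.ratio_lo < 1.0 < self.ratio_hi:
            raise ConfigError("require ratio_lo < 1 < ratio_hi")


@dataclass
class PipelineConfig:
    """Aggregate configuration for the end-to-end pipeline."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filtration: FilterCriteria = field(default_factory=FilterCriteria)
    stats: StatsThresholds = field(default_factory=StatsThresholds)
    network: NetworkParams = field(default_factory=NetworkParams)
    contrast: ContrastParams = field(default_factory=ContrastParams)


_SECTIONS = {
    "simulation": SimulationConfig,
    "filtration": FilterCriteria,
    "stats": StatsThresholds,
    "network": NetworkParams,
    "contrast": ContrastParams,
}

_TUPLE_FIELDS = {
    "baseline_tpm_range",
    "lps_up_log2fc",
    "lps_down_log2fc",
    "mesenchyme_fraction_range",
    "site_quality_range",
    "genotype_quality_range",
}


def _build_section(cls: type, data: dict[str, Any], section: str) -> Any:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section '{section}': {', '.join(sorted(unknown))}"
        )
    coerced = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)) else v
        for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path: str) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level of the config file must be a mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown top-level section(s): {', '.join(sorted(unknown))}")
    kwargs = {
        name: _build_section(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return PipelineConfig(**kwargs)


def dump_config(config: PipelineConfig, path: str) -> None:
    """Write a PipelineConfig back to YAML (lossless round-trip)."""
    as_dict = dataclasses.asdict(config)

    def _listify(obj: Any) -> Any:
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: _listify(v) for k, v in obj.items()}
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(_listify(as_dict), fh, sort_keys=False)
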