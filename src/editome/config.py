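"""Configuration objects for simulation and site calling.

Two small frozen-ish dataclasses carry every tunable: :class:`SimulationConfig`
for the synthetic-cohort generator and :class:`ThresholdSet` for the variant
call cascade. Both validate eagerly and raise :class:`ConfigurationError`
naming the offending field, so downstream code never sees an invalid value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the field."""


#: Functional-category placement weights for simulated editing sites.
#: Editing concentrates in introns and 3'-UTRs of protein-coding genes,
#: with small contributions from coding exons, 5'-UTRs, noncoding exons
#: and intergenic space.
DEFAULT_CATEGORY_WEIGHTS: Mapping[str, float] = {
    "intron": 0.80,
    "3'UTR": 0.12,
    "CDS": 0.03,
    "5'UTR": 0.02,
    "noncoding_exon": 0.01,
    "intergenic": 0.02,
}

FUNCTIONAL_CATEGORIES = ("CDS", "3'UTR", "5'UTR", "noncoding_exon", "intron", "intergenic")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-region, two-group editing cohort.

    Defaults emulate a postmortem brain cohort with seven sepsis patients and
    seven controls per region, negative-binomial sequencing coverage around
    50x, mostly intronic/3'-UTR Alu-located editing sites of which ~85% are
    in the known-site catalog, and a mild global reduction of editing in the
    first region's sepsis samples.

    Parameters
    ----------
    n_per_group
        Samples per group (sepsis / control) per region.
    regions
        Region labels; the global ``region_shift_logit`` applies to sepsis
        samples of ``regions[0]``.
    n_edit_sites, n_snp_sites, n_error_sites
        Planted true editing sites, germline-like SNP contaminants
        (allele fraction ~= 0.5 in every sample) and sequencing-error sites
        (allele fraction below the callability threshold in expectation).
    coverage_mean, coverage_dispersion
        Negative-binomial read depth per site per sample; dispersion is the
        NB size parameter (smaller = more overdispersed).
    baseline_beta_a, baseline_beta_b
        Beta shape of per-site baseline editing level, truncated to
        [0.05, 0.95] so every true site is callable at default thresholds.
    site_sd_logit
        Between-sample biological noise SD on the logit of the editing level.
    frac_differential, disease_effect_logit
        Fraction of edit sites given a planted sepsis-vs-control logit shift,
        and that shift.
    region_shift_logit
        Global logit shift applied to ALL edit sites in sepsis samples of the
        first region (models a region-wide loss of editing activity).
    frac_known, frac_alu
        Fraction of edit sites present in the known-site catalog / covered by
        an Alu interval.
    expression_coupling, expression_noise_sd
        Linear coupling of host-gene expression to the sample's mean editing
        logit at the gene's differential sites (0 = no coupling), and the
        residual expression noise SD (log2 units).
    error_rate
        Per-read alternative-allele probability at sequencing-error sites.
    category_weights
        Functional-category placement weights for edit sites; must sum to 1.
    seed
        Base seed; identical (config, seed) gives byte-identical fixtures.
    """

    n_per_group: int = 7
    regions: Sequence[str] = ("hippocampus", "prefrontal_cortex")
    n_edit_sites: int = 500
    n_snp_sites: int = 50
    n_error_sites: int = 50
    coverage_mean: float = 50.0
    coverage_dispersion: float = 8.0
    baseline_beta_a: float = 2.0
    baseline_beta_b: float = 6.0
    site_sd_logit: float = 0.15
    frac_differential: float = 0.05
    disease_effect_logit: float = 1.0
    region_shift_logit: float = -0.12
    frac_known: float = 0.85
    frac_alu: float = 0.80
    expression_coupling: float = 0.0
    expression_noise_sd: float = 0.5
    error_rate: float = 0.002
    category_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = ("n_per_group", "n_edit_sites", "n_snp_sites", "n_error_sites")
        for name in counts:
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ConfigurationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        fractions = ("frac_differential", "frac_known", "frac_alu", "error_rate")
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("coverage_mean", "coverage_dispersion"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("baseline_beta_a", "baseline_beta_b", "expression_noise_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if self.site_sd_logit < 0:
            raise ConfigurationError(f"site_sd_logit must be >= 0, got {self.site_sd_logit!r}")
        if len(self.regions) < 1:
            raise ConfigurationError("regions must name at least one region")
        if len(set(self.regions)) != len(self.regions):
            raise ConfigurationError("regions must be unique labels")
        w = dict(self.category_weights)
        unknown = set(w) - set(FUNCTIONAL_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"category_weights has unknown categories: {sorted(unknown)}")
        total = sum(w.values())
        if abs(total - 1.0) > 1e-9 or any(x < 0 for x in w.values()):
            raise ConfigurationError(
                f"category_weights must be non-negative and sum to 1 (sum={total})"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = list(self.regions)
        d["category_weights"] = dict(self.category_weights)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**{k: (tuple(v) if k == "regions" else v) for k, v in dict(d).items()})


@dataclass(frozen=True)
class ThresholdSet:
    """Variant-call retention thresholds (all conjunctive, boundaries inclusive).

    Defaults: mean base quality >= 25, alternative-allele depth >= 2, total
    depth >= 10, alternative allele frequency (AAF) >= 1%.
    """

    min_base_quality: float = 25.0
    min_alt_depth: int = 2
    min_depth: int = 10
    min_aaf: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_base_quality", "min_alt_depth", "min_depth", "min_aaf"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        if self.min_aaf > 1:
            raise ConfigurationError(f"min_aaf must be <= 1, got {self.min_aaf!r}")
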