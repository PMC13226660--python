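"""Simulation configuration.

:class:`SimConfig` collects every knob of the synthetic-data generators in
one validated, seed-deterministic record. The defaults define the study
conditions used throughout the test-suite and the analysis scripts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


class SimConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Parameters
    ----------
    seed
        Root seed; fixing it makes every generator output bit-identical.
    n_genes
        Size of the gene universe shared by the bulk and response datasets.
    n_samples_per_tissue
        Bulk samples per tissue (GTEx-like donor count).
    n_tissues
        Tissue columns of the consensus profile (>= 3).
    n_cells_per_cluster
        Cells per single-cell cluster; exactly one entry must be < 10 so the
        small-cluster exclusion filter is exercised.
    module_size
        Genes per planted co-expression module (anchors included).
    module_loading
        Latent-factor loading of module genes, in (0, 1].
    noise_sd
        Gene-level Gaussian noise s.d. of the bulk factor model. Together
        with ``module_loading`` it fixes the within-module correlation
        ``loading^2 / (loading^2 + noise_sd^2)``.
    n_responsive
        Fasting/refeeding-responsive genes in the response dataset.
    blunted_fraction, enhanced_fraction
        Fractions of responsive genes whose knockout response is shrunk /
        amplified beyond the twofold-difference line; remainder concordant.
    nb_dispersion
        Negative-binomial dispersion (gamma shape) shared across genes.
    base_expression_scale
        Baseline bulk expression level (TPM-like units).
    """

    seed: int = 0
    n_genes: int = 2000
    n_samples_per_tissue: int = 60
    n_tissues: int = 12
    n_cells_per_cluster: list[int] = field(
        default_factory=lambda: [120, 80, 60, 40, 9]
    )
    module_size: int = 40
    module_loading: float = 0.9
    noise_sd: float = 0.5
    n_responsive: int = 200
    blunted_fraction: float = 0.85
    enhanced_fraction: float = 0.15
    nb_dispersion: float = 2.0
    base_expression_scale: float = 10.0
    # generator-shape parameters (see docs/methods.md)
    n_broad: int = 40
    n_decoy_groups: int = 2
    profile_noise_sd: float = 0.05
    response_noise_sd: float = 0.15
    n_replicates: int = 4
    n_sc_background: int = 220

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_samples_per_tissue": self.n_samples_per_tissue,
            "n_tissues": self.n_tissues,
            "module_size": self.module_size,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise SimConfigError(f"{name} must be a positive integer, got {value}")
        if self.n_responsive < 0:
            raise SimConfigError("n_responsive must be >= 0")
        if not self.n_cells_per_cluster:
            raise SimConfigError("n_cells_per_cluster must be non-empty")
        if any(c < 1 for c in self.n_cells_per_cluster):
            raise SimConfigError("every cluster must have >= 1 cell")
        if not 0.0 < self.module_loading <= 1.0:
            raise SimConfigError("module_loading must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise SimConfigError("noise_sd must be positive")
        if self.nb_dispersion <= 0:
            raise SimConfigError("nb_dispersion must be positive")
        if self.base_expression_scale <= 0:
            raise SimConfigError("base_expression_scale must be positive")
        for name in ("blunted_fraction", "enhanced_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if self.blunted_fraction + self.enhanced_fraction > 1.0 + 1e-12:
            raise SimConfigError("blunted_fraction + enhanced_fraction must be <= 1")
        if self.module_size > self.n_genes:
            raise SimConfigError("module_size cannot exceed n_genes")
        if self.n_responsive > self.n_genes:
            raise SimConfigError("n_responsive cannot exceed n_genes")
        if self.profile_noise_sd < 0 or self.response_noise_sd < 0:
            raise SimConfigError("noise standard deviations must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SimConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise SimConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(payload)
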