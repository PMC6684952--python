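"""Configuration objects for the synthetic study and the analysis pipeline.

``SimConfig`` holds every generative knob of the synthetic study: the
expression compendium (a planted factor model over ordered disease
phenotypes), the knockdown experiment, the yeast deletion screen, the
protein-interaction network, the survival cohort, and the dose-response
surfaces.  ``PipelineConfig`` holds the analysis-stage parameters with
defaults mirroring the printed settings of the study design the package
emulates (minimum module size 30, merge threshold 0.25, alpha 0.05, STRING
confidence 0.7 with >=2 neighbours, z threshold 1.96).
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


DEFAULT_PHENOTYPES = ("normal", "benign", "HGPIN", "cancer", "CRPC", "metastasis")


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Named child random stream.

    Every generator draws from its own stream derived from (seed, name), so
    adding a generator never perturbs the draws of another.
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode("utf8"))])


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic study."""

    seed: int = 1

    # --- expression compendium (planted factor model) ---
    n_genes: int = 2000
    n_datasets: int = 8
    phenotypes: Sequence[str] = DEFAULT_PHENOTYPES
    samples_per_phenotype: Mapping[str, int] | None = None  # default: 50 each
    n_modules: int = 8
    module_sizes: Sequence[int] = (80, 100, 90, 70, 60, 120, 50, 110)
    # per-module slope of module activity vs phenotype rank (expression
    # units per rank); nonzero entries define the disease modules
    trait_effect: Sequence[float] = (0.6, 0.0, 0.4, 0.0, 0.0, 0.4, 0.0, 0.0)
    batch_sd: float = 0.2
    noise_sd: float = 0.4
    loading_range: tuple[float, float] = (0.5, 1.0)
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5

    # --- knockdown perturbation experiment ---
    perturb_module: int = 0          # 0-based index of the targeted disease module
    perturb_fraction: float = 0.75   # fraction of that module's genes regulated
    perturb_effect: float = 2.0      # mean shift (expression units)
    perturb_noise_sd: float = 0.5
    perturb_replicates: int = 3
    extra_regulated_count: int = 120  # background genes regulated outside the module
    control_artifact_count: int = 40  # genes regulated in the control construct

    # --- yeast deletion screen ---
    n_strains: int = 300
    n_interactors: int = 30
    interaction_effect: float = 0.6  # growth-rate multiplier for suppressors
    sga_replicates: int = 4
    sga_noise_sd: float = 0.05       # lognormal sigma of per-curve replicate noise
    sga_hours: float = 72.0
    sga_interval: float = 6.0
    n_essential: int = 5             # library-absent genes wired into the network

    # --- interaction network / orthology ---
    n_decoy_edges: int = 200
    n_hub_genes: int = 7

    # --- survival cohort ---
    n_patients: int = 200
    altered_fraction: float = 0.2
    alteration_shift: float = 6.0    # cohort SD units; must separate under the z rule
    hazard_ratio: float = 3.0
    baseline_hazard: float = 0.02    # events per month
    censoring_rate: float = 0.3

    # --- dose-response surfaces ---
    drug_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"drug1": (1.5, 50.0), "drug2": (2.0, 200.0)}
    )
    combo_alpha: float = 1.0         # 1 = Loewe additive; <1 synergy; >1 antagonism
    dose_noise_sd: float = 0.0       # sd of logit-scale noise on single-agent rows

    def __post_init__(self) -> None:
        if self.samples_per_phenotype is None:
            self.samples_per_phenotype = {p: 50 for p in self.phenotypes}
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_datasets < 1 or self.n_modules < 1:
            raise ConfigError("all counts must be >= 1")
        if len(self.module_sizes) != self.n_modules:
            raise ConfigError("module_sizes must have n_modules entries")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("sum(module_sizes) exceeds n_genes")
        if len(self.trait_effect) != self.n_modules:
            raise ConfigError("trait_effect must have n_modules entries")
        if not (0.0 < self.perturb_fraction <= 1.0):
            raise ConfigError("perturb_fraction must be in (0, 1]")
        if not (0 <= self.perturb_module < self.n_modules):
            raise ConfigError("perturb_module out of range")
        if self.perturb_replicates < 2:
            raise ConfigError("perturb_replicates must be >= 2 (differential test undefined)")
        if self.n_interactors > self.n_strains:
            raise ConfigError("n_interactors exceeds n_strains")
        if self.interaction_effect <= 0:
            raise ConfigError("interaction_effect (growth-rate multiplier) must be > 0")
        if self.hazard_ratio <= 0:
            raise ConfigError("hazard_ratio must be > 0")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ConfigError("censoring_rate must be in [0, 1)")
        if self.combo_alpha <= 0:
            raise ConfigError("combo_alpha must be > 0")
        for drug, (m, dm) in self.drug_params.items():
            if m <= 0 or dm <= 0:
                raise ConfigError(f"drug {drug!r}: m and Dm must be > 0")
        lo, hi = self.loading_range
        if not (0 < lo <= hi):
            raise ConfigError("loading_range must satisfy 0 < lo <= hi")

    def rng(self, name: str) -> np.random.Generator:
        return child_rng(self.seed, name)

    @property
    def n_samples(self) -> int:
        return sum(self.samples_per_phenotype[p] for p in self.phenotypes)

    @property
    def disease_modules(self) -> frozenset[int]:
        """1-based labels of modules with nonzero phenotype slope."""
        return frozenset(i + 1 for i, s in enumerate(self.trait_effect) if s != 0)


_DEFAULT_BETA_GRID = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20)


@dataclass
class PipelineConfig:
    """Analysis-stage parameters for the full pipeline run."""

    sim: SimConfig = field(default_factory=SimConfig)

    # preprocess
    sd_threshold: float = 2.5
    outlier_scope: str = "per_dataset"  # or "combined"
    skip_outlier_filter: bool = False

    # co-expression network
    beta: float | str = "auto"
    beta_grid: Sequence[float] = _DEFAULT_BETA_GRID
    r2_target: float = 0.8
    network_mode: str = "unsigned"
    min_module_size: int = 30
    merge_threshold: float = 0.25
    cut: float | str = "gap"  # largest-gap midpoint, or a quantile in (0, 1)

    # perturbation
    perturb_alpha: float = 0.05
    perturb_adjust: str | None = None  # None (unadjusted, as printed) or "bh"

    # disease-module selection for the intersection
    trait_for_disease: str = "phenotype_rank"
    disease_p_threshold: float = 0.01

    # SGA
    sga_alpha: float = 0.05
    min_conf: float = 0.7
    min_neighbors: int = 2
    fitness_metric: str = "auc"  # or "endpoint"

    # integration / survival
    z_threshold: float = 1.96
    k_of_m: int | None = None  # None -> all m genes must be altered
    z_method: str = "robust"   # median/MAD reference; "mean" for mean/SD

    # synergy
    ci_form: str = "exclusive"
    additive_tol: float = 0.05

    def validate(self) -> None:
        self.sim.validate()
        if self.sd_threshold <= 0:
            raise ConfigError("sd_threshold must be > 0")
        if self.outlier_scope not in ("per_dataset", "combined"):
            raise ConfigError("outlier_scope must be 'per_dataset' or 'combined'")
        if self.beta != "auto" and float(self.beta) < 1:
            raise ConfigError("beta must be >= 1 or 'auto'")
        if self.network_mode not in ("unsigned", "signed"):
            raise ConfigError("network_mode must be 'unsigned' or 'signed'")
        if not (0 < self.merge_threshold < 1):
            raise ConfigError("merge_threshold must be in (0, 1)")
        if isinstance(self.cut, (int, float)) and not (0 < float(self.cut) < 1):
            raise ConfigError("quantile cut must be in (0, 1)")
        if not (0 <= self.min_conf <= 1):
            raise ConfigError("min_conf must be in [0, 1]")
        if self.min_neighbors < 1:
            raise ConfigError("min_neighbors must be >= 1")
        if self.ci_form not in ("exclusive", "nonexclusive"):
            raise ConfigError("ci_form must be 'exclusive' or 'nonexclusive'")

    # --- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["phenotypes"] = list(self.sim.phenotypes)
        d["sim"]["module_sizes"] = list(self.sim.module_sizes)
        d["sim"]["trait_effect"] = list(self.sim.trait_effect)
        d["sim"]["loading_range"] = list(self.sim.loading_range)
        d["sim"]["samples_per_phenotype"] = dict(self.sim.samples_per_phenotype)
        d["sim"]["drug_params"] = {k: list(v) for k, v in self.sim.drug_params.items()}
        d["beta_grid"] = list(self.beta_grid)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        unknown = set(sim_d) - sim_fields
        if unknown:
            raise ConfigError(f"unknown sim config keys: {sorted(unknown)}")
        if "loading_range" in sim_d:
            sim_d["loading_range"] = tuple(sim_d["loading_range"])
        if "drug_params" in sim_d:
            sim_d["drug_params"] = {k: tuple(v) for k, v in sim_d["drug_params"].items()}
        sim = SimConfig(**sim_d)
        top_fields = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(d) - top_fields
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(sim=sim, **d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
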