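"""Configuration objects for the synthetic study and the pipeline."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class HazardParams:
    """Log-hazard model for progression-free survival (months).

    Defaults follow the multivariable PFS model of the trial analysis:
    a small positive score effect, a small negative treatment effect and a
    negative treatment-by-score interaction.
    """

    baseline_rate: float = 0.015      # events / month under covariates = 0
    treat_coef: float = -0.0797       # TMZ vs RT
    score_coef: float = 0.0502        # per unit of methylation score
    interaction_coef: float = -0.2851 # score x TMZ


@dataclass
class SimConfig:
    """Knobs of the synthetic HM-450K study generator.

    The defaults describe a desk-scale version of a four-dataset low-grade
    glioma study: trimodal probe methylation states in normal brain,
    CIMP hypermethylation of normally-unmethylated promoters in IDH-mutant
    tumors with an extra codeletion-associated shift, negative
    methylation-to-expression coupling for a designated functional gene
    subset, Beta-distributed tumor purity mixing tumor and normal signal,
    per-batch location/scale effects on the M scale, arm-level intensity
    loss on 1p/19q in codeleted samples, and exponential PFS with a
    treatment-by-score interaction.
    """

    n_datasets: int = 4
    n_samples_per_dataset: int = 60
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "IDHwt": 0.2,
            "IDHmt-noncodel": 0.4,
            "IDHmt-codel": 0.4,
        }
    )
    n_genes: int = 120
    cpgs_per_gene: tuple[int, int] = (1, 4)
    n_intergenic_probes: int = 300
    n_other_probes: int = 60
    n_sex_probes: int = 15
    snp_fraction: float = 0.02
    ddr_fraction: float = 0.5
    n_functional_genes: int = 20
    coupling_slope: float = -2.0          # expression units per M unit
    expression_noise_sd: float = 0.5
    state_means_M: tuple[float, float, float] = (-4.0, 0.0, 4.0)
    state_sds_M: tuple[float, float, float] = (0.5, 0.5, 0.5)
    state_weights: tuple[float, float, float] = (0.5, 0.15, 0.35)
    cimp_shift_M: float = 2.0
    codel_extra_shift_M: float = 1.0
    tumor_intergenic_shift_M: float = 1.5
    probe_noise_sd_M: float = 0.3
    ntb_noise_sd_M: float = 0.1
    purity_beta_params: tuple[float, float] = (5.0, 2.0)
    codel_purity_alpha_bonus: float = 2.0
    batch_count: int = 2
    batch_shift_sd: float = 0.3
    batch_scale_sd: float = 0.05
    detection_fail_fraction: float = 0.005
    mean_total_intensity: float = 5000.0
    intensity_offset: float = 100.0
    codel_intensity_factor: float = 0.5   # per-allele loss in tumor cells
    hazard_params: HazardParams = field(default_factory=HazardParams)
    censor_rate: float = 0.01
    n_ntb: int = 5
    seed: int = 0

    def validate(self) -> "SimConfig":
        total = sum(self.subtype_proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError("subtype_proportions must sum to 1")
        means = self.state_means_M
        if not (means[0] < means[1] < means[2]):
            raise ValueError("state_means_M must be strictly increasing")
        for name in (
            "n_datasets",
            "n_samples_per_dataset",
            "n_genes",
            "n_intergenic_probes",
            "n_functional_genes",
            "batch_count",
            "n_ntb",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.cpgs_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("cpgs_per_gene must be a valid (lo, hi) range with lo >= 1")
        if self.cimp_shift_M < 0 or self.codel_extra_shift_M < 0:
            raise ValueError("methylation shifts must be non-negative")
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        if "hazard_params" in raw and isinstance(raw["hazard_params"], dict):
            raw["hazard_params"] = HazardParams(**raw["hazard_params"])
        for key in ("cpgs_per_gene", "state_means_M", "state_sds_M",
                    "state_weights", "purity_beta_params"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw).validate()


DEFAULT_THRESHOLDS = {
    "promoter_window": 1500,
    "det_p_max": 0.01,
    "r_max": -0.3,
    "q_max": 0.1,
    "delta_beta_min": 0.1,
    "log2fc_min": math.log2(1.2),
    "mgmt_cutoff": 0.358,
    "purity_beta_median_max": 0.2,
    "statis_permutations": 999,
    "cbs_alpha": 0.01,
    "cbs_permutations": 200,
    "loss_threshold": -0.2,
    "interaction_q_max": 0.1,
}

PIPELINE_STAGES = [
    "simulate",
    "preprocess",
    "select",
    "mgmt",
    "purity",
    "statis",
    "differential",
    "cnv",
    "survival",
]


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end analysis pipeline."""

    sim: SimConfig = field(default_factory=SimConfig)
    stages: list[str] = field(default_factory=lambda: list(PIPELINE_STAGES))
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        unknown = [s for s in self.stages if s not in PIPELINE_STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        # stages execute in canonical order regardless of listing order
        self.stages = [s for s in PIPELINE_STAGES if s in self.stages]
        th = dict(DEFAULT_THRESHOLDS)
        th.update(self.thresholds)
        self.thresholds = th
        if not (0 < th["q_max"] <= 1) or not (0 < th["mgmt_cutoff"] < 1):
            raise ValueError("thresholds out of range")
        self.sim.validate()
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimConfig.from_dict(raw.pop("sim", {}))
        return cls(sim=sim, **raw).validate()
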