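"""Pipeline configuration: one YAML document with per-stage blocks.

Every tunable threshold and design-decision switch of the pipeline is a
named field with a documented default; seeds are explicit and never
wall-clock. Unknown or missing required fields fail fast with the field
name in the error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import yaml

__all__ = ["PipelineConfig", "ScreenConfig", "PreprocessConfig", "HitConfig",
           "RankingConfig", "SignatureConfig", "MetaboliteConfig"]


def _from_dict(cls, d: dict, context: str):
    if d is None:
        d = {}
    allowed = {f.name for f in fields(cls)}
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown field(s) in {context}: {sorted(unknown)}")
    return cls(**d)


@dataclass
class ScreenConfig:
    """Simulation of the pooled screen (the study conditions)."""

    n_genes: int = 500
    hairpins_per_gene: tuple = (4, 4)
    n_pools: int = 6
    n_replicates: int = 3
    n_protective: int = 20
    n_lethal: int = 20
    effect_size: float = 1.2  # |delta| of planted genes, log2 units
    efficacy_range: tuple = (0.6, 1.0)
    baseline_stress_survival: float = 0.5
    representation: int = 1000
    noise_sd: float = 0.25
    background_median: float = 50.0
    background_log_sd: float = 0.5
    pcr_log2_sd: float = 0.25
    equalize_channel_mass: bool = True
    conditions: tuple = ("hypoxia", "lactic_acidosis")
    shared_hit_fraction: float = 0.25  # true genes shared between the two stresses


@dataclass
class PreprocessConfig:
    background_fold: float = 2.0
    background_channels: str = "both"
    subtract_background: bool = True
    group_by_pool: bool = True


@dataclass
class HitConfig:
    tau: float = 0.7
    min_reps: int = 2
    cv_max: float = 0.5
    min_hairpins: int = 2
    allow_mixed_direction: bool = False


@dataclass
class RankingConfig:
    direction: str = "enrichment"
    n_permutations: int = 1000


@dataclass
class SignatureConfig:
    n_genes: int = 2000
    n_de: int = 50
    overlap: float = 0.6
    effect_size: float = 1.0
    noise_sd: float = 0.5
    samples_per_class: int = 6
    cohort_samples: int = 130
    n_sig: int = 100
    k_factors: int = 2
    ridge: float = 1e-3
    fold: float = 1.7
    min_arrays: int = 6
    filter_scale: str = "fold"


@dataclass
class MetaboliteConfig:
    noise_sd: float = 0.1
    mode: str = "fold"
    numerator: str = "alpha-ketoglutarate"
    denominator: str = "succinate"
    ratio_of_means: bool = False


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    hits: HitConfig = field(default_factory=HitConfig)
    ranking: RankingConfig = field(default_factory=RankingConfig)
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    metabolites: MetaboliteConfig = field(default_factory=MetaboliteConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "outdir" not in d:
            raise ValueError("config missing required field: outdir")
        sub = {
            "screen": ScreenConfig,
            "preprocess": PreprocessConfig,
            "hits": HitConfig,
            "ranking": RankingConfig,
            "signature": SignatureConfig,
            "metabolites": MetaboliteConfig,
        }
        kwargs = {"outdir": d.pop("outdir"), "seed": int(d.pop("seed", 0))}
        for name, subcls in sub.items():
            block = d.pop(name, None)
            if block is not None and not isinstance(block, dict):
                raise ValueError(f"config block {name!r} must be a mapping")
            kwargs[name] = _from_dict(subcls, block, name)
        if d:
            raise ValueError(f"unknown top-level config field(s): {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
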