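"""Run configuration: one YAML-serializable object for the whole pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

STAGE_OF_DIM = {64: 1, 128: 2, 256: 3, 512: 4}


@dataclass
class SimulateConfig:
    n_proteins: int = 50
    images_per_condition: tuple[int, int] = (2, 4)
    tumor_images_per_condition: tuple[int, int] = (5, 8)
    relocated_fraction: float = 0.1
    image_size: int = 96
    noise_sd: float = 0.05
    multi_label_rate: float = 0.1
    low_quality_fraction: float = 0.1
    intensity_choices: tuple[str, ...] = ("strong", "moderate")


@dataclass
class ModelConfig:
    feature_dim: int = 128
    depth: int = 4
    heads: int = 6
    threshold: float = 0.5
    extract_image_size: int = 96


@dataclass
class EnsembleConfig:
    fractions: tuple[float, ...] = (0.9, 0.7)
    repeats: int = 10
    max_epochs: int = 80
    lr: float = 3e-3


@dataclass
class DlpConfig:
    q: float = 0.05
    alpha: float = 0.05
    loo_min_effect: float = 0.02
    require_any_difference: bool = True
    min_count_fraction: float | None = None


@dataclass
class ExpressionConfig:
    enabled: bool = True
    n_proteins: int = 500
    n_tumor: int = 20
    n_normal: int = 20
    n_de: int = 25
    log2fc: float = 2.0
    missing_rate: float = 0.05
    knn_k: int = 10
    ntree: int = 500
    n_random: int = 10


@dataclass
class RunConfig:
    dataset_dir: str = "dataset"
    out_dir: str = "run"
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    dlp: DlpConfig = field(default_factory=DlpConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        kwargs = {}
        sub = {"simulate": SimulateConfig, "model": ModelConfig,
               "ensemble": EnsembleConfig, "dlp": DlpConfig,
               "expression": ExpressionConfig}
        valid = {f.name for f in fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in raw.items():
            if key in sub:
                d = dict(value or {})
                for rk in ("images_per_condition", "tumor_images_per_condition",
                           "intensity_choices"):
                    if rk in d:
                        d[rk] = tuple(d[rk])
                if "fractions" in d:
                    d["fractions"] = tuple(d["fractions"])
                kwargs[key] = sub[key](**d)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
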