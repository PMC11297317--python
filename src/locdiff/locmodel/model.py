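"""Model containers: spec, probability vectors, localization calls."""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from locdiff._rng import substream
from locdiff.categories import CATEGORIES, N_CATEGORIES
from locdiff.locmodel import nn


@dataclass
class ModelSpec:
    """Aggregator hyperparameters.

    depth/heads/feed-forward width follow the reference configuration
    (depth 4, heads 6, feed-forward 4x the feature dimension); feature_dim
    128 and threshold 0.5 are the selected operating point.
    """

    feature_dim: int = 128
    depth: int = 4
    heads: int = 6
    ff_dim: int | None = None
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.ff_dim is None:
            self.ff_dim = 4 * self.feature_dim
        if self.feature_dim not in (64, 128, 256, 512):
            raise ValueError("feature_dim must be one of 64/128/256/512")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0,1)")


@dataclass(frozen=True)
class ProbVector:
    """7-category localization probabilities for one protein+condition.

    Components are independent sigmoid outputs (multi-label); they need not
    sum to one.
    """

    protein_id: str
    condition: str
    p: tuple[float, ...]

    def __post_init__(self):
        if len(self.p) != N_CATEGORIES:
            raise ValueError("probability vector must have 7 components")
        if any(not 0.0 <= v <= 1.0 for v in self.p):
            raise ValueError("probabilities must be in [0,1]")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.p, dtype=float)


@dataclass(frozen=True)
class LocalizationCall:
    protein_id: str
    condition: str
    labels: frozenset[str]
    threshold: float


@dataclass
class TransformerAggregator:
    """A trained multi-instance aggregator with its input standardization."""

    spec: ModelSpec
    params: dict = field(default_factory=dict)
    feat_mean: np.ndarray | None = None
    feat_std: np.ndarray | None = None
    model_id: str = "model"

    @classmethod
    def initialize(cls, spec: ModelSpec, model_id: str = "model",
                   dtype=np.float32) -> "TransformerAggregator":
        rng = substream(spec.seed, "locmodel", "init", model_id)
        params = nn.init_params(rng, spec.feature_dim, spec.depth, spec.heads,
                                spec.ff_dim, N_CATEGORIES, dtype=dtype)
        return cls(spec=spec, params=params, model_id=model_id)

    def set_standardization(self, mean: np.ndarray, std: np.ndarray) -> None:
        self.feat_mean = mean.astype(np.float32)
        self.feat_std = np.maximum(std, 1e-6).astype(np.float32)

    def _standardize(self, tokens: np.ndarray) -> np.ndarray:
        x = np.asarray(tokens, dtype=np.float32)
        if self.feat_mean is not None:
            x = (x - self.feat_mean) / self.feat_std
        return x

    def predict_batch(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """x: (B,T,D) already padded; returns (B,7) probabilities."""
        logits, _ = nn.forward(self.params, x, mask, self.spec.depth, self.spec.heads)
        return 1.0 / (1.0 + np.exp(-logits))

    def predict_proba(self, tokens: np.ndarray) -> np.ndarray:
        """tokens: (T,D) image features of one protein+condition -> 7-vector."""
        tokens = np.atleast_2d(np.asarray(tokens, dtype=np.float32))
        if tokens.shape[0] < 1:
            raise ValueError("need at least one feature vector")
        if tokens.shape[1] != self.spec.feature_dim:
            raise ValueError(
                f"feature dim {tokens.shape[1]} does not match model "
                f"dim {self.spec.feature_dim}")
        x = self._standardize(tokens)[None, ...]
        mask = np.ones((1, x.shape[1]), dtype=np.float32)
        return self.predict_batch(x, mask)[0].astype(float)

    def predict_probvector(self, protein_id: str, condition: str,
                           tokens: np.ndarray) -> ProbVector:
        return ProbVector(protein_id, condition, tuple(self.predict_proba(tokens)))

    def save(self, path: str) -> None:
        os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
        meta = {"spec": asdict(self.spec), "model_id": self.model_id}
        arrays = dict(self.params)
        if self.feat_mean is not None:
            arrays["__feat_mean"] = self.feat_mean
            arrays["__feat_std"] = self.feat_std
        np.savez(path, __meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str) -> "TransformerAggregator":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta"]).decode())
            params = {k: data[k] for k in data.files if not k.startswith("__")}
            mean = data["__feat_mean"] if "__feat_mean" in data.files else None
            std = data["__feat_std"] if "__feat_std" in data.files else None
        model = cls(spec=ModelSpec(**meta["spec"]), params=params,
                    model_id=meta["model_id"])
        if mean is not None:
            model.feat_mean, model.feat_std = mean, std
        return model


def labels_to_matrix(label_sets: list[frozenset[str]]) -> np.ndarray:
    """(B,7) 0/1 matrix in category order."""
    y = np.zeros((len(label_sets), N_CATEGORIES), dtype=np.float32)
    for i, labels in enumerate(label_sets):
        for lab in labels:
            y[i, CATEGORIES.index(lab)] = 1.0
    return y
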