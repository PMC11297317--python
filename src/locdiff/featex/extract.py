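"""Run the backbone over image records and cache features as TSV tables."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from PIL import Image

from locdiff.featex.backbone import STAGE_DIMS, ResidualBackbone


def _load_image(path: str, image_size: int) -> np.ndarray:
    try:
        with Image.open(path) as im:
            im = im.convert("RGB").resize((image_size, image_size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float32) / 255.0
    except OSError as exc:
        raise OSError(f"cannot read image {path!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-size image: {path!r}")
    # fixed standardization; the aggregator re-standardizes features anyway
    arr = (arr - 0.5) / 0.25
    return arr.transpose(2, 0, 1)


def extract_features(records, stage: int = 2, weights: str = "random",
                     seed: int = 0, image_size: int = 64,
                     backbone: ResidualBackbone | None = None) -> pd.DataFrame:
    """One feature row per image record.

    Returns a DataFrame with protein_id, condition, path and f0..f{D-1}
    columns, D = {64,128,256,512}[stage].  Deterministic for a fixed seed.
    """
    if stage not in STAGE_DIMS:
        raise ValueError(f"stage must be in 1..4, got {stage}")
    if backbone is None:
        backbone = ResidualBackbone(weights=weights, seed=seed)
    dim = STAGE_DIMS[stage]
    rows = []
    vectors = []
    for rec in records:
        vec = backbone.forward(_load_image(rec.path, image_size), stage=stage)
        assert vec.shape == (dim,)
        # per-image L2 normalization: the rectified backbone is positively
        # homogeneous, so overall stain intensity mostly rescales the GAP
        # vector; normalizing removes that nuisance factor
        vec = vec / max(float(np.linalg.norm(vec)), 1e-8)
        rows.append((rec.protein_id, rec.condition, rec.path))
        vectors.append(vec)
    feats = pd.DataFrame(np.stack(vectors) if vectors else np.empty((0, dim), np.float32),
                         columns=[f"f{i}" for i in range(dim)])
    head = pd.DataFrame(rows, columns=["protein_id", "condition", "path"])
    return pd.concat([head, feats], axis=1)


def save_feature_table(features: pd.DataFrame, path: str) -> None:
    # %.9g preserves float32 exactly, so cached features reproduce
    # in-memory results bit for bit
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    features.to_csv(path, sep="\t", index=False, float_format="%.9g")


def load_feature_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def bag_feature_map(features: pd.DataFrame) -> dict[str, dict[str, np.ndarray]]:
    """Group a feature table into per-protein, per-condition token arrays.

    Returns ``{protein_id: {condition: (T, D) float32 array}}`` preserving
    the table's image order.
    """
    fcols = [c for c in features.columns if c.startswith("f")]
    out: dict[str, dict[str, np.ndarray]] = {}
    for (pid, cond), grp in features.groupby(["protein_id", "condition"], sort=True):
        out.setdefault(str(pid), {})[str(cond)] = \
            grp[fcols].to_numpy(dtype=np.float32)
    return out
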