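"""Generate a synthetic IHC image dataset with a planted relocation truth.

Layout written under ``out_dir``::

    images/<protein>_<condition>_<k>.png
    metadata.tsv   protein_id, condition, path, intensity, quantity_pct, reliability
    truth.tsv      protein_id, normal_labels, tumor_labels, is_relocated
    labels.tsv     protein_id, raw_location, reliability   (normal-condition truth)

Default class weights mimic a Nuclear-dominant breast IHC corpus.  A small
fraction of images is rendered weak or sparsely stained so the screening
rules have something to reject; the first two images of every condition are
always screen-passing so no protein is lost to screening by construction.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from locdiff._rng import substream
from locdiff.categories import CATEGORIES
from locdiff.synthgen.render import PatternSpec, render_image

# protein-count proportions of a Nuclear-heavy breast IHC corpus
DEFAULT_LABEL_WEIGHTS = np.array([72, 12, 20, 46, 19, 170, 24], dtype=float)
DEFAULT_LABEL_WEIGHTS /= DEFAULT_LABEL_WEIGHTS.sum()


@dataclass
class TruthRow:
    protein_id: str
    normal_labels: frozenset[str]
    tumor_labels: frozenset[str]

    @property
    def is_relocated(self) -> bool:
        return self.normal_labels != self.tumor_labels


def _sample_label_set(rng, weights, multi_label_rate):
    primary = rng.choice(len(CATEGORIES), p=weights)
    labels = {CATEGORIES[primary]}
    if rng.uniform() < multi_label_rate:
        others = [i for i in range(len(CATEGORIES)) if i != primary]
        w = weights[others] / weights[others].sum()
        labels.add(CATEGORIES[rng.choice(others, p=w)])
    return frozenset(labels)


def _relocate(rng, normal_labels):
    """Tumor label set with the dominant compartment swapped out."""
    pool = [c for c in CATEGORIES if c not in normal_labels]
    new = rng.choice(pool)
    keep = sorted(normal_labels)
    dropped = keep[rng.integers(len(keep))]
    tumor = (set(normal_labels) - {dropped}) | {new}
    return frozenset(tumor)


def generate_image_dataset(
    out_dir,
    n_proteins: int = 50,
    images_per_condition: tuple[int, int] = (2, 4),
    tumor_images_per_condition: tuple[int, int] | None = (5, 8),
    relocated_fraction: float = 0.1,
    label_weights=None,
    image_size: int = 96,
    noise_sd: float = 0.05,
    multi_label_rate: float = 0.1,
    low_quality_fraction: float = 0.1,
    intensity_choices: tuple[str, ...] = ("strong", "moderate"),
    seed: int = 0,
) -> pd.DataFrame:
    """Write the dataset and return the truth table as a DataFrame.

    Exactly ``round(relocated_fraction * n_proteins)`` proteins are planted
    as relocated.  Identical seeds give byte-identical TSVs and
    pixel-identical images.

    Tumor bags default to a larger size range than normal bags, mirroring
    the roughly threefold tumor/normal image imbalance of breast IHC
    corpora; pass ``tumor_images_per_condition=None`` to use the normal
    range for both conditions.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    lo, hi = images_per_condition
    if lo < 1 or hi < lo:
        raise ValueError("images_per_condition must be a (low, high) range with low >= 1")
    t_lo, t_hi = tumor_images_per_condition or images_per_condition
    if t_lo < 1 or t_hi < t_lo:
        raise ValueError("tumor_images_per_condition must be a valid range")
    if not 0.0 <= relocated_fraction <= 1.0:
        raise ValueError("relocated_fraction must be in [0, 1]")
    if label_weights is None:
        label_weights = DEFAULT_LABEL_WEIGHTS
    label_weights = np.asarray(label_weights, dtype=float)
    if label_weights.shape != (len(CATEGORIES),):
        raise ValueError("label_weights must have one weight per category")
    if abs(label_weights.sum() - 1.0) > 1e-6:
        raise ValueError("label_weights must sum to 1")

    rng = substream(seed, "synthgen", "design")
    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)

    n_relocated = int(round(relocated_fraction * n_proteins))
    relocated_idx = set(rng.choice(n_proteins, size=n_relocated, replace=False).tolist())

    truth_rows: list[TruthRow] = []
    meta_rows = []
    label_rows = []
    for i in range(n_proteins):
        pid = f"P{i:04d}"
        normal = _sample_label_set(rng, label_weights, multi_label_rate)
        tumor = _relocate(rng, normal) if i in relocated_idx else normal
        truth_rows.append(TruthRow(pid, normal, tumor))
        for lab in sorted(normal):
            label_rows.append({"protein_id": pid, "raw_location": lab,
                               "reliability": "enhanced"})

        for condition, labels in (("normal", normal), ("tumor", tumor)):
            c_lo, c_hi = (lo, hi) if condition == "normal" else (t_lo, t_hi)
            n_img = int(rng.integers(c_lo, c_hi + 1))
            for k in range(n_img):
                img_rng = substream(seed, "synthgen", "image", pid, condition, k)
                # the first two images of a condition always pass screening
                degraded = k >= 2 and img_rng.uniform() < low_quality_fraction
                if degraded:
                    if img_rng.uniform() < 0.5:
                        intensity = "weak"
                        quantity = float(img_rng.integers(60, 101))
                    else:
                        intensity = str(img_rng.choice(["strong", "moderate"]))
                        quantity = float(img_rng.integers(40, 76))
                else:
                    intensity = str(img_rng.choice(list(intensity_choices)))
                    quantity = float(img_rng.integers(78, 101))
                spec = PatternSpec(tuple(sorted(labels)), stain_intensity=intensity,
                                   stained_quantity=quantity)
                img = render_image(spec, size=image_size, noise_sd=noise_sd, rng=img_rng)
                rel_path = os.path.join("images", f"{pid}_{condition}_{k}.png")
                Image.fromarray(img).save(os.path.join(out_dir, rel_path))
                meta_rows.append({
                    "protein_id": pid, "condition": condition, "path": rel_path,
                    "intensity": intensity, "quantity_pct": quantity,
                    "reliability": "enhanced",
                })

    meta = pd.DataFrame(meta_rows)
    meta.to_csv(os.path.join(out_dir, "metadata.tsv"), sep="\t", index=False)
    truth = pd.DataFrame({
        "protein_id": [t.protein_id for t in truth_rows],
        "normal_labels": [";".join(sorted(t.normal_labels)) for t in truth_rows],
        "tumor_labels": [";".join(sorted(t.tumor_labels)) for t in truth_rows],
        "is_relocated": [t.is_relocated for t in truth_rows],
    })
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    pd.DataFrame(label_rows).to_csv(os.path.join(out_dir, "labels.tsv"),
                                    sep="\t", index=False)
    return truth
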