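"""Dataset loading, screening rules and the 7-category label mapping.

Screening keeps only images whose staining intensity is strong or moderate
and whose stained quantity is strictly above 75%.  Protein bags are then
built from the surviving images: a protein must have images in both the
normal and the tumor condition and at least two images in total; label rows
below the requested reliability ("enhanced") are dropped before attaching
known normal-condition labels.

The raw-sublocation -> 7-category mapping ships as an editable TSV seeded
with common atlas sublocation names.  The true grouping used to build the
reference corpus is not published, so the shipped table is a best-effort
stand-in; unknown terms are hard errors rather than silent drops, because
silently losing labels corrupts training.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from locdiff.categories import CATEGORIES

_DATA_DIR = os.path.join(os.path.dirname(__file__), "data")

INTENSITY_LEVELS = ("strong", "moderate", "weak")
RELIABILITY_LEVELS = ("enhanced", "supported", "approved")


@dataclass(frozen=True)
class ImageRecord:
    """One IHC image with its protein, condition and staining covariates."""

    protein_id: str
    condition: str
    path: str
    intensity: str
    quantity_pct: float
    reliability: str = "enhanced"

    def __post_init__(self):
        if self.condition not in ("normal", "tumor"):
            raise ValueError(f"condition must be normal/tumor, got {self.condition!r}")
        if self.intensity not in INTENSITY_LEVELS:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        if not 0.0 <= self.quantity_pct <= 100.0:
            raise ValueError("quantity_pct must be in [0, 100]")


@dataclass
class ProteinBag:
    """A protein's per-condition image sets plus its known label set."""

    protein_id: str
    normal_images: list = field(default_factory=list)
    tumor_images: list = field(default_factory=list)
    known_labels: frozenset[str] = frozenset()

    @property
    def n_images(self) -> int:
        return len(self.normal_images) + len(self.tumor_images)


def load_image_records(dataset_dir, check_paths: bool = True) -> list[ImageRecord]:
    """Read metadata.tsv from a dataset directory into ImageRecords."""
    meta = pd.read_csv(os.path.join(dataset_dir, "metadata.tsv"), sep="\t")
    records = []
    for row in meta.itertuples(index=False):
        path = os.path.join(dataset_dir, row.path)
        if check_paths and not os.path.exists(path):
            raise FileNotFoundError(f"image listed in metadata does not exist: {path}")
        records.append(ImageRecord(str(row.protein_id), row.condition, path,
                                   row.intensity, float(row.quantity_pct),
                                   row.reliability))
    return records


def screen_images(records: list[ImageRecord]) -> list[ImageRecord]:
    """Keep images with strong/moderate intensity and quantity > 75 (strict)."""
    return [r for r in records
            if r.intensity in ("strong", "moderate") and r.quantity_pct > 75.0]


@lru_cache(maxsize=4)
def _load_mapping(path: str) -> dict[str, str]:
    table = pd.read_csv(path, sep="\t")
    mapping = {}
    for row in table.itertuples(index=False):
        cat = row.category
        if cat not in CATEGORIES:
            raise ValueError(f"mapping table targets unknown category {cat!r}")
        mapping[str(row.raw_location).strip().lower()] = cat
    return mapping


def map_labels(raw_location: str, mapping_path: str | None = None) -> str:
    """Map a raw sublocation annotation to one of the 7 categories."""
    path = mapping_path or os.path.join(_DATA_DIR, "location_map.tsv")
    mapping = _load_mapping(path)
    key = raw_location.strip().lower()
    if key not in mapping:
        raise KeyError(
            f"no 7-category mapping for sublocation {raw_location!r}; "
            f"add it to {path}"
        )
    return mapping[key]


def load_label_table(path) -> pd.DataFrame:
    """Read a label TSV (protein_id, raw_location, reliability)."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"protein_id", "raw_location", "reliability"} - set(table.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    return table


def build_bags(records: list[ImageRecord], labels: pd.DataFrame,
               reliability_filter: bool = True,
               mapping_path: str | None = None) -> list[ProteinBag]:
    """Assemble screened images into per-protein bags with known labels.

    Proteins lacking either condition, or with fewer than two images in
    total, are dropped.  Label rows are reliability-filtered (enhanced only)
    before mapping; a protein whose filtered label set is empty is dropped
    from the result (it cannot be used for training).
    """
    if reliability_filter:
        labels = labels[labels["reliability"] == "enhanced"]
    known: dict[str, set[str]] = {}
    for row in labels.itertuples(index=False):
        cat = map_labels(row.raw_location, mapping_path)
        known.setdefault(str(row.protein_id), set()).add(cat)

    by_protein: dict[str, ProteinBag] = {}
    for rec in records:
        bag = by_protein.setdefault(rec.protein_id, ProteinBag(rec.protein_id))
        (bag.normal_images if rec.condition == "normal" else bag.tumor_images).append(rec)

    bags = []
    for pid in sorted(by_protein):
        bag = by_protein[pid]
        if not bag.normal_images or not bag.tumor_images or bag.n_images < 2:
            continue
        if pid not in known or not known[pid]:
            continue
        bag.known_labels = frozenset(known[pid])
        bags.append(bag)
    return bags


def summarize(bags: list[ProteinBag]) -> pd.DataFrame:
    """Per-label protein and image counts (label-distribution summary).

    Multi-label proteins count once under every label they carry, so label
    columns can sum to more than the distinct totals given in the last row.
    """
    rows = []
    for cat in CATEGORIES:
        with_cat = [b for b in bags if cat in b.known_labels]
        rows.append({
            "label": cat,
            "proteins": len(with_cat),
            "normal_images": sum(len(b.normal_images) for b in with_cat),
            "tumor_images": sum(len(b.tumor_images) for b in with_cat),
        })
    rows.append({
        "label": "Total",
        "proteins": len(bags),
        "normal_images": sum(len(b.normal_images) for b in bags),
        "tumor_images": sum(len(b.tumor_images) for b in bags),
    })
    return pd.DataFrame(rows)
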