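"""The fixed 7-category subcellular localization scheme.

The order is contractual: probability vectors, label matrices and TSV
columns all use this ordering.
"""

CATEGORIES: tuple[str, ...] = (
    "Cytoplasm",
    "Endoplasmic reticulum",
    "Golgi apparatus",
    "Mitochondria",
    "Plasma membrane",
    "Nuclear",
    "Vesicles",
)

N_CATEGORIES = len(CATEGORIES)

CATEGORY_INDEX = {name: i for i, name in enumerate(CATEGORIES)}


def label_set_to_vector(labels) -> list[int]:
    """0/1 indicator vector (category order) for a set of category names."""
    unknown = set(labels) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown localization categories: {sorted(unknown)}")
    return [1 if c in set(labels) else 0 for c in CATEGORIES]


def vector_to_label_set(indicator) -> frozenset[str]:
    if len(indicator) != N_CATEGORIES:
        raise ValueError("indicator must have length 7")
    return frozenset(c for c, v in zip(CATEGORIES, indicator) if v)
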