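"""Synthetic proteins-by-samples expression matrices (log2 scale).

Three kinds of structure are planted on top of i.i.d. Gaussian noise around
per-protein baselines:

* ``de_ids``  - differentially expressed rows: the tumor group mean is
  shifted by ``log2fc`` (these should pass a p < 0.05, |log2FC| > 1 filter).
* ``dlp_ids`` - rows that emulate differentially *localized* proteins: a
  modest, low-noise group shift that carries classification signal while
  staying below the fold-change gate (such proteins are typically not DE).
* missingness - completely-at-random holes at ``missing_rate``, plus a small
  fraction of rows with ~45% missing cells so the >30%-missing row filter
  has something to drop.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from locdiff._rng import substream


def generate_expression(
    n_proteins: int = 1000,
    n_tumor: int = 20,
    n_normal: int = 20,
    dlp_ids=(),
    de_ids=(),
    log2fc: float = 2.0,
    noise_sd: float = 0.5,
    dlp_log2fc: float = 0.6,
    dlp_noise_sd: float = 0.35,
    missing_rate: float = 0.05,
    high_missing_fraction: float = 0.05,
    seed: int = 0,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Return (matrix, sample_condition); optionally write both as TSVs.

    The matrix is proteins x samples with protein ids ``P0000``... as the
    index; ``sample_condition`` maps sample id -> {tumor, normal}.
    """
    if n_proteins < 1 or n_tumor < 2 or n_normal < 2:
        raise ValueError("need >= 1 protein and >= 2 samples per condition")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    ids = [f"P{i:04d}" for i in range(n_proteins)]
    id_set = set(ids)
    dlp_ids, de_ids = set(dlp_ids), set(de_ids)
    unknown = (dlp_ids | de_ids) - id_set
    if unknown:
        raise ValueError(f"unknown protein ids: {sorted(unknown)[:5]}")
    both = dlp_ids & de_ids
    if both:
        raise ValueError(
            f"ids planted as both DE and DLP are ambiguous: {sorted(both)[:5]}"
        )

    rng = substream(seed, "synthgen", "expression")
    samples = [f"T{i:03d}" for i in range(n_tumor)] + [f"N{i:03d}" for i in range(n_normal)]
    condition = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal,
                          index=samples, name="condition")
    is_tumor = np.array([c == "tumor" for c in condition], dtype=float)

    baseline = rng.normal(22.0, 1.5, size=n_proteins)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_proteins, len(samples)))
    for i, pid in enumerate(ids):
        if pid in de_ids:
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            values[i] += sign * log2fc * is_tumor
        elif pid in dlp_ids:
            sign = 1.0 if rng.uniform() < 0.5 else -1.0
            shift = sign * dlp_log2fc * is_tumor
            values[i] = baseline[i] + shift + rng.normal(0.0, dlp_noise_sd, len(samples))

    mask = rng.uniform(size=values.shape) < missing_rate
    n_high = int(round(high_missing_fraction * n_proteins))
    if n_high:
        protected = dlp_ids | de_ids
        eligible = [i for i, pid in enumerate(ids) if pid not in protected]
        high_rows = rng.choice(eligible, size=min(n_high, len(eligible)), replace=False)
        for i in high_rows:
            mask[i] = rng.uniform(size=len(samples)) < 0.45
    values[mask] = np.nan

    matrix = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"), columns=samples)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        matrix.to_csv(os.path.join(out_dir, "expression.tsv"), sep="\t")
        condition.rename_axis("sample_id").reset_index().to_csv(
            os.path.join(out_dir, "sample_condition.tsv"), sep="\t", index=False)
    return matrix, condition
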