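"""Generator contracts: determinism, planted-truth bookkeeping, separability."""

import filecmp

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from locdiff.categories import CATEGORIES
from locdiff.synthgen import (
    PatternSpec,
    generate_expression,
    generate_image_dataset,
    render_image,
)
from locdiff.synthgen.render import brownness


def test_empty_request_rejected(tmp_path):
    with pytest.raises(ValueError):
        generate_image_dataset(tmp_path, n_proteins=0)


def test_bad_label_weights_rejected(tmp_path):
    weights = np.ones(7) / 6.0  # sums to 7/6
    with pytest.raises(ValueError, match="sum to 1"):
        generate_image_dataset(tmp_path, n_proteins=3, label_weights=weights)


def test_planted_relocation_count_is_exact(tmp_path):
    truth = generate_image_dataset(
        tmp_path, n_proteins=50, images_per_condition=(1, 1),
        relocated_fraction=0.1, image_size=32, seed=7)
    assert int(truth["is_relocated"].sum()) == 5  # round(0.1 * 50)
    # relocation is exactly set inequality of the label columns
    neq = truth["normal_labels"] != truth["tumor_labels"]
    assert (neq == truth["is_relocated"]).all()
    assert (truth["normal_labels"].str.len() > 0).all()


def test_seed_determinism_and_seed_sensitivity(tmp_path):
    a, b, c = tmp_path / "a", tmp_path / "b", tmp_path / "c"
    for d, seed in ((a, 7), (b, 7), (c, 8)):
        generate_image_dataset(d, n_proteins=4, images_per_condition=(1, 2),
                               image_size=48, seed=seed)
    for name in ("truth.tsv", "metadata.tsv", "labels.tsv"):
        assert filecmp.cmp(a / name, b / name, shallow=False)
    img = "images/P0000_normal_0.png"
    assert (a / img).read_bytes() == (b / img).read_bytes()
    assert not filecmp.cmp(a / "truth.tsv", c / "truth.tsv", shallow=False) or \
        (a / img).read_bytes() != (c / img).read_bytes()


def test_every_protein_has_both_conditions(tiny_dataset):
    root, truth = tiny_dataset
    meta = pd.read_csv(root / "metadata.tsv", sep="\t")
    per = meta.groupby(["protein_id", "condition"]).size().unstack()
    assert (per["normal"] >= 1).all() and (per["tumor"] >= 1).all()
    assert set(per.index) == set(truth["protein_id"])


def _profile(img):
    """Stain-intensity profile statistics: coverage, edge density, granularity."""
    from scipy import ndimage

    b = brownness(img)
    covers = [(b > t).mean() for t in (0.06, 0.15, 0.28)]
    grad = np.abs(np.diff(b, axis=0)).mean() + np.abs(np.diff(b, axis=1)).mean()
    fine = np.abs(b - ndimage.uniform_filter(b, 5)).mean()
    lab, n = ndimage.label(b > 0.15)
    sizes = ndimage.sum(np.ones_like(b), lab, range(1, n + 1)) if n else [0]
    comp = np.log1p(np.mean(sizes)) if n else 0.0
    return np.array([b.mean(), *covers, grad, fine, n / 100.0, comp])


def test_patterns_separable_by_intensity_profiles():
    """A nearest-centroid stain-profile classifier gets >90% on noise-free images."""
    rng = np.random.default_rng(0)
    X, Y = [], []
    for label in CATEGORIES:
        for _ in range(12):
            spec = PatternSpec((label,), stain_intensity="strong",
                               stained_quantity=90.0)
            img = render_image(spec, size=96, noise_sd=0.0,
                               rng=np.random.default_rng(rng.integers(2**31)))
            X.append(_profile(img))
            Y.append(label)
    X, Y = np.array(X), np.array(Y)
    Xs = (X - X.mean(0)) / (X.std(0) + 1e-9)
    cent = {lab: Xs[np.where(Y == lab)[0][:6]].mean(0) for lab in CATEGORIES}
    test_idx = [i for lab in CATEGORIES for i in np.where(Y == lab)[0][6:]]
    correct = sum(
        1 for i in test_idx
        if min(cent, key=lambda c: np.linalg.norm(Xs[i] - cent[c])) == Y[i])
    assert correct / len(test_idx) > 0.9


def test_multilabel_composites_contain_both_patterns():
    rng = np.random.default_rng(3)
    single = render_image(PatternSpec(("Nuclear",)), size=64, noise_sd=0.0,
                          rng=np.random.default_rng(3))
    combo = render_image(PatternSpec(("Cytoplasm", "Nuclear")), size=64,
                         noise_sd=0.0, rng=np.random.default_rng(3))
    # compositing can only add stain
    assert brownness(combo).mean() > brownness(single).mean()


def test_expression_no_missing_when_rate_zero():
    m, cond = generate_expression(n_proteins=50, missing_rate=0.0,
                                  high_missing_fraction=0.0, seed=1)
    assert not m.isna().any().any()
    assert set(cond.unique()) == {"tumor", "normal"}


def test_expression_null_pvalues_uniform():
    """With nothing planted, row t-tests behave like the null."""
    from scipy import stats
    m, cond = generate_expression(n_proteins=1000, missing_rate=0.0,
                                  high_missing_fraction=0.0, seed=5)
    t = m.loc[:, cond == "tumor"].to_numpy()
    n = m.loc[:, cond == "normal"].to_numpy()
    p = stats.ttest_ind(t, n, axis=1, equal_var=False).pvalue
    frac = float((p < 0.05).mean())
    # 3 sigma binomial band around 0.05 at 1000 rows
    assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 1000) + 1e-9


def test_expression_rejects_bad_ids():
    with pytest.raises(ValueError, match="unknown"):
        generate_expression(n_proteins=10, de_ids=["P9999"], seed=0)
    with pytest.raises(ValueError, match="ambiguous"):
        generate_expression(n_proteins=10, de_ids=["P0001"],
                            dlp_ids=["P0001"], seed=0)


def test_rendered_images_are_valid_png(tiny_dataset):
    root, _ = tiny_dataset
    meta = pd.read_csv(root / "metadata.tsv", sep="\t")
    path = root / meta.iloc[0]["path"]
    with Image.open(path) as im:
        assert im.size == (64, 64) and im.mode == "RGB"
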