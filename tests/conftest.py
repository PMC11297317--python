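import numpy as np
import pytest

from locdiff.dataio import build_bags, load_image_records, load_label_table, screen_images
from locdiff.featex import bag_feature_map, extract_features
from locdiff.synthgen import generate_image_dataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 12-protein dataset with planted relocations, small and fast."""
    root = tmp_path_factory.mktemp("tiny_ds")
    truth = generate_image_dataset(
        root, n_proteins=12, images_per_condition=(2, 3),
        relocated_fraction=0.25, image_size=64, noise_sd=0.05, seed=42)
    return root, truth


@pytest.fixture(scope="session")
def tiny_bags(tiny_dataset):
    root, _ = tiny_dataset
    records = screen_images(load_image_records(root))
    labels = load_label_table(root / "labels.tsv")
    return build_bags(records, labels)


@pytest.fixture(scope="session")
def tiny_features(tiny_bags):
    records = [r for b in tiny_bags for r in b.normal_images + b.tumor_images]
    table = extract_features(records, stage=2, seed=1, image_size=48)
    return table


@pytest.fixture(scope="session")
def tiny_bag_features(tiny_features):
    return bag_feature_map(tiny_features)


@pytest.fixture(scope="session")
def tiny_labels(tiny_bags):
    return {b.protein_id: b.known_labels for b in tiny_bags}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
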