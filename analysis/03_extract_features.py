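#!/usr/bin/env python
"""Extract 128-d backbone features for every screened study image.

Stage-2 features of the seeded random-weight residual backbone, globally
average-pooled and L2-normalized per image, cached as a TSV for the
training stages.
"""

import os
import sys
import time

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from locdiff import dataio  # noqa: E402
from locdiff._rng import substream_seed  # noqa: E402
from locdiff.featex import extract_features, save_feature_table  # noqa: E402
from locdiff.study import study_config  # noqa: E402

ROOT = os.path.join(os.path.dirname(__file__), "..")


def main():
    cfg = study_config(os.path.join(ROOT, "scratch", "study"), seed=1)
    records = dataio.screen_images(dataio.load_image_records(cfg.dataset_dir))
    bags = dataio.build_bags(records, dataio.load_label_table(
        os.path.join(cfg.dataset_dir, "labels.tsv")))
    kept = [r for b in bags for r in b.normal_images + b.tumor_images]
    t0 = time.perf_counter()
    feats = extract_features(kept, stage=2,
                             seed=substream_seed(cfg.seed, "featex"),
                             image_size=cfg.model.extract_image_size)
    out = os.path.join(ROOT, "scratch", "study", "features_128.tsv")
    save_feature_table(feats, out)
    print(f"extracted {len(feats)} x 128 features in "
          f"{time.perf_counter() - t0:.1f}s -> {out}")


if __name__ == "__main__":
    main()
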