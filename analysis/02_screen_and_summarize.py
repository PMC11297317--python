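#!/usr/bin/env python
"""Screen the study images and tabulate the label distribution.

Applies the staining-quality rules (intensity strong/moderate, stained
quantity > 75%), drops proteins lacking either condition or with fewer than
two images, and writes the per-label protein/image count matrix alongside
the published breast-corpus counts for a side-by-side look.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd  # noqa: E402

from locdiff import dataio  # noqa: E402

ROOT = os.path.join(os.path.dirname(__file__), "..")
DATASET = os.path.join(ROOT, "scratch", "study", "dataset")


def main():
    records = dataio.load_image_records(DATASET)
    screened = dataio.screen_images(records)
    bags = dataio.build_bags(screened, dataio.load_label_table(
        os.path.join(DATASET, "labels.tsv")))
    summary = dataio.summarize(bags)
    out = os.path.join(ROOT, "results", "02_label_summary.tsv")
    summary.to_csv(out, sep="\t", index=False)
    print(f"{len(screened)}/{len(records)} images pass screening; "
          f"{len(bags)} protein bags retained")
    print(summary.to_string(index=False))
    reference = pd.read_csv(os.path.join(dataio._DATA_DIR,
                                         "hpa_breast_label_counts.tsv"), sep="\t")
    print("\npublished breast-corpus label distribution for comparison:")
    print(reference.to_string(index=False))


if __name__ == "__main__":
    main()
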