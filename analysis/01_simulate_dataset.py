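#!/usr/bin/env python
"""Generate the synthetic breast-IHC study dataset.

Fifty proteins with Nuclear-heavy multi-label truth, 2-4 normal and 5-8
tumor images each, 10% of proteins relocated in the tumor condition.
Images and per-image metadata land under scratch/study/dataset; the planted
truth table is copied to results/ for the later stages to score against.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from locdiff.pipeline import simulate_dataset  # noqa: E402
from locdiff.study import study_config  # noqa: E402

SEED = 1
ROOT = os.path.join(os.path.dirname(__file__), "..")


def main():
    cfg = study_config(os.path.join(ROOT, "scratch", "study"), seed=SEED)
    truth = simulate_dataset(cfg)
    os.makedirs(os.path.join(ROOT, "results"), exist_ok=True)
    truth.to_csv(os.path.join(ROOT, "results", "01_truth.tsv"),
                 sep="\t", index=False)
    n_rel = int(truth["is_relocated"].sum())
    print(f"wrote {len(truth)} proteins ({n_rel} relocated) "
          f"to {cfg.dataset_dir}")


if __name__ == "__main__":
    main()
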