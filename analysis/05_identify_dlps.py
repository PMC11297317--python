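#!/usr/bin/env python
"""Train the resampling ensembles and identify differentially localized
proteins.

Twenty models (10 at 90% sampling, 10 at 70%) are trained on normal-
condition bags; the three filters — upper-quartile stability of difference
calls in both schemes, top-distance selection under the best member, and
leave-one-image-out robustness — are intersected, and the final set is
scored against the planted relocation truth.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd  # noqa: E402

from locdiff import dataio, dlpid  # noqa: E402
from locdiff._rng import substream_seed  # noqa: E402
from locdiff.featex import bag_feature_map, load_feature_table  # noqa: E402
from locdiff.locmodel import ModelSpec, run_ensembles  # noqa: E402
from locdiff.study import precision_recall, study_config  # noqa: E402

ROOT = os.path.join(os.path.dirname(__file__), "..")


def main():
    cfg = study_config(os.path.join(ROOT, "scratch", "study"), seed=1)
    feats = load_feature_table(os.path.join(ROOT, "scratch", "study",
                                            "features_128.tsv"))
    bag_features = bag_feature_map(feats)
    records = dataio.screen_images(dataio.load_image_records(cfg.dataset_dir))
    bags = dataio.build_bags(records, dataio.load_label_table(
        os.path.join(cfg.dataset_dir, "labels.tsv")))
    labels = {b.protein_id: b.known_labels for b in bags}

    spec = ModelSpec(feature_dim=128, threshold=cfg.model.threshold,
                     seed=substream_seed(cfg.seed, "locmodel"))
    ensemble = run_ensembles(bag_features, labels, spec,
                             seed=substream_seed(cfg.seed, "ensemble"),
                             max_epochs=cfg.ensemble.max_epochs,
                             lr=cfg.ensemble.lr)
    result = dlpid.identify_dlps(ensemble, bag_features,
                                 threshold=cfg.model.threshold,
                                 q=cfg.dlp.q, alpha=cfg.dlp.alpha,
                                 loo_min_effect=cfg.dlp.loo_min_effect,
                                 min_count_fraction=cfg.dlp.min_count_fraction)

    result.ledger.table.to_csv(os.path.join(ROOT, "results", "05_dlp_ledger.tsv"),
                               sep="\t", index=False, float_format="%.6g")
    with open(os.path.join(ROOT, "results", "05_dlp_result.json"), "w") as fh:
        fh.write(result.to_json())

    truth = pd.read_csv(os.path.join(ROOT, "results", "01_truth.tsv"), sep="\t")
    planted = set(truth.loc[truth["is_relocated"], "protein_id"].astype(str))
    precision, recall = precision_recall(result.final, planted)
    summary = {"final": sorted(result.final), "planted": sorted(planted),
               "precision": precision, "recall": recall,
               "q70": result.q70, "q90": result.q90}
    with open(os.path.join(ROOT, "results", "05_recovery.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
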