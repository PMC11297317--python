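"""End-to-end pipeline: simulate -> screen -> features -> ensembles ->
identify -> expression check.

Every stage logs its wall time; TSV/JSON outputs are stamped with the
config digest and master seed, and a rerun with the same config reproduces
them bitwise.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import pandas as pd

from locdiff import dataio, dlpid, exprclass, synthgen
from locdiff._rng import substream, substream_seed
from locdiff.config import STAGE_OF_DIM, RunConfig
from locdiff.featex import bag_feature_map, extract_features, save_feature_table
from locdiff.locmodel import ModelSpec, run_ensembles

log = logging.getLogger("locdiff")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    config: RunConfig
    truth: pd.DataFrame | None = None
    bags: list = field(default_factory=list)
    ensemble: object = None
    dlp: dlpid.DlpResult | None = None
    classifier: exprclass.ClassifierReport | None = None
    timings: dict = field(default_factory=dict)

    @property
    def final_dlps(self) -> set[str]:
        return set() if self.dlp is None else set(self.dlp.final)


def _timed(timings, name):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 3)
            log.info("stage %-10s %7.2fs", name, timings[name])
            return False
    return _Ctx()


def simulate_dataset(config: RunConfig) -> pd.DataFrame:
    """Generate the config's synthetic image dataset; returns the truth table."""
    sim = config.simulate
    return synthgen.generate_image_dataset(
        config.dataset_dir,
        n_proteins=sim.n_proteins,
        images_per_condition=sim.images_per_condition,
        tumor_images_per_condition=sim.tumor_images_per_condition,
        relocated_fraction=sim.relocated_fraction,
        image_size=sim.image_size,
        noise_sd=sim.noise_sd,
        multi_label_rate=sim.multi_label_rate,
        low_quality_fraction=sim.low_quality_fraction,
        intensity_choices=sim.intensity_choices,
        seed=substream_seed(config.seed, "simulate"),
    )


def run_pipeline(config: RunConfig, simulate: bool = True,
                 write_outputs: bool = True) -> PipelineResult:
    """Run the pipeline described by ``config`` and return all results."""
    result = PipelineResult(config=config)
    timings = result.timings
    out_dir = config.out_dir
    if write_outputs:
        os.makedirs(out_dir, exist_ok=True)

    if simulate:
        with _timed(timings, "simulate"):
            result.truth = simulate_dataset(config)
    if not os.path.exists(os.path.join(config.dataset_dir, "metadata.tsv")):
        raise StageError("screen", f"no dataset at {config.dataset_dir!r}")

    with _timed(timings, "screen"):
        records = dataio.load_image_records(config.dataset_dir)
        screened = dataio.screen_images(records)
        labels_tbl = dataio.load_label_table(
            os.path.join(config.dataset_dir, "labels.tsv"))
        bags = dataio.build_bags(screened, labels_tbl)
        result.bags = bags
        if not bags:
            raise StageError("screen", "no protein bags survive screening")
        if write_outputs:
            dataio.summarize(bags).to_csv(
                os.path.join(out_dir, "summary.tsv"), sep="\t", index=False)

    with _timed(timings, "features"):
        kept = [r for b in bags for r in b.normal_images + b.tumor_images]
        stage = STAGE_OF_DIM[config.model.feature_dim]
        features = extract_features(
            kept, stage=stage, seed=substream_seed(config.seed, "featex"),
            image_size=config.model.extract_image_size)
        bag_features = bag_feature_map(features)
        if write_outputs:
            save_feature_table(features, os.path.join(out_dir, "features.tsv"))

    with _timed(timings, "ensemble"):
        labels = {b.protein_id: b.known_labels for b in bags}
        spec = ModelSpec(feature_dim=config.model.feature_dim,
                         depth=config.model.depth, heads=config.model.heads,
                         threshold=config.model.threshold,
                         seed=substream_seed(config.seed, "locmodel"))
        ensemble = run_ensembles(bag_features, labels, spec,
                                 fractions=config.ensemble.fractions,
                                 repeats=config.ensemble.repeats,
                                 seed=substream_seed(config.seed, "ensemble"),
                                 max_epochs=config.ensemble.max_epochs,
                                 lr=config.ensemble.lr)
        result.ensemble = ensemble
        if write_outputs:
            ensemble.prob_table.to_csv(
                os.path.join(out_dir, "ensemble_probs.tsv"),
                sep="\t", index=False, float_format="%.6g")
            pd.DataFrame([{"model_id": m.model_id, "fraction": m.fraction,
                           "repeat": m.repeat, "heldout_f1": m.heldout_f1,
                           "heldout_auc": m.heldout_auc,
                           "n_train": len(m.train_ids)}
                          for m in ensemble.members]).to_csv(
                os.path.join(out_dir, "ensemble_metrics.tsv"),
                sep="\t", index=False, float_format="%.6g")

    with _timed(timings, "identify"):
        dlp = dlpid.identify_dlps(
            ensemble, bag_features, threshold=config.model.threshold,
            q=config.dlp.q, alpha=config.dlp.alpha,
            loo_min_effect=config.dlp.loo_min_effect,
            require_any_difference=config.dlp.require_any_difference,
            min_count_fraction=config.dlp.min_count_fraction)
        result.dlp = dlp
        if write_outputs:
            dlp.ledger.table.to_csv(os.path.join(out_dir, "dlp_ledger.tsv"),
                                    sep="\t", index=False, float_format="%.6g")
            with open(os.path.join(out_dir, "dlp_result.json"), "w") as fh:
                fh.write(dlp.to_json())

    if config.expression.enabled:
        with _timed(timings, "classify"):
            result.classifier = _expression_check(config, result, write_outputs)

    if write_outputs:
        stamp = {"config_digest": config.digest(), "seed": config.seed,
                 "timings": timings}
        with open(os.path.join(out_dir, "run_stamp.json"), "w") as fh:
            json.dump(stamp, fh, indent=2, sort_keys=True)
        with open(os.path.join(out_dir, "config.yaml"), "w") as fh:
            fh.write(config.to_yaml())
    return result


def _expression_check(config: RunConfig, result: PipelineResult,
                      write_outputs: bool):
    """Synthesize an expression cohort and compare DLP vs random classifiers."""
    ex = config.expression
    dlp_ids = sorted(result.final_dlps)
    if not dlp_ids:
        log.info("no DLPs identified; skipping expression check")
        return None
    # plant classification signal at the truly relocated proteins and an
    # independent DE subset elsewhere
    truth = result.truth
    relocated = set() if truth is None else \
        set(truth.loc[truth["is_relocated"], "protein_id"].astype(str))
    rng = substream(config.seed, "expression", "de_choice")
    candidates = [f"P{i:04d}" for i in range(ex.n_proteins)]
    non_reloc = [p for p in candidates if p not in relocated]
    de_ids = sorted(rng.choice(non_reloc, size=min(ex.n_de, len(non_reloc)),
                               replace=False))
    matrix, condition = synthgen.generate_expression(
        n_proteins=ex.n_proteins, n_tumor=ex.n_tumor, n_normal=ex.n_normal,
        dlp_ids=sorted(relocated), de_ids=de_ids, log2fc=ex.log2fc,
        missing_rate=ex.missing_rate,
        seed=substream_seed(config.seed, "expression"))
    clean = exprclass.preprocess(matrix, knn_k=ex.knn_k)
    de_found, de_table = exprclass.de_proteins(clean, condition)
    dlp_in_matrix = [p for p in dlp_ids if p in set(clean.index.astype(str))]
    if not dlp_in_matrix:
        log.info("no identified DLP has expression data; skipping comparison")
        return None
    report = exprclass.compare_sets(
        clean, condition, dlp_in_matrix, de_ids=de_found,
        n_random=ex.n_random, ntree=ex.ntree,
        seed=substream_seed(config.seed, "expression", "compare"))
    if write_outputs:
        de_table.to_csv(os.path.join(config.out_dir, "de_stats.tsv"),
                        sep="\t", index=False, float_format="%.6g")
        report.to_frame().to_csv(os.path.join(config.out_dir, "classifier_aucs.tsv"),
                                 sep="\t", index=False, float_format="%.6g")
        with open(os.path.join(config.out_dir, "classifier_report.json"), "w") as fh:
            json.dump({"dlp_aucs": report.dlp_aucs,
                       "random_aucs": report.random_aucs,
                       "p_values": report.p_values,
                       "n_random": report.n_random}, fh, indent=2)
    return report
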