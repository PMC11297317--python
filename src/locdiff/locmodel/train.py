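"""Training: single models, protein-level CV, the selection sweep, ensembles.

Bags are represented as ``bag_features[protein_id][condition] -> (T, D)``
token arrays plus ``labels[protein_id] -> frozenset`` of known
normal-condition categories.  Training always uses normal-condition images
and labels only; tumor-condition probabilities come from feeding tumor
image features through the same (normal-trained) model.

Splits are by protein, so all of a protein's images stay on one side of
every split.  All randomness flows from one master seed via named
substreams (test split, fold shuffling, ensemble membership, weight init).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from locdiff._rng import substream, substream_seed
from locdiff.categories import N_CATEGORIES
from locdiff.locmodel import nn
from locdiff.locmodel.metrics import EvalReport, evaluate
from locdiff.locmodel.model import (
    ModelSpec,
    ProbVector,
    TransformerAggregator,
    labels_to_matrix,
)


def _pad_bags(token_list: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    t_max = max(t.shape[0] for t in token_list)
    d = token_list[0].shape[1]
    x = np.zeros((len(token_list), t_max, d), dtype=np.float32)
    mask = np.zeros((len(token_list), t_max), dtype=np.float32)
    for i, t in enumerate(token_list):
        x[i, : t.shape[0]] = t
        mask[i, : t.shape[0]] = 1.0
    return x, mask


def train_model(bag_features: dict, labels: dict, train_ids: list[str],
                spec: ModelSpec, model_id: str = "model",
                max_epochs: int = 120, lr: float = 3e-3,
                patience: int = 12, min_delta: float = 5e-4,
                token_dropout: float = 0.3, feature_jitter: float = 0.15,
                val_ids: list[str] | None = None) -> TransformerAggregator:
    """Fit one aggregator on the normal-condition bags of ``train_ids``.

    Bag-level augmentation regularizes the small-sample fit: each epoch
    drops every token with probability ``token_dropout`` (always keeping at
    least one image per bag) and adds N(0, ``feature_jitter``) noise to the
    standardized features, so the model learns patterns that survive image
    deletion and render-to-render variation instead of memorizing training
    bags.  Early stopping: on validation micro-F1 when ``val_ids`` is given
    (best parameters restored), otherwise on a plateau of the clean
    (non-augmented) training loss.
    """
    if not train_ids:
        raise ValueError("empty training set")
    model = TransformerAggregator.initialize(spec, model_id=model_id)
    tokens = [np.asarray(bag_features[pid]["normal"], dtype=np.float32)
              for pid in train_ids]
    flat = np.concatenate(tokens, axis=0)
    model.set_standardization(flat.mean(0), flat.std(0))
    tokens = [model._standardize(t) for t in tokens]
    x, mask = _pad_bags(tokens)
    y = labels_to_matrix([labels[pid] for pid in train_ids])
    aug_rng = substream(spec.seed, "train", "augment", model_id)

    if val_ids:
        val_tokens = [model._standardize(
            np.asarray(bag_features[pid]["normal"], dtype=np.float32))
            for pid in val_ids]
        xv, mv = _pad_bags(val_tokens)
        yv = labels_to_matrix([labels[pid] for pid in val_ids])

    opt = nn.Adam(model.params, lr=lr)
    best_metric, best_params, since_best = -np.inf, None, 0
    best_loss = np.inf
    for _epoch in range(max_epochs):
        if token_dropout > 0 or feature_jitter > 0:
            keep = mask * (aug_rng.uniform(size=mask.shape) >= token_dropout)
            # never drop a whole bag: restore the first token where needed
            dead = keep.sum(-1) == 0
            keep[dead, 0] = mask[dead, 0]
            x_aug = x + aug_rng.normal(0.0, feature_jitter,
                                       x.shape).astype(np.float32)
            m_aug = keep.astype(np.float32)
        else:
            x_aug, m_aug = x, mask
        logits, cache = nn.forward(model.params, x_aug, m_aug,
                                   spec.depth, spec.heads)
        loss, dlogits = nn.bce_loss_and_grad(logits, y)
        grads = nn.backward(model.params, dlogits, cache)
        opt.step(model.params, grads)
        if token_dropout > 0 or feature_jitter > 0:
            clean_logits, _ = nn.forward(model.params, x, mask,
                                         spec.depth, spec.heads)
            loss, _ = nn.bce_loss_and_grad(clean_logits, y)

        if val_ids:
            pv = model.predict_batch(xv, mv)
            pred = pv > spec.threshold
            tp = np.sum(pred * yv)
            metric = 2 * tp / max(1e-9, 2 * tp + np.sum(pred * (1 - yv))
                                  + np.sum((1 - pred) * yv))
            if metric > best_metric + 1e-6:
                best_metric, since_best = metric, 0
                best_params = {k: v.copy() for k, v in model.params.items()}
            else:
                since_best += 1
        else:
            if loss < best_loss - min_delta:
                best_loss, since_best = loss, 0
            else:
                since_best += 1
        if since_best >= patience:
            break
    if val_ids and best_params is not None:
        model.params = best_params
    return model


def predict_table(model: TransformerAggregator, bag_features: dict,
                  protein_ids=None) -> pd.DataFrame:
    """Batched predictions for every (protein, condition) bag.

    Returns a tidy table: protein_id, condition, model_id, p1..p7.
    """
    ids = sorted(bag_features) if protein_ids is None else list(protein_ids)
    keys, tokens = [], []
    for pid in ids:
        for cond in sorted(bag_features[pid]):
            keys.append((pid, cond))
            tokens.append(model._standardize(
                np.asarray(bag_features[pid][cond], dtype=np.float32)))
    x, mask = _pad_bags(tokens)
    probs = model.predict_batch(x, mask)
    out = pd.DataFrame(keys, columns=["protein_id", "condition"])
    out["model_id"] = model.model_id
    for j in range(N_CATEGORIES):
        out[f"p{j + 1}"] = probs[:, j]
    return out


def _probvectors(table: pd.DataFrame, condition: str) -> list[ProbVector]:
    cols = [f"p{j + 1}" for j in range(N_CATEGORIES)]
    sub = table[table["condition"] == condition]
    return [ProbVector(str(r.protein_id), condition,
                       tuple(float(getattr(r, c)) for c in cols))
            for r in sub.itertuples(index=False)]


@dataclass
class CvResult:
    fold_models: list[TransformerAggregator]
    fold_assignments: dict[str, int]
    test_ids: list[str]
    fold_reports: list[EvalReport]
    test_report: EvalReport


def train_cv(bag_features: dict, labels: dict, spec: ModelSpec,
             folds: int = 10, test_fraction: float = 0.1,
             seed: int = 0, **fit_kw) -> CvResult:
    """Held-out test split, then protein-level k-fold CV on the remainder.

    The held-out report scores the fold-ensemble mean probability on the
    test proteins.
    """
    ids = sorted(set(bag_features) & set(labels))
    rng = substream(seed, "cv", "test_split")
    perm = list(np.array(ids)[rng.permutation(len(ids))])
    n_test = int(round(test_fraction * len(ids)))
    test_ids, pool = perm[:n_test], sorted(perm[n_test:])
    if len(pool) < folds:
        raise ValueError(f"{len(pool)} training proteins < {folds} folds")

    kf = KFold(n_splits=folds, shuffle=True,
               random_state=substream_seed(seed, "cv", "folds"))
    fold_models, fold_reports = [], []
    assignments: dict[str, int] = {}
    pool_arr = np.array(pool)
    for fold, (tr, va) in enumerate(kf.split(pool_arr)):
        tr_ids, va_ids = list(pool_arr[tr]), list(pool_arr[va])
        for pid in va_ids:
            assignments[pid] = fold
        fspec = ModelSpec(**{**spec.__dict__,
                             "seed": substream_seed(spec.seed, "cv", "fold", fold)})
        model = train_model(bag_features, labels, tr_ids, fspec,
                            model_id=f"cv_fold{fold}", val_ids=va_ids, **fit_kw)
        fold_models.append(model)
        table = predict_table(model, bag_features, va_ids)
        fold_reports.append(evaluate(_probvectors(table, "normal"), labels,
                                     threshold=spec.threshold))

    # fold-ensemble mean probabilities on the held-out test proteins
    if test_ids:
        stacks = []
        for model in fold_models:
            t = predict_table(model, bag_features, test_ids)
            t = t[t["condition"] == "normal"].sort_values("protein_id")
            stacks.append(t[[f"p{j + 1}" for j in range(N_CATEGORIES)]].to_numpy())
        mean_p = np.mean(stacks, axis=0)
        sorted_ids = sorted(test_ids)
        probs = [ProbVector(pid, "normal", tuple(map(float, mean_p[i])))
                 for i, pid in enumerate(sorted_ids)]
        test_report = evaluate(probs, labels, threshold=spec.threshold)
    else:
        test_report = EvalReport(auc=float("nan"), f1=float("nan"))
    test_report.provenance = {"folds": folds, "n_test": len(test_ids),
                              "n_pool": len(pool), "seed": seed}
    return CvResult(fold_models, assignments, sorted(test_ids),
                    fold_reports, test_report)


def sweep(features_by_dim: dict[int, dict], labels: dict,
          dims=(64, 128, 256, 512),
          thresholds=(0.3, 0.4, 0.5, 0.6, 0.7, 0.8),
          folds: int = 10, test_fraction: float = 0.1, seed: int = 0,
          **fit_kw) -> tuple[pd.DataFrame, dict]:
    """Grid over feature dimension and call threshold.

    AUC is threshold-free, so it is constant across the threshold rows of a
    dimension; F1 varies.  The selected cell maximizes F1 with AUC as the
    tie-break.
    """
    rows = []
    for dim in dims:
        spec = ModelSpec(feature_dim=dim, seed=substream_seed(seed, "sweep", dim))
        cv = train_cv(features_by_dim[dim], labels, spec, folds=folds,
                      test_fraction=test_fraction, seed=seed, **fit_kw)
        base = cv.test_report
        # recompute F1 at each threshold from the same test probabilities
        stacks = []
        for model in cv.fold_models:
            t = predict_table(model, bag_features=features_by_dim[dim],
                              protein_ids=cv.test_ids)
            t = t[t["condition"] == "normal"].sort_values("protein_id")
            stacks.append(t[[f"p{j + 1}" for j in range(N_CATEGORIES)]].to_numpy())
        mean_p = np.mean(stacks, axis=0)
        probs = [ProbVector(pid, "normal", tuple(map(float, mean_p[i])))
                 for i, pid in enumerate(sorted(cv.test_ids))]
        for thr in thresholds:
            rep = evaluate(probs, labels, threshold=thr)
            rows.append({"dim": dim, "threshold": thr,
                         "auc": base.auc, "f1": rep.f1})
    table = pd.DataFrame(rows)
    best = table.sort_values(["f1", "auc"], ascending=False).iloc[0]
    selected = {"dim": int(best["dim"]), "threshold": float(best["threshold"]),
                "auc": float(best["auc"]), "f1": float(best["f1"])}
    return table, selected


@dataclass
class EnsembleMember:
    model: TransformerAggregator
    fraction: float
    repeat: int
    train_ids: list[str]
    heldout_f1: float
    heldout_auc: float

    @property
    def model_id(self) -> str:
        return self.model.model_id


def save_ensemble(result: "EnsembleResult", out_dir: str) -> None:
    """Persist every member (weights + metadata) and the prediction table."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for m in result.members:
        m.model.save(os.path.join(out_dir, f"{m.model_id}.npz"))
        rows.append({"model_id": m.model_id, "fraction": m.fraction,
                     "repeat": m.repeat, "heldout_f1": m.heldout_f1,
                     "heldout_auc": m.heldout_auc,
                     "train_ids": ";".join(m.train_ids)})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "members.tsv"),
                              sep="\t", index=False)
    result.prob_table.to_csv(os.path.join(out_dir, "ensemble_probs.tsv"),
                             sep="\t", index=False, float_format="%.6g")


def load_ensemble(out_dir: str) -> "EnsembleResult":
    import os

    from locdiff.locmodel.model import TransformerAggregator

    meta = pd.read_csv(os.path.join(out_dir, "members.tsv"), sep="\t")
    members = []
    for row in meta.itertuples(index=False):
        model = TransformerAggregator.load(
            os.path.join(out_dir, f"{row.model_id}.npz"))
        members.append(EnsembleMember(
            model, float(row.fraction), int(row.repeat),
            str(row.train_ids).split(";"), float(row.heldout_f1),
            float(row.heldout_auc)))
    table = pd.read_csv(os.path.join(out_dir, "ensemble_probs.tsv"), sep="\t")
    return EnsembleResult(members, table)


@dataclass
class EnsembleResult:
    members: list[EnsembleMember]
    prob_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def reference_member(self) -> EnsembleMember:
        """Best held-out F1; ties broken by AUC, then model id."""
        def key(m: EnsembleMember):
            f1 = -np.inf if np.isnan(m.heldout_f1) else m.heldout_f1
            auc = -np.inf if np.isnan(m.heldout_auc) else m.heldout_auc
            return (-f1, -auc, m.model_id)
        return min(self.members, key=key)


def run_ensembles(bag_features: dict, labels: dict, spec: ModelSpec,
                  fractions=(0.9, 0.7), repeats: int = 10,
                  seed: int = 0, **fit_kw) -> EnsembleResult:
    """Train the two resampling ensembles and emit per-model predictions.

    For each fraction f and repeat, round(f*n) proteins are drawn (without
    replacement) as the training set; the rest evaluate the member.  Every
    member predicts both condition vectors for every protein.
    """
    ids = sorted(set(bag_features) & set(labels))
    n = len(ids)
    members: list[EnsembleMember] = []
    tables = []
    for frac in fractions:
        for rep in range(repeats):
            rng = substream(seed, "ensemble", frac, rep)
            k = int(round(frac * n))
            train_ids = sorted(np.array(ids)[rng.permutation(n)[:k]])
            heldout = sorted(set(ids) - set(train_ids))
            mspec = ModelSpec(**{**spec.__dict__,
                                 "seed": substream_seed(spec.seed, "ensemble",
                                                        frac, rep)})
            model_id = f"f{int(round(frac * 100))}_r{rep}"
            model = train_model(bag_features, labels, train_ids, mspec,
                                model_id=model_id, **fit_kw)
            table = predict_table(model, bag_features, ids)
            tables.append(table)
            if heldout:
                ht = table[table["protein_id"].isin(heldout)]
                rep_eval = evaluate(_probvectors(ht, "normal"), labels,
                                    threshold=spec.threshold)
                f1, auc = rep_eval.f1, rep_eval.auc
            else:
                f1, auc = float("nan"), float("nan")
            members.append(EnsembleMember(model, frac, rep, list(train_ids),
                                          f1, auc))
    return EnsembleResult(members, pd.concat(tables, ignore_index=True))
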