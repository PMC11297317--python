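"""Expression-based classification check for differentially localized proteins.

Pipeline: drop proteins with more than 30% missing values, impute the rest
from the k nearest protein rows (Euclidean distance over shared observed
samples, mean of the neighbours' values), flag differentially expressed
proteins (Welch t-test p < 0.05 and |log2 fold change| > 1), then compare a
random-forest tumor/normal classifier built on the DLP rows against
size-matched random protein sets under leave-one-out cross-validation.

Random-forest settings follow the reference configuration: 500 trees and
mtry = floor(log2 N) with N the number of samples (an unconventional mtry,
kept for fidelity; overridable).  Class imbalance is removed before LOOCV
by subsampling the majority class down to the minority class size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer
from sklearn.metrics import roc_auc_score

from locdiff._rng import substream, substream_seed


def preprocess(matrix: pd.DataFrame, max_missing: float = 0.30,
               knn_k: int = 10) -> pd.DataFrame:
    """Row filter on missingness, then row-neighbour KNN imputation.

    Rows (proteins) with a missing fraction strictly above ``max_missing``
    are dropped.  Imputation treats protein rows as the samples and the
    study samples as features, so a hole is filled with the mean of the k
    nearest protein rows that observe that sample.
    """
    if knn_k < 1:
        raise ValueError("knn_k must be >= 1")
    frac_missing = matrix.isna().mean(axis=1)
    kept = matrix.loc[frac_missing <= max_missing]
    if (kept.isna().all(axis=1)).any():
        raise ValueError("a retained protein row has no observed values")
    if not kept.isna().any().any():
        return kept.copy()
    if knn_k >= len(kept):
        raise ValueError(f"knn_k={knn_k} but only {len(kept)} protein rows")
    imputer = KNNImputer(n_neighbors=knn_k, weights="uniform")
    values = imputer.fit_transform(kept.to_numpy(dtype=float))
    return pd.DataFrame(values, index=kept.index, columns=kept.columns)


def de_proteins(matrix: pd.DataFrame, condition: pd.Series,
                p_cutoff: float = 0.05, fc_cutoff: float = 1.0,
                equal_var: bool = False) -> tuple[set[str], pd.DataFrame]:
    """Differentially expressed proteins: p < 0.05 and |log2FC| > 1.

    Fold change is the tumor-minus-normal difference of group means on the
    log2 scale.  Welch's t-test by default.  Zero-variance rows whose test
    is undefined are excluded and flagged in the stats table.
    """
    tumor_cols = condition.index[condition == "tumor"]
    normal_cols = condition.index[condition == "normal"]
    if len(tumor_cols) < 2 or len(normal_cols) < 2:
        raise ValueError("need >= 2 samples per condition")
    t_vals = matrix[tumor_cols].to_numpy(dtype=float)
    n_vals = matrix[normal_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(t_vals, n_vals, axis=1, equal_var=equal_var)
    log2fc = t_vals.mean(axis=1) - n_vals.mean(axis=1)
    table = pd.DataFrame({
        "protein_id": matrix.index,
        "log2fc": log2fc,
        "t": res.statistic,
        "p": res.pvalue,
    })
    table["undefined"] = ~np.isfinite(table["p"])
    ok = ~table["undefined"]
    table["is_de"] = ok & (table["p"] < p_cutoff) & (table["log2fc"].abs() > fc_cutoff)
    de = set(table.loc[table["is_de"], "protein_id"].astype(str))
    return de, table


def _balance(condition: pd.Series, rng: np.random.Generator) -> list[str]:
    """Subsample the majority class to the minority class size."""
    groups = {c: list(condition.index[condition == c]) for c in ("tumor", "normal")}
    n_min = min(len(v) for v in groups.values())
    if n_min < 2:
        raise ValueError("fewer than 2 samples in a class")
    chosen = []
    for c, cols in sorted(groups.items()):
        if len(cols) > n_min:
            cols = list(np.array(cols)[rng.permutation(len(cols))[:n_min]])
        chosen.extend(cols)
    return chosen


def rf_loocv_auc(matrix: pd.DataFrame, condition: pd.Series,
                 protein_set, ntree: int = 500, mtry: int | None = None,
                 seed: int = 0) -> float:
    """Leave-one-out AUC of a random forest on the given protein rows.

    Samples are balanced first (seeded); each held-out sample is scored by
    the forest's tumor-class probability and AUC is computed over all
    held-out scores.
    """
    protein_set = sorted(set(protein_set))
    missing = set(protein_set) - set(matrix.index.astype(str))
    if missing:
        raise ValueError(f"proteins not in matrix: {sorted(missing)[:5]}")
    rng = substream(seed, "rf", "balance")
    cols = _balance(condition, rng)
    x = matrix.loc[protein_set, cols].to_numpy(dtype=float).T  # samples x proteins
    y = (condition[cols] == "tumor").to_numpy(dtype=int)
    n = len(cols)
    if mtry is None:
        mtry = max(1, int(np.floor(np.log2(n))))
    mtry = min(mtry, x.shape[1])
    scores = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        clf = RandomForestClassifier(
            n_estimators=ntree, max_features=mtry,
            random_state=substream_seed(seed, "rf", "fit", i))
        clf.fit(x[keep], y[keep])
        tumor_col = list(clf.classes_).index(1)
        scores[i] = clf.predict_proba(x[i:i + 1])[0, tumor_col]
    return float(roc_auc_score(y, scores))


@dataclass
class ClassifierReport:
    dlp_aucs: list[float]
    random_aucs: dict[str, list[float]] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    strata: tuple[str, ...] = ("all",)
    n_random: int = 10

    def to_frame(self) -> pd.DataFrame:
        rows = [{"set": "DLP", "stratum": "dlp", "run": i, "auc": a}
                for i, a in enumerate(self.dlp_aucs)]
        for stratum, aucs in self.random_aucs.items():
            rows += [{"set": "random", "stratum": stratum, "run": i, "auc": a}
                     for i, a in enumerate(aucs)]
        return pd.DataFrame(rows)


def compare_sets(matrix: pd.DataFrame, condition: pd.Series, dlp_ids,
                 de_ids=frozenset(), n_random: int = 10,
                 strata=("all",), ntree: int = 500, mtry: int | None = None,
                 seed: int = 0) -> ClassifierReport:
    """DLP-set classification AUC versus size-matched random protein sets.

    For each stratum (all / DE / nonDE), ``n_random`` random sets of
    |dlp_ids| proteins are drawn excluding the DLPs, and their LOOCV AUCs
    are compared with the DLP AUC replicated over ``n_random`` balancing
    seeds via a two-sample t-test.
    """
    dlp_ids = sorted(set(dlp_ids))
    if not dlp_ids:
        raise ValueError("empty DLP set")
    de_ids = set(de_ids)
    all_ids = set(matrix.index.astype(str))
    pools = {}
    for stratum in strata:
        if stratum == "all":
            pool = all_ids - set(dlp_ids)
        elif stratum == "DE":
            pool = (de_ids & all_ids) - set(dlp_ids)
        elif stratum == "nonDE":
            pool = all_ids - de_ids - set(dlp_ids)
        else:
            raise ValueError(f"unknown stratum {stratum!r}")
        if len(pool) < len(dlp_ids):
            raise ValueError(f"stratum {stratum!r} smaller than the DLP set")
        pools[stratum] = sorted(pool)

    dlp_aucs = [rf_loocv_auc(matrix, condition, dlp_ids, ntree=ntree, mtry=mtry,
                             seed=substream_seed(seed, "compare", "dlp", r))
                for r in range(n_random)]
    report = ClassifierReport(dlp_aucs=dlp_aucs, strata=tuple(strata),
                              n_random=n_random)
    for stratum, pool in pools.items():
        aucs = []
        for r in range(n_random):
            rng = substream(seed, "compare", stratum, r)
            chosen = list(np.array(pool)[rng.permutation(len(pool))[:len(dlp_ids)]])
            aucs.append(rf_loocv_auc(
                matrix, condition, chosen, ntree=ntree, mtry=mtry,
                seed=substream_seed(seed, "compare", stratum, "fit", r)))
        report.random_aucs[stratum] = aucs
        res = stats.ttest_ind(dlp_aucs, aucs, equal_var=False)
        p = float(res.pvalue)
        report.p_values[stratum] = 1.0 if np.isnan(p) else p
    return report
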