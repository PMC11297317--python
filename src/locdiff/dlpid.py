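"""Identification of differentially localized proteins (DLPs).

Three filters over the resampling-ensemble predictions, intersected:

1. **Stability** - for each sampling scheme (90% and 70%), count per protein
   how many of the 10 models call different localization label sets in
   tumor vs normal; keep proteins whose count reaches the scheme's upper
   quartile value Q (the count at 1-based position floor(0.75*(n+1)) of the
   ascending counts) in *both* schemes.  A protein with no difference call
   in a scheme is never a candidate, so retention additionally requires a
   count of at least one; without this, an all-zero count distribution
   (Q = 0) would degenerate to retaining every protein.
2. **Distance** - with the single best ensemble member (highest held-out
   F1, ties by AUC then model id), keep the top 5% of proteins by Euclidean
   distance between the tumor and normal probability vectors
   (ceil(q*n) proteins; cutoff ties broken by lexicographic protein id).
3. **Robustness** - leave-one-image-out: re-predict each condition with one
   image removed and paired-t-test the 7 components of the reduced vector
   against the all-images vector; a protein is robust iff every such
   p-value is >= alpha in both conditions (identical vectors give p = 1 by
   convention).  "Insignificant change under deletion" is the retention
   rule: a protein whose call hinges on a single image is discarded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from locdiff.categories import CATEGORIES, N_CATEGORIES
from locdiff.locmodel.metrics import call_localizations
from locdiff.locmodel.model import ProbVector

_PCOLS = [f"p{j + 1}" for j in range(N_CATEGORIES)]


def diff_call(pn: ProbVector, pc: ProbVector, threshold: float) -> bool:
    """True iff the thresholded label sets differ (strict set inequality)."""
    ln = call_localizations(pn, threshold).labels
    lc = call_localizations(pc, threshold).labels
    return ln != lc


def upper_quartile_value(counts) -> int:
    """The count at 1-based position floor(0.75*(n+1)) of the sorted counts."""
    values = sorted(counts)
    n = len(values)
    if n == 0:
        raise ValueError("empty count distribution")
    pos = min(max(int(math.floor(0.75 * (n + 1))), 1), n)
    return values[pos - 1]


def stable_proteins(counts70: dict[str, int], counts90: dict[str, int],
                    require_any_difference: bool = True,
                    min_count_fraction: float | None = None,
                    n_models: int = 10) -> tuple[set[str], int, int]:
    """Proteins whose difference-call count reaches Q in both schemes.

    ``min_count_fraction`` optionally overrides the quartile rule with a
    fixed fraction of the per-scheme model count (e.g. 0.75 -> count > 7.5
    of 10 models).
    """
    if set(counts70) != set(counts90):
        raise ValueError("the two schemes cover different protein universes")
    if not counts70:
        raise ValueError("empty protein universe")
    if min_count_fraction is not None:
        q70 = q90 = int(math.floor(min_count_fraction * n_models)) + 1
    else:
        q70 = upper_quartile_value(counts70.values())
        q90 = upper_quartile_value(counts90.values())
    floor_count = 1 if require_any_difference else 0
    retained = {p for p in counts70
                if counts70[p] >= max(q70, floor_count)
                and counts90[p] >= max(q90, floor_count)}
    return retained, q70, q90


def euclidean_distance(pn, pc) -> float:
    return float(np.linalg.norm(np.asarray(pn, dtype=float)
                                - np.asarray(pc, dtype=float)))


def distance_top(probpairs: dict[str, tuple], q: float = 0.05
                 ) -> tuple[set[str], dict[str, float]]:
    """Top ceil(q*n) proteins by condition-pair Euclidean distance."""
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0,1)")
    if not probpairs:
        raise ValueError("empty protein universe")
    distances = {pid: euclidean_distance(pn, pc)
                 for pid, (pn, pc) in probpairs.items()}
    k = math.ceil(q * len(distances))
    ranked = sorted(distances, key=lambda p: (-distances[p], p))
    return set(ranked[:k]), distances


def _paired_t_pvalue(full: np.ndarray, loo: np.ndarray,
                     min_effect: float = 0.0) -> float:
    """Two-sided paired t-test over the 7 components.

    Identical vectors give p = 1 by convention.  ``min_effect`` is a
    practical-significance floor: when no component moves by more than it,
    the deletion did not change the prediction in any meaningful sense and
    p = 1 is returned — the paired test would otherwise flag arbitrarily
    tiny but consistently-signed shifts as significant.
    """
    diff = np.asarray(full, dtype=float) - np.asarray(loo, dtype=float)
    if np.max(np.abs(diff)) <= max(min_effect, 1e-12):
        return 1.0
    res = stats.ttest_rel(full, loo)
    p = float(res.pvalue)
    return 1.0 if np.isnan(p) else p


def loo_robust(model, bag_feats: dict[str, np.ndarray], alpha: float = 0.05,
               min_effect: float = 0.02,
               threshold: float | None = 0.5) -> tuple[bool, dict, list[str]]:
    """Leave-one-image-out robustness of one protein under one model.

    A protein is robust iff, in both conditions, every single-image
    deletion (a) leaves the paired t-test over the 7 components
    non-significant (p >= alpha) and (b) leaves the thresholded label set
    unchanged — the predicted *result* must not depend on any one image,
    so a deletion that flips a localization call breaks robustness even
    when the vector-level test is weak (a one-component change dilutes
    across the seven paired differences).  Pass ``threshold=None`` to skip
    the call-level check.

    ``bag_feats`` maps condition -> (T, D) token array.  Returns
    (robust, {(condition, removed_index): p}, skipped_conditions).
    """
    pvals: dict[tuple[str, int], float] = {}
    skipped: list[str] = []
    call_stable = True
    for cond in sorted(bag_feats):
        tokens = np.asarray(bag_feats[cond], dtype=np.float32)
        t = tokens.shape[0]
        if t < 2:
            skipped.append(cond)
            continue
        # one batched forward: the full bag plus every T-1 deletion bag
        if hasattr(model, "predict_batch"):
            std = model._standardize(tokens)
            x = np.zeros((t + 1, t, std.shape[1]), dtype=np.float32)
            mask = np.zeros((t + 1, t), dtype=np.float32)
            x[0], mask[0] = std, 1.0
            for i in range(t):
                x[i + 1, : t - 1] = np.delete(std, i, axis=0)
                mask[i + 1, : t - 1] = 1.0
            probs = model.predict_batch(x, mask)
            full, loos = probs[0], probs[1:]
        else:  # plain objects exposing predict_proba only
            full = model.predict_proba(tokens)
            loos = [model.predict_proba(np.delete(tokens, i, axis=0))
                    for i in range(t)]
        full_call = {i for i in range(len(full)) if full[i] > (threshold or 0)}
        for i in range(t):
            loo = loos[i]
            pvals[(cond, i)] = _paired_t_pvalue(full, loo, min_effect)
            if threshold is not None:
                loo_call = {j for j in range(len(loo)) if loo[j] > threshold}
                if loo_call != full_call:
                    call_stable = False
    robust = call_stable and all(p >= alpha for p in pvals.values())
    return robust, pvals, skipped


@dataclass
class DiffLedger:
    """Per-protein evidence for the three filters."""

    table: pd.DataFrame  # protein_id, diff_count_70, diff_count_90, distance
    loo_pvals: dict = field(default_factory=dict)
    skipped_conditions: dict = field(default_factory=dict)


@dataclass
class DlpResult:
    stable_set: set[str]
    distance_set: set[str]
    robust_set: set[str]
    final: set[str]
    q70: int = 0
    q90: int = 0
    params: dict = field(default_factory=dict)
    ledger: DiffLedger | None = None

    def to_json(self) -> str:
        payload = {
            "final": sorted(self.final),
            "stable_set": sorted(self.stable_set),
            "distance_set": sorted(self.distance_set),
            "robust_set": sorted(self.robust_set),
            "q70": self.q70, "q90": self.q90,
            "params": self.params,
        }
        return json.dumps(payload, indent=2)


def identify(stable: set[str], distance: set[str], robust: set[str],
             universe: set[str]) -> set[str]:
    """Intersect the three filter sets (each must live in the universe)."""
    for name, s in (("stable", stable), ("distance", distance), ("robust", robust)):
        extra = s - universe
        if extra:
            raise ValueError(f"{name} set contains proteins outside the "
                             f"universe: {sorted(extra)[:5]}")
    return stable & distance & robust


def identify_dlps(ensemble, bag_features: dict, threshold: float = 0.5,
                  q: float = 0.05, alpha: float = 0.05,
                  loo_min_effect: float = 0.02,
                  require_any_difference: bool = True,
                  min_count_fraction: float | None = None) -> DlpResult:
    """Run all three filters on an ensemble's predictions and intersect.

    ``ensemble`` is a ``locmodel.train.EnsembleResult``; ``bag_features``
    supplies per-image tokens for the leave-one-image-out step.
    """
    table = ensemble.prob_table
    universe = sorted(set(table["protein_id"].astype(str)))
    frac_of_model = {m.model_id: m.fraction for m in ensemble.members}

    counts: dict[float, dict[str, int]] = {0.7: {}, 0.9: {}}
    for frac in counts:
        for pid in universe:
            counts[frac][pid] = 0
    for model_id, sub in table.groupby("model_id"):
        frac = round(frac_of_model[str(model_id)], 2)
        piv = sub.pivot(index="protein_id", columns="condition", values=_PCOLS)
        for pid in universe:
            pn = ProbVector(pid, "normal",
                            tuple(float(piv.loc[pid, (c, "normal")]) for c in _PCOLS))
            pc = ProbVector(pid, "tumor",
                            tuple(float(piv.loc[pid, (c, "tumor")]) for c in _PCOLS))
            if diff_call(pn, pc, threshold):
                counts[frac][pid] += 1

    n_models = sum(1 for m in ensemble.members if round(m.fraction, 2) == 0.7)
    stable, q70, q90 = stable_proteins(
        counts[0.7], counts[0.9], require_any_difference=require_any_difference,
        min_count_fraction=min_count_fraction, n_models=n_models)

    reference = ensemble.reference_member()
    ref_table = table[table["model_id"] == reference.model_id]
    piv = ref_table.pivot(index="protein_id", columns="condition", values=_PCOLS)
    probpairs = {
        pid: (np.array([piv.loc[pid, (c, "normal")] for c in _PCOLS]),
              np.array([piv.loc[pid, (c, "tumor")] for c in _PCOLS]))
        for pid in universe
    }
    distance_set, distances = distance_top(probpairs, q=q)

    robust_set = set()
    loo_pvals, skipped = {}, {}
    for pid in universe:
        ok, pvals, skip = loo_robust(reference.model, bag_features[pid],
                                     alpha=alpha, min_effect=loo_min_effect,
                                     threshold=threshold)
        loo_pvals[pid] = pvals
        if skip:
            skipped[pid] = skip
        if ok:
            robust_set.add(pid)

    final = identify(stable, distance_set, robust_set, set(universe))
    ledger = DiffLedger(
        table=pd.DataFrame({
            "protein_id": universe,
            "diff_count_70": [counts[0.7][p] for p in universe],
            "diff_count_90": [counts[0.9][p] for p in universe],
            "distance": [distances[p] for p in universe],
            "min_loo_p": [min(loo_pvals[p].values()) if loo_pvals[p] else np.nan
                          for p in universe],
        }),
        loo_pvals=loo_pvals,
        skipped_conditions=skipped,
    )
    return DlpResult(stable, distance_set, robust_set, final, q70, q90,
                     params={"threshold": threshold, "q": q, "alpha": alpha,
                             "reference_model": reference.model_id,
                             "categories": list(CATEGORIES)},
                     ledger=ledger)
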