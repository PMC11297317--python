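"""Calls, metrics, CV and ensemble machinery of the localization model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locdiff.categories import CATEGORIES
from locdiff.locmodel import (
    ModelSpec,
    ProbVector,
    call_localizations,
    evaluate,
    f1_score,
    run_ensembles,
    train_cv,
)
from locdiff.locmodel.train import sweep

FAST_FIT = dict(max_epochs=4, patience=2)


def _pv(p, pid="P1", cond="normal"):
    return ProbVector(pid, cond, tuple(p))


class TestCalls:
    def test_threshold_call_example(self):
        pv = _pv((0.9, 0.1, 0.1, 0.1, 0.1, 0.6, 0.1))
        call = call_localizations(pv, 0.5)
        assert call.labels == frozenset({"Cytoplasm", "Nuclear"})

    def test_boundary_is_strict(self):
        call = call_localizations(_pv((0.5,) * 7), 0.5)
        assert call.labels == frozenset()

    probs = st.tuples(*[st.floats(0, 1) for _ in range(7)])

    @settings(max_examples=50, derandomize=True)
    @given(p=probs, t1=st.floats(0.05, 0.95), t2=st.floats(0.05, 0.95))
    def test_calls_monotone_in_threshold(self, p, t1, t2):
        lo, hi = min(t1, t2), max(t1, t2)
        assert call_localizations(_pv(p), hi).labels <= \
            call_localizations(_pv(p), lo).labels


class TestF1:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (5, 0, 0, 1.0),            # precision = recall = 1
        (1, 1, 0, 2.0 / 3.0),      # precision 0.5, recall 1
        (0, 3, 2, 0.0),            # degenerate: no true positives
        (0, 0, 0, 0.0),
    ])
    def test_formula(self, tp, fp, fn, expected):
        assert f1_score(tp, fp, fn) == pytest.approx(expected)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            f1_score(-1, 0, 0)

    @settings(max_examples=50, derandomize=True)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    def test_bounded_and_matches_direct_formula(self, tp, fp, fn):
        f1 = f1_score(tp, fp, fn)
        assert 0.0 <= f1 <= 1.0
        if tp:
            prec, rec = tp / (tp + fp), tp / (tp + fn)
            assert f1 == pytest.approx(2 * prec * rec / (prec + rec))


class TestEvaluate:
    def _truth(self, assignments):
        return {pid: frozenset(labs) for pid, labs in assignments.items()}

    def test_perfect_predictions(self):
        truth = self._truth({"A": {"Nuclear"}, "B": {"Cytoplasm"}})
        probs = [
            _pv(tuple(1.0 if c in truth[pid] else 0.0 for c in CATEGORIES), pid)
            for pid in truth
        ]
        rep = evaluate(probs, truth)
        assert rep.auc == 1.0 and rep.f1 == 1.0

    def test_random_probabilities_auc_near_half(self, rng):
        truth = {f"P{i}": frozenset({"Nuclear"} if rng.uniform() < 0.5
                                    else {"Cytoplasm"}) for i in range(200)}
        probs = [_pv(tuple(rng.uniform(size=7)), pid) for pid in truth]
        rep = evaluate(probs, truth)
        assert abs(rep.auc - 0.5) < 0.12

    def test_matches_bruteforce_oracle_on_toy_table(self):
        # 4 proteins, one informative label; oracle computed by counting
        # concordant/discordant pairs by hand
        truth = self._truth({"A": {"Nuclear"}, "B": {"Nuclear"},
                             "C": {"Cytoplasm"}, "D": {"Cytoplasm"}})
        nuc = {"A": 0.9, "B": 0.6, "C": 0.7, "D": 0.1}
        cyt = {"A": 0.2, "B": 0.3, "C": 0.8, "D": 0.9}
        probs = [
            _pv(tuple(nuc[p] if c == "Nuclear" else cyt[p] if c == "Cytoplasm"
                      else 0.0 for c in CATEGORIES), p)
            for p in "ABCD"
        ]
        # Nuclear AUC: pairs (A,C)=1,(A,D)=1,(B,C)=0,(B,D)=1 -> 3/4
        # Cytoplasm AUC: positives C,D vs negatives A,B: all 4 pairs win -> 1
        rep = evaluate(probs, truth)
        assert rep.auc == pytest.approx((0.75 + 1.0) / 2)
        # micro-F1 at 0.5: tp=4 (A,B nuclear? B=0.6>0.5 yes; C,D cyt yes)
        # fp=2 (C nuclear 0.7, D cyt? D nuclear 0.1 no; A cyt 0.2 no ->
        #       fp = C-nuclear only... plus none) fn=0
        tp, fp, fn = 4, 1, 0
        assert rep.f1 == pytest.approx(f1_score(tp, fp, fn))

    def test_degenerate_labels_are_skipped_and_listed(self):
        truth = self._truth({"A": {"Nuclear"}, "B": {"Nuclear"}})
        probs = [_pv((0.1,) * 7, p) for p in "AB"]
        rep = evaluate(probs, truth)
        assert "Nuclear" in rep.skipped_labels  # no negatives for Nuclear
        assert np.isnan(rep.auc)

    def test_missing_truth_is_error(self):
        with pytest.raises(ValueError, match="truth"):
            evaluate([_pv((0.5,) * 7, "X")], {})


class TestTrainCv:
    def test_folds_partition_pool_and_are_seed_stable(self, tiny_bag_features,
                                                      tiny_labels):
        spec = ModelSpec(feature_dim=128, seed=1)
        cv1 = train_cv(tiny_bag_features, tiny_labels, spec, folds=3,
                       test_fraction=0.2, seed=5, **FAST_FIT)
        cv2 = train_cv(tiny_bag_features, tiny_labels, spec, folds=3,
                       test_fraction=0.2, seed=5, **FAST_FIT)
        assert cv1.fold_assignments == cv2.fold_assignments
        assert cv1.test_ids == cv2.test_ids
        pool = set(tiny_labels) - set(cv1.test_ids)
        assert set(cv1.fold_assignments) == pool
        folds = [set(p for p, f in cv1.fold_assignments.items() if f == k)
                 for k in range(3)]
        assert all(a.isdisjoint(b) for i, a in enumerate(folds)
                   for b in folds[i + 1:])

    def test_too_few_proteins_rejected(self, tiny_bag_features, tiny_labels):
        with pytest.raises(ValueError, match="folds"):
            train_cv(tiny_bag_features, tiny_labels,
                     ModelSpec(feature_dim=128), folds=50, seed=0, **FAST_FIT)


class TestEnsembles:
    def test_member_bookkeeping_and_determinism(self, tiny_bag_features,
                                                tiny_labels):
        spec = ModelSpec(feature_dim=128, seed=2)
        ens1 = run_ensembles(tiny_bag_features, tiny_labels, spec,
                             repeats=2, seed=9, **FAST_FIT)
        ens2 = run_ensembles(tiny_bag_features, tiny_labels, spec,
                             repeats=2, seed=9, **FAST_FIT)
        assert len(ens1.members) == 4  # 2 fractions x 2 repeats
        n = len(tiny_labels)
        for m in ens1.members:
            assert len(m.train_ids) == round(m.fraction * n)
        assert [m.train_ids for m in ens1.members] == \
            [m.train_ids for m in ens2.members]
        # every protein gets both condition vectors from every member
        tab = ens1.prob_table
        assert len(tab) == 4 * n * 2
        assert set(tab["condition"]) == {"normal", "tumor"}

    def test_reference_member_prefers_best_f1(self, tiny_bag_features,
                                              tiny_labels):
        ens = run_ensembles(tiny_bag_features, tiny_labels,
                            ModelSpec(feature_dim=128, seed=2),
                            repeats=2, seed=9, **FAST_FIT)
        ref = ens.reference_member()
        best = max((m.heldout_f1, m.heldout_auc) for m in ens.members
                   if not np.isnan(m.heldout_f1))
        assert (ref.heldout_f1, ref.heldout_auc) == best


def test_sweep_grid_shape_and_auc_constant_per_dim(tiny_bags, tiny_labels):
    from locdiff.featex import bag_feature_map, extract_features
    records = [r for b in tiny_bags for r in b.normal_images + b.tumor_images]
    features_by_dim = {
        dim: bag_feature_map(extract_features(records, stage=s, seed=1,
                                              image_size=48))
        for dim, s in ((64, 1), (128, 2))
    }
    table, selected = sweep(features_by_dim, tiny_labels, dims=(64, 128),
                            thresholds=(0.3, 0.5, 0.8), folds=2,
                            test_fraction=0.2, seed=3, **FAST_FIT)
    assert len(table) == 2 * 3
    for dim, grp in table.groupby("dim"):
        assert grp["auc"].nunique() == 1  # AUC is threshold-free
    assert selected["dim"] in (64, 128)
    best = table.sort_values(["f1", "auc"], ascending=False).iloc[0]
    assert selected["f1"] == pytest.approx(best["f1"])
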