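"""The three DLP filters against brute-force oracles and edge cases."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from locdiff.dlpid import (
    diff_call,
    distance_top,
    identify,
    loo_robust,
    stable_proteins,
    upper_quartile_value,
)
from locdiff.locmodel import ProbVector


def _pv(p, pid="P1", cond="normal"):
    return ProbVector(pid, cond, tuple(p))


class TestDiffCall:
    def test_identical_vectors_not_different(self):
        p = _pv((0.9, 0.1, 0.1, 0.1, 0.1, 0.6, 0.1))
        assert diff_call(p, p, 0.5) is False

    def test_relocation_is_different(self):
        pn = _pv((0.1, 0.1, 0.1, 0.1, 0.1, 0.9, 0.1))          # Nuclear
        pc = _pv((0.9, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1), cond="tumor")  # Cytoplasm
        assert diff_call(pn, pc, 0.5) is True

    def test_strict_set_inequality_counts_additions(self):
        pn = _pv((0.1, 0.1, 0.1, 0.1, 0.1, 0.9, 0.1))
        pc = _pv((0.9, 0.1, 0.1, 0.1, 0.1, 0.9, 0.1), cond="tumor")
        assert diff_call(pn, pc, 0.5) is True

    def test_probability_shift_without_label_change_is_not_different(self):
        pn = _pv((0.1, 0.1, 0.1, 0.1, 0.1, 0.95, 0.1))
        pc = _pv((0.45, 0.1, 0.1, 0.1, 0.1, 0.55, 0.1), cond="tumor")
        assert diff_call(pn, pc, 0.5) is False


class TestStableProteins:
    def test_hand_worked_quartile_example(self):
        # n=7 counts 0..6: 1-based position floor(0.75*8)=6 -> Q=5
        counts = {f"P{i}": i for i in range(7)}
        retained, q70, q90 = stable_proteins(counts, counts)
        assert q70 == q90 == 5
        assert retained == {"P5", "P6"}

    def test_identical_nonzero_counts_retain_all(self):
        counts = {f"P{i}": 3 for i in range(10)}
        retained, q70, q90 = stable_proteins(counts, counts)
        assert retained == set(counts)

    def test_zero_count_proteins_are_never_candidates(self):
        counts = {f"P{i}": 0 for i in range(10)}
        retained, q70, _ = stable_proteins(counts, counts)
        assert q70 == 0 and retained == set()

    def test_requires_both_schemes(self):
        c70 = {"A": 9, "B": 0, "C": 1}
        c90 = {"A": 9, "B": 9, "C": 1}
        retained, _, _ = stable_proteins(c70, c90)
        assert retained == {"A"}

    def test_oracle_equivalence_on_random_counts(self, rng):
        ids = [f"P{i:03d}" for i in range(200)]
        c70 = {p: int(rng.integers(0, 11)) for p in ids}
        c90 = {p: int(rng.integers(0, 11)) for p in ids}
        retained, q70, q90 = stable_proteins(c70, c90)
        # independent brute force, straight from the retention definition
        def quartile(cs):
            v = sorted(cs)
            return v[math.floor(0.75 * (len(v) + 1)) - 1]
        oq70, oq90 = quartile(c70.values()), quartile(c90.values())
        oracle = {p for p in ids
                  if c70[p] >= max(oq70, 1) and c90[p] >= max(oq90, 1)}
        assert (q70, q90) == (oq70, oq90)
        assert retained == oracle

    @settings(max_examples=30, derandomize=True)
    @given(st.dictionaries(st.sampled_from([f"P{i}" for i in range(12)]),
                           st.integers(0, 10), min_size=3),
           st.sampled_from([f"P{i}" for i in range(12)]))
    def test_retention_monotone_in_counts(self, counts, pid):
        if pid not in counts:
            counts[pid] = 0
        retained, _, _ = stable_proteins(counts, counts)
        bumped = dict(counts)
        bumped[pid] = min(10, bumped[pid] + 1)
        retained2, _, _ = stable_proteins(bumped, bumped)
        # raising one protein's count never removes IT from the stable set
        if pid in retained:
            assert pid in retained2

    def test_mismatched_universes_rejected(self):
        with pytest.raises(ValueError):
            stable_proteins({"A": 1}, {"B": 1})
        with pytest.raises(ValueError):
            stable_proteins({}, {})


class TestDistanceTop:
    def test_unit_shift_ranks_first(self):
        pairs = {f"P{i}": (np.full(7, 0.3), np.full(7, 0.3)) for i in range(20)}
        shifted = np.full(7, 0.3)
        shifted[5] = 1.3
        pairs["P7"] = (np.full(7, 0.3), shifted)
        top, dist = distance_top(pairs, q=0.05)
        assert top == {"P7"} and dist["P7"] == pytest.approx(1.0)

    def test_all_ties_broken_lexicographically(self):
        pairs = {f"P{i}": (np.zeros(7), np.zeros(7)) for i in range(10)}
        top, _ = distance_top(pairs, q=0.25)
        assert top == {"P0", "P1", "P2"}  # ceil(0.25*10)=3 smallest ids

    def test_oracle_equivalence_on_random_pairs(self, rng):
        pairs = {f"P{i:03d}": (rng.uniform(size=7), rng.uniform(size=7))
                 for i in range(100)}
        top, _ = distance_top(pairs, q=0.05)
        oracle = sorted(pairs, key=lambda p: (-float(np.sqrt(np.sum(
            (pairs[p][0] - pairs[p][1]) ** 2))), p))[:math.ceil(0.05 * 100)]
        assert top == set(oracle)

    def test_returns_exactly_ceil_qn(self, rng):
        for n, q in ((10, 0.05), (50, 0.1), (7, 0.5)):
            pairs = {f"P{i}": (rng.uniform(size=7), rng.uniform(size=7))
                     for i in range(n)}
            top, _ = distance_top(pairs, q=q)
            assert len(top) == math.ceil(q * n)


class _StubModel:
    """Deterministic aggregator stand-in: probability = mean token, clipped."""

    def predict_proba(self, tokens):
        return np.clip(np.asarray(tokens, dtype=float).mean(axis=0)[:7], 0, 1)


class TestLooRobust:
    def test_identical_images_are_robust_with_p_one(self):
        tokens = np.tile(np.linspace(0.1, 0.7, 7), (4, 1))
        ok, pvals, skipped = loo_robust(_StubModel(),
                                        {"normal": tokens, "tumor": tokens})
        assert ok and not skipped
        assert all(p == 1.0 for p in pvals.values())

    def test_adversarial_image_breaks_robustness(self):
        base = np.tile(np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.9, 0.1]), (3, 1))
        adversarial = np.vstack([base, 5.0 * np.arange(7)[None, :]])
        ok, pvals, _ = loo_robust(_StubModel(), {"normal": adversarial,
                                                 "tumor": base})
        assert not ok
        assert min(pvals.values()) < 0.05

    def test_single_image_condition_skipped_and_flagged(self):
        one = np.array([[0.2] * 7])
        many = np.tile(np.array([0.3] * 7), (3, 1))
        ok, pvals, skipped = loo_robust(_StubModel(), {"normal": many,
                                                       "tumor": one})
        assert skipped == ["tumor"]
        assert all(cond == "normal" for cond, _ in pvals)

    def test_pvalues_match_manual_paired_t(self, rng):
        tokens = rng.uniform(size=(3, 7))
        model = _StubModel()
        _, pvals, _ = loo_robust(model, {"normal": tokens}, min_effect=0.0)
        full = model.predict_proba(tokens)
        from scipy import stats as ss
        for (cond, i), p in pvals.items():
            loo = model.predict_proba(np.delete(tokens, i, axis=0))
            d = full - loo
            t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
            manual = 2 * ss.t.sf(abs(t), df=len(d) - 1)
            assert p == pytest.approx(manual, rel=1e-6, abs=1e-8)


class TestIdentify:
    def test_disjoint_sets_give_empty_final(self):
        universe = {"A", "B", "C"}
        assert identify({"A"}, {"B"}, {"C"}, universe) == set()

    def test_final_subset_of_each_input(self, rng):
        universe = {f"P{i}" for i in range(30)}
        sets = [set(rng.choice(sorted(universe), size=10, replace=False))
                for _ in range(3)]
        final = identify(*sets, universe)
        assert all(final <= s for s in sets)

    def test_universe_mismatch_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            identify({"X"}, set(), set(), {"A"})


def test_quartile_value_small_universes():
    assert upper_quartile_value([4]) == 4
    assert upper_quartile_value([1, 9]) == 9
    with pytest.raises(ValueError):
        upper_quartile_value([])
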