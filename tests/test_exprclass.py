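"""Expression preprocessing, the DE filter, and the RF classification check."""

import numpy as np
import pandas as pd
import pytest

from locdiff.exprclass import compare_sets, de_proteins, preprocess, rf_loocv_auc
from locdiff.synthgen import generate_expression


def _matrix(values, ids=None, samples=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"P{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=ids, columns=samples)


class TestPreprocess:
    def test_missing_fraction_boundary_is_strict(self):
        # 10 samples: 3 missing = 30% kept, 4 missing = 40% dropped
        m = _matrix(np.ones((3, 10)))
        m.iloc[0, :3] = np.nan
        m.iloc[1, :4] = np.nan
        out = preprocess(m, knn_k=1)
        assert list(out.index) == ["P0", "P2"]
        assert not out.isna().any().any()

    def test_complete_matrix_unchanged(self, rng):
        m = _matrix(rng.normal(size=(20, 8)))
        pd.testing.assert_frame_equal(preprocess(m, knn_k=3), m)

    def test_imputation_beats_column_mean(self, rng):
        # two protein clusters with distinct profiles; mask random cells
        profiles = np.vstack([np.tile([5.0, 1.0], (25, 1)).repeat(5, axis=1),
                              np.tile([1.0, 5.0], (25, 1)).repeat(5, axis=1)])
        full = profiles + rng.normal(0, 0.2, profiles.shape)
        m = _matrix(full.copy())
        holes = rng.uniform(size=m.shape) < 0.1
        masked = m.mask(holes)
        imputed = preprocess(masked, knn_k=5)
        col_mean = masked.fillna(masked.mean(axis=0), axis=0)
        rmse_knn = np.sqrt(((imputed.to_numpy() - full)[holes] ** 2).mean())
        rmse_col = np.sqrt(((col_mean.to_numpy() - full)[holes] ** 2).mean())
        assert rmse_knn < rmse_col

    def test_k_larger_than_rows_rejected(self):
        m = _matrix(np.ones((3, 4)))
        m.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="knn_k"):
            preprocess(m, knn_k=10)


class TestDeProteins:
    def _cond(self, n_t=20, n_n=20):
        idx = [f"T{i}" for i in range(n_t)] + [f"N{i}" for i in range(n_n)]
        return pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=idx)

    def test_planted_strong_effects_all_recovered(self):
        de_ids = [f"P{i:04d}" for i in range(10)]
        m, cond = generate_expression(n_proteins=300, de_ids=de_ids,
                                      log2fc=4.0, noise_sd=0.5,
                                      missing_rate=0.0,
                                      high_missing_fraction=0.0, seed=3)
        found, table = de_proteins(m, cond)
        assert set(de_ids) <= found

    def test_null_rows_rarely_pass_both_gates(self):
        m, cond = generate_expression(n_proteins=1000, missing_rate=0.0,
                                      high_missing_fraction=0.0, seed=4)
        found, _ = de_proteins(m, cond)
        # the |log2FC|>1 gate at sd=0.5 makes null passes very rare
        assert len(found) / 1000 < 0.01

    def test_zero_variance_rows_flagged_not_crashing(self):
        cond = self._cond(3, 3)
        values = np.vstack([np.ones(6) * 5.0,
                            np.r_[np.ones(3) * 9.0, np.ones(3) * 1.0],
                            np.random.default_rng(0).normal(5, 1, 6)])
        found, table = de_proteins(_matrix(values, samples=list(cond.index)),
                                   cond)
        assert bool(table.loc[table.protein_id == "P0", "undefined"].iloc[0])
        assert "P0" not in found
        assert "P1" in found  # clean separation, |fc| = 8

    def test_requires_two_samples_per_group(self):
        cond = self._cond(1, 3)
        with pytest.raises(ValueError):
            de_proteins(_matrix(np.ones((2, 4)), samples=list(cond.index)), cond)


class TestRfLoocv:
    def _data(self, rng, n_per=10, signal=True):
        samples = [f"T{i}" for i in range(n_per)] + [f"N{i}" for i in range(n_per)]
        cond = pd.Series(["tumor"] * n_per + ["normal"] * n_per, index=samples)
        values = rng.normal(5, 1, size=(30, 2 * n_per))
        if signal:  # one perfectly separating protein
            values[0] = np.r_[np.full(n_per, 9.0), np.full(n_per, 1.0)]
        return _matrix(values, samples=samples), cond

    def test_separating_protein_gives_auc_one(self, rng):
        m, cond = self._data(rng)
        auc = rf_loocv_auc(m, cond, ["P0"], ntree=100, seed=1)
        assert auc == 1.0

    def test_deterministic_under_seed(self, rng):
        m, cond = self._data(rng)
        a = rf_loocv_auc(m, cond, ["P0", "P1", "P2"], ntree=50, seed=7)
        b = rf_loocv_auc(m, cond, ["P0", "P1", "P2"], ntree=50, seed=7)
        assert a == b

    def test_unknown_protein_rejected(self, rng):
        m, cond = self._data(rng)
        with pytest.raises(ValueError, match="not in matrix"):
            rf_loocv_auc(m, cond, ["nope"], seed=0)

    def test_imbalanced_design_is_subsampled(self, rng):
        samples = [f"T{i}" for i in range(20)] + [f"N{i}" for i in range(6)]
        cond = pd.Series(["tumor"] * 20 + ["normal"] * 6, index=samples)
        m = _matrix(rng.normal(size=(10, 26)), samples=samples)
        # runs and yields a valid AUC despite 20 vs 6 samples
        auc = rf_loocv_auc(m, cond, ["P0", "P1"], ntree=50, seed=2)
        assert 0.0 <= auc <= 1.0


class TestCompareSets:
    def test_report_bookkeeping(self, rng):
        m, cond = TestRfLoocv()._data(rng, n_per=8)
        report = compare_sets(m, cond, ["P0", "P1"], n_random=3,
                              strata=("all",), ntree=50, seed=5)
        assert len(report.dlp_aucs) == 3
        assert len(report.random_aucs["all"]) == 3
        assert "all" in report.p_values
        frame = report.to_frame()
        assert set(frame["set"]) == {"DLP", "random"}

    def test_stratum_too_small_rejected(self, rng):
        m, cond = TestRfLoocv()._data(rng, n_per=5)
        with pytest.raises(ValueError, match="smaller"):
            compare_sets(m, cond, list(m.index[:20]), strata=("DE",),
                         de_ids=["P0"], n_random=2, ntree=20, seed=0)
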