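"""Splitting, the statistics battery vs a hand-computed oracle, gating on the
published model statistics, bootstrap, and the applicability domain."""

import copy

import numpy as np
import pandas as pd
import pytest

import qsarfep as q
from qsarfep.errors import ParameterError
from qsarfep.validation import (
    ValidationReport,
    bootstrap_r2,
    external_metrics,
    stratified_split,
    threshold_gate,
    williams_ad,
)


def _acts(values):
    return pd.DataFrame({"id": [f"C{i}" for i in range(len(values))],
                         "pIC50": values})


class TestStratifiedSplit:
    def test_twelve_compounds_three_test(self):
        acts = _acts([4, 4.1, 4.2, 4.3, 6, 6.1, 6.2, 6.3, 8, 8.1, 8.2, 8.3])
        split = stratified_split(acts, seed=0, boundaries=(5.0, 7.0))
        assert len(split.test_ids) == 3
        test_classes = {split.class_label[c] for c in split.test_ids}
        assert test_classes == {"low", "medium", "high"}

    def test_124_compounds_three_to_one(self, rng):
        acts = _acts(rng.uniform(4, 10, 124))
        split = stratified_split(acts, seed=1)
        assert len(split.train_ids) == 93
        assert len(split.test_ids) == 31

    def test_same_seed_identical(self, rng):
        acts = _acts(rng.uniform(4, 10, 40))
        a = stratified_split(acts, seed=7)
        b = stratified_split(acts, seed=7)
        assert a.role == b.role and a.class_label == b.class_label

    def test_small_class_rejected(self):
        acts = _acts([4, 6, 6.1, 6.2, 6.3, 8, 8.1, 8.2, 8.3, 8.4])
        with pytest.raises(ParameterError, match="low"):
            stratified_split(acts, boundaries=(5.0, 7.0))

    def test_classes_partition_the_set(self, rng):
        acts = _acts(rng.uniform(4, 10, 40))
        split = stratified_split(acts, seed=3)
        assert sorted(split.train_ids + split.test_ids) == sorted(acts["id"])


class TestExternalMetrics:
    def test_perfect_prediction(self):
        y = np.array([5.0, 6.0, 7.0, 8.0])
        out = external_metrics(y, y.copy(), y_train_mean=6.0, y_train_ss=10.0, n_train=10)
        for key in ("r_pred_2", "qf1_2", "qf2_2", "qf3_2", "q_ccc_2", "r2",
                    "k", "k_prime", "rm_2", "rm_2_prime"):
            assert out[key] == pytest.approx(1.0, abs=1e-12), key

    def test_train_mean_prediction_gives_zero_r_pred(self):
        y = np.array([5.0, 6.0, 7.0, 8.0])
        yhat = np.full(4, 6.5)
        out = external_metrics(y, yhat, y_train_mean=6.5, y_train_ss=10.0, n_train=10)
        assert out["r_pred_2"] == pytest.approx(0.0, abs=1e-12)

    def test_four_point_toy_matches_spreadsheet(self):
        """Every statistic checked against explicit cell-by-cell arithmetic."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.array([1.1, 1.9, 3.2, 3.8])
        y_train_mean, y_train_ss, n_train = 2.5, 5.0, 5
        out = external_metrics(y, yhat, y_train_mean, y_train_ss, n_train)

        # --- independent spreadsheet-style computation ---
        press = (1.0 - 1.1) ** 2 + (2.0 - 1.9) ** 2 + (3.0 - 3.2) ** 2 + (4.0 - 3.8) ** 2
        ybar, pbar = 2.5, (1.1 + 1.9 + 3.2 + 3.8) / 4.0
        ss_y = sum((v - ybar) ** 2 for v in y)
        ss_p = sum((v - pbar) ** 2 for v in yhat)
        sxy = sum((a - ybar) * (b - pbar) for a, b in zip(y, yhat))
        r2 = sxy**2 / (ss_y * ss_p)
        k = sum(a * b for a, b in zip(y, yhat)) / sum(b * b for b in yhat)
        k_prime = sum(a * b for a, b in zip(y, yhat)) / sum(a * a for a in y)
        r0_2 = 1.0 - sum((a - k * b) ** 2 for a, b in zip(y, yhat)) / ss_y
        r0_2p = 1.0 - sum((b - k_prime * a) ** 2 for a, b in zip(y, yhat)) / ss_p
        rm_2 = r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))
        rm_2p = r2 * (1.0 - np.sqrt(abs(r2 - r0_2p)))
        r_pred_2 = 1.0 - press / sum((v - y_train_mean) ** 2 for v in y)
        qf2_2 = 1.0 - press / ss_y
        qf3_2 = 1.0 - (press / 4.0) / (y_train_ss / n_train)
        ccc = 2.0 * (sxy / 4.0) / (ss_y / 4.0 + ss_p / 4.0 + (ybar - pbar) ** 2)
        chi2 = sum((a - b) ** 2 / abs(b) for a, b in zip(y, yhat))
        rmse = np.sqrt(press / 4.0)
        mae = sum(abs(a - b) for a, b in zip(y, yhat)) / 4.0

        expected = dict(r2=r2, k=k, k_prime=k_prime, r0_2=r0_2, r0_2_prime=r0_2p,
                        delta_r0_2=abs(r0_2 - r0_2p), rm_2=rm_2, rm_2_prime=rm_2p,
                        r_pred_2=r_pred_2, qf1_2=r_pred_2, qf2_2=qf2_2, qf3_2=qf3_2,
                        q_ccc_2=ccc, chi2=chi2, rmse=rmse, mae=mae, rss=press)
        for key, val in expected.items():
            assert out[key] == pytest.approx(val, abs=1e-10), key

    def test_order_invariance(self, rng):
        y = rng.uniform(5, 9, 10)
        yhat = y + rng.normal(0, 0.3, 10)
        a = external_metrics(y, yhat, 7.0, 8.0, 20)
        perm = rng.permutation(10)
        b = external_metrics(y[perm], yhat[perm], 7.0, 8.0, 20)
        for key in a:
            assert a[key] == pytest.approx(b[key], abs=1e-12), key

    def test_zero_y_variance_rejected(self):
        with pytest.raises(ParameterError):
            external_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], 1.0, 1.0, 5)


# Published CoMFA statistics for the four training/test splits, with the
# test-side slope and through-origin values used by the gates.
PUBLISHED_SETS = {
    "SET-A": dict(q2=0.593, r2=0.839, chi2=0.285, rmse=0.333, k_test=0.994,
                  k_prime_test=1.002, delta_r0_2_test=0.046, rm_2_test=0.410,
                  rm_2_prime_test=0.466, r_pred_2=0.495),
    "SET-B": dict(q2=0.541, r2=0.666, chi2=0.537, rmse=0.437, k_test=0.979,
                  k_prime_test=1.015, delta_r0_2_test=0.137, rm_2_test=0.333,
                  rm_2_prime_test=0.242, r_pred_2=0.361),
    "SET-C": dict(q2=0.505, r2=0.643, chi2=0.507, rmse=0.430, k_test=1.009,
                  k_prime_test=0.985, delta_r0_2_test=0.317, rm_2_test=0.630,
                  rm_2_prime_test=0.313, r_pred_2=0.724),
    "SET-D": dict(q2=0.633, r2=0.897, chi2=0.387, rmse=0.382, k_test=1.007,
                  k_prime_test=0.991, delta_r0_2_test=0.028, rm_2_test=0.846,
                  rm_2_prime_test=0.748, r_pred_2=0.911),
}


class TestThresholdGate:
    @pytest.mark.parametrize("name", list(PUBLISHED_SETS))
    def test_only_set_d_passes_all_gates(self, name):
        flags = threshold_gate(ValidationReport(**PUBLISHED_SETS[name]))
        assert flags["overall"] == (name == "SET-D")

    def test_set_b_fails_on_predictivity(self):
        flags = threshold_gate(ValidationReport(**PUBLISHED_SETS["SET-B"]))
        assert not flags["r_pred^2 > 0.6"]

    def test_boundary_is_strict(self):
        report = ValidationReport(**{**PUBLISHED_SETS["SET-D"], "q2": 0.5})
        assert not threshold_gate(report)["q2 > 0.5"]


class TestBootstrap:
    def test_noiseless_gives_unit_r2_zero_sd(self, rng):
        X = rng.normal(0, 1, (15, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 7.0
        bs_r2, bs_sd = bootstrap_r2(X, y, onc=3, n_boot=30, seed=0)
        assert bs_r2 == pytest.approx(1.0, abs=1e-10)
        assert bs_sd == pytest.approx(0.0, abs=1e-10)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(0, 1, (20, 5))
        y = X[:, 0] + rng.normal(0, 0.5, 20)
        assert bootstrap_r2(X, y, 2, seed=3) == bootstrap_r2(X, y, 2, seed=3)

    def test_bootstrap_r2_is_optimistic(self):
        """Resampled training r^2 exceeds the full-sample r^2 in nearly every
        run (duplicated rows are easier to fit)."""
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.normal(0, 1, (20, 6))
            y = X[:, 0] - X[:, 1] + r.normal(0, 1.0, 20)
            full = q.fit_pls(X, y, 2).r2
            bs, _ = bootstrap_r2(X, y, 2, n_boot=30, seed=seed)
            wins += bs >= full
        assert wins >= 16


class TestWilliamsAD:
    def test_centroid_test_point_leverage(self, rng):
        T = rng.normal(0, 1, (20, 3))
        T -= T.mean(axis=0)  # scores are centered in PLS
        ad = williams_ad(T, T.mean(axis=0, keepdims=True), np.zeros(20), [0.0],
                         onc=3, test_ids=["center"])
        assert ad.leverages["center"] == pytest.approx(1.0 / 20.0, abs=1e-12)

    def test_training_leverages_sum_to_onc_plus_one(self, pipeline_result):
        ad = pipeline_result.ad
        train_sum = sum(ad.leverages[c] for c, r in ad.roles.items() if r == "train")
        assert train_sum == pytest.approx(pipeline_result.report.onc + 1, abs=1e-6)

    def test_big_residual_flagged(self, rng):
        T = rng.normal(0, 1, (15, 2))
        res = np.zeros(15)
        res[4] = 3.5
        ad = williams_ad(T, None, res, [], onc=2,
                         train_ids=[f"c{i}" for i in range(15)])
        assert "c4" in ad.outliers

    def test_displaced_compound_is_flagged(self):
        """A compound whose structure is moved out of the common frame after
        activity assignment becomes an applicability-domain outlier."""
        mset, acts = q.generate_ligand_series(q.SyntheticSeriesSpec(seed=1))
        split = q.stratified_split(acts, seed=1)
        cid = split.test_ids[0]
        mols = []
        for m in mset:
            m2 = copy.deepcopy(m)
            if m.id == cid:
                m2.coords = m2.coords + np.array([2.5, 0.0, 0.0])
            mols.append(m2)
        res = q.qsar_pipeline(q.MoleculeSet(mols), acts, seed=1, n_boot=5)
        assert cid in res.ad.outliers


class TestPipelineReport:
    def test_qf1_equals_r_pred(self, pipeline_result):
        r = pipeline_result.report
        assert r.qf1_2 == pytest.approx(r.r_pred_2, abs=1e-12)

    def test_report_complete_and_finite(self, pipeline_result):
        r = pipeline_result.report
        for name, val in r.as_dict().items():
            if isinstance(val, float):
                assert np.isfinite(val), name
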