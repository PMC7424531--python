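import shutil
import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ttnsight.classifier import (
    build_features,
    compare_auc,
    cv_classify,
    external_validate,
    fit_model,
    genomic_instability_group,
    msi_pcr_call,
)
from ttnsight.tmb import profile_samples


class TestBuildFeatures:
    def test_arithmetic(self, toy_mutations, toy_metadata):
        profiles = profile_samples(toy_mutations, toy_metadata)
        feats = build_features(profiles, "BRAF")
        assert feats.loc["S1", "snv"] == 0
        assert feats.loc["S1", "indel"] == 1
        assert feats.loc["S1", "index1"] == 1.0  # indel-only sample
        assert feats.loc["S1", "index2"] == 0.0  # snv=0 policy

    def test_ratio_values(self, small_cohort):
        _, mutations, metadata, _ = small_cohort
        profiles = profile_samples(mutations, metadata)
        feats = build_features(profiles, "TTN")
        nz = feats[feats["total"] > 0]
        np.testing.assert_allclose(nz["index1"], nz["indel"] / nz["total"])
        snv_pos = feats[feats["snv"] > 0]
        np.testing.assert_allclose(snv_pos["index2"], snv_pos["indel"] / snv_pos["snv"])

    def test_zero_sample_indices_are_zero_and_finite(self, toy_mutations, toy_metadata):
        profiles = profile_samples(toy_mutations, toy_metadata)
        feats = build_features(profiles, "TP53")
        assert feats.loc["S3", "index1"] == 0.0 and feats.loc["S3", "index2"] == 0.0
        assert np.isfinite(feats.to_numpy()).all()

    def test_fuzzed_counts_never_nonfinite(self):
        rng = np.random.default_rng(6)
        from ttnsight.tmb import SampleProfiles

        n = 200
        snv = pd.DataFrame({"X": rng.integers(0, 3, n)}, index=[f"S{i}" for i in range(n)])
        indel = pd.DataFrame({"X": rng.integers(0, 3, n)}, index=snv.index)
        profiles = SampleProfiles(
            counts=snv + indel, snv_counts=snv, indel_counts=indel,
            tmb=(snv + indel).sum(axis=1),
            metadata=pd.DataFrame({"sample_id": snv.index}),
        )
        feats = build_features(profiles, "X")
        assert np.isfinite(feats.to_numpy()).all()

    def test_absent_gene_rejected(self, toy_mutations, toy_metadata):
        profiles = profile_samples(toy_mutations, toy_metadata)
        with pytest.raises(KeyError):
            build_features(profiles, "NOPE")


class TestMsiPcrCall:
    @pytest.mark.parametrize(
        "loci,expected",
        [
            ([True, True, False, False, False], "MSI_H"),
            ([True, True, True, True, True], "MSI_H"),
            ([True, False, False, False, False], "MSI_L"),
            ([False, False, False, False, False], "MSS"),
        ],
    )
    def test_locus_thresholds(self, loci, expected):
        assert msi_pcr_call(loci) == expected

    @pytest.mark.parametrize("n", [4, 6, 0])
    def test_wrong_locus_count_rejected(self, n):
        with pytest.raises(ValueError):
            msi_pcr_call([True] * n)


class TestInstabilityGrouping:
    def test_rules(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d"],
                "msi_status": ["MSI_H", "MSS", "MSI_L", "MSS"],
                "pole_status": ["wildtype", "exonuclease_mutant", "wildtype", "wildtype"],
            }
        )
        groups = genomic_instability_group(meta)
        assert groups["a"] == "HGI"   # MSI-H
        assert groups["b"] == "HGI"   # non-MSI POLE mutant
        assert groups["c"] == "LGI"   # MSI-L counts as non-MSI
        assert groups["d"] == "LGI"

    def test_unknown_status_excluded(self):
        meta = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "msi_status": ["unknown", "MSS"],
                "pole_status": ["wildtype", "wildtype"],
            }
        )
        groups = genomic_instability_group(meta)
        assert list(groups.index) == ["b"]


def _feature_frame(rng, n):
    return pd.DataFrame(
        rng.normal(size=(n, 5)),
        columns=["snv", "indel", "total", "index1", "index2"],
        index=[f"S{i}" for i in range(n)],
    )


class TestCvClassify:
    def test_separable_labels_reach_auc_one(self):
        rng = np.random.default_rng(1)
        feats = _feature_frame(rng, 100)
        feats["total"] = np.r_[rng.uniform(10, 20, 50), rng.uniform(0, 5, 50)]
        labels = pd.Series(np.r_[np.ones(50), np.zeros(50)].astype(int), index=feats.index)
        cv = cv_classify(feats, labels, b=30, seed=2, n_estimators=25)
        assert cv.auc_0 == pytest.approx(1.0, abs=0.01)
        assert cv.perm_p <= 1 / 30

    def test_each_sample_predicted_once_and_fold_order_invariance(self):
        rng = np.random.default_rng(3)
        feats = _feature_frame(rng, 60)
        labels = pd.Series(rng.integers(0, 2, 60), index=feats.index)
        cv = cv_classify(feats, labels, b=0, seed=5, n_estimators=25)
        assert len(cv.pooled_probabilities) == 60
        assert cv.pooled_probabilities.index.equals(feats.index)
        # pooled AUC recomputed from the stored probabilities matches auc_0
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(labels, cv.pooled_probabilities) == pytest.approx(cv.auc_0)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(4)
        feats = _feature_frame(rng, 20)
        labels = pd.Series(np.zeros(20, dtype=int), index=feats.index)
        with pytest.raises(ValueError):
            cv_classify(feats, labels)

    def test_fold_count_reduced_with_warning_for_tiny_cohorts(self):
        rng = np.random.default_rng(5)
        feats = _feature_frame(rng, 8)
        labels = pd.Series([0, 1] * 4, index=feats.index)
        with pytest.warns(UserWarning, match="fold"):
            cv = cv_classify(feats, labels, folds=10, b=0, seed=6, n_estimators=10)
        assert cv.folds == 4  # capped by the minority-class size under stratification

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        feats = _feature_frame(rng, 40)
        labels = pd.Series(rng.integers(0, 2, 40), index=feats.index)
        a = cv_classify(feats, labels, b=5, seed=9, n_estimators=10)
        b = cv_classify(feats, labels, b=5, seed=9, n_estimators=10)
        assert a.auc_0 == b.auc_0
        np.testing.assert_array_equal(a.perm_aucs, b.perm_aucs)

    def test_permutation_p_type_one_error_controlled(self):
        """Empirical type-I error of the permutation AUC p at alpha=0.1
        stays within binomial tolerance of nominal under null labels."""
        rng = np.random.default_rng(11)
        n_rep, alpha = 40, 0.1
        rejections = 0
        for _ in range(n_rep):
            feats = _feature_frame(rng, 60)
            labels = pd.Series(rng.integers(0, 2, 60), index=feats.index)
            if labels.nunique() < 2:
                continue
            cv = cv_classify(feats, labels, b=50, seed=int(rng.integers(2**31)), n_estimators=8)
            rejections += int(cv.perm_p <= alpha)
        assert rejections / n_rep <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / n_rep)


class TestExternalValidation:
    def _cohorts(self):
        rng = np.random.default_rng(13)
        feats = _feature_frame(rng, 120)
        y = np.tile([1, 0], 60)
        feats["total"] = rng.uniform(0, 10, 120) + 8 * y
        labels = pd.Series(y.astype(int), index=feats.index)
        return feats.iloc[:80], labels.iloc[:80], feats.iloc[80:], labels.iloc[80:]

    def test_no_refit_and_training_optimism(self):
        fa, la, fb, lb = self._cohorts()
        model = fit_model(fa, la, seed=1, n_estimators=50)
        _, auc_ext = external_validate(model, fb, lb)
        _, auc_train = external_validate(model, fa, la)
        cv = cv_classify(fa, la, b=0, seed=1, n_estimators=50)
        assert auc_train >= cv.auc_0 - 1e-9  # resubstitution optimism
        assert 0.0 <= auc_ext <= 1.0

    def test_flipped_labels_mirror_auc(self):
        fa, la, fb, lb = self._cohorts()
        model = fit_model(fa, la, seed=1, n_estimators=25)
        _, auc = external_validate(model, fb, lb)
        _, auc_flipped = external_validate(model, fb, 1 - lb)
        assert auc_flipped == pytest.approx(1.0 - auc, abs=1e-12)

    def test_single_sample_cohort_rejected(self):
        fa, la, fb, lb = self._cohorts()
        model = fit_model(fa, la, seed=1, n_estimators=10)
        with pytest.raises(ValueError):
            external_validate(model, fb.iloc[:1], lb.iloc[:1])

    def test_schema_mismatch_rejected(self):
        fa, la, fb, lb = self._cohorts()
        model = fit_model(fa, la, seed=1, n_estimators=10)
        with pytest.raises(ValueError, match="schema"):
            external_validate(model, fb.rename(columns={"snv": "x"}), lb)


class TestCompareAuc:
    def test_identical_predictors_give_p_one(self):
        rng = np.random.default_rng(17)
        y = rng.integers(0, 2, 50)
        p = rng.random(50)
        assert compare_auc(p, p, y) == 1.0

    def test_perfect_vs_random_detected(self):
        rng = np.random.default_rng(18)
        y = np.r_[np.ones(100), np.zeros(100)].astype(int)
        perfect = np.r_[rng.uniform(0.6, 1.0, 100), rng.uniform(0.0, 0.4, 100)]
        random_p = rng.random(200)
        assert compare_auc(perfect, random_p, y) < 0.01

    def test_tiny_cohort_computed_with_warning(self):
        y = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning, match="low-power"):
            p = compare_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([0.6, 0.2, 0.9, 0.3]), y)
        assert 0.0 <= p <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_auc(np.zeros(3), np.zeros(4), np.array([0, 1, 0, 1]))

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_proc_delong_oracle(self):
        """Cross-check the paired DeLong p-value against pROC::roc.test."""
        rng = np.random.default_rng(19)
        y = np.r_[np.ones(30), np.zeros(30)].astype(int)
        p1 = np.clip(0.5 * y + rng.normal(0.25, 0.2, 60), 0, 1)
        p2 = np.clip(0.3 * y + rng.normal(0.35, 0.25, 60), 0, 1)
        ours = compare_auc(p1, p2, y)
        with tempfile.TemporaryDirectory() as td:
            data = Path(td) / "d.csv"
            pd.DataFrame({"y": y, "p1": p1, "p2": p2}).to_csv(data, index=False)
            script = (
                f'd <- read.csv("{data}"); suppressMessages(library(pROC));'
                "r1 <- roc(d$y, d$p1, quiet=TRUE); r2 <- roc(d$y, d$p2, quiet=TRUE);"
                'cat(roc.test(r1, r2, method="delong", paired=TRUE)$p.value)'
            )
            out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        assert ours == pytest.approx(float(out.stdout.strip()), rel=1e-6)
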