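"""MSI-H classification from single-gene mutation-count features.

Five features summarize a sample's mutation load within the surrogate gene
(TTN by default): the SNV count, the indel count, their total, index 1 =
indel/(SNV+indel) and index 2 = indel/SNV (both defined as 0 when their
denominator is 0, keeping every feature finite).  Because MSI-H tumors are
indel-enriched, these features separate MSI-H from microsatellite-stable
tumors.  A random forest is evaluated by pooled 10-fold cross-validation —
every sample predicted exactly once on held-out data, one ROC over the
pooled probabilities — and calibrated by a label-permutation p-value that
reruns the full CV per permutation: p = B^-1 sum_b I(AUC_0 <= AUC_b).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

from .tmb import SampleProfiles
from .vocab import MsiStatus, PoleStatus

log = logging.getLogger(__name__)

FEATURE_COLUMNS = ["snv", "indel", "total", "index1", "index2"]


def build_features(profiles: SampleProfiles, gene: str = "TTN") -> pd.DataFrame:
    """Per-sample feature table from the surrogate gene's SNV/indel counts."""
    if gene not in profiles.genes:
        raise KeyError(f"gene {gene!r} absent from profiles")
    snv = profiles.snv_counts[gene].astype(float)
    indel = profiles.indel_counts[gene].astype(float)
    total = snv + indel
    with np.errstate(invalid="ignore", divide="ignore"):
        index1 = np.where(total > 0, indel / total, 0.0)
        index2 = np.where(snv > 0, indel / snv, 0.0)
    out = pd.DataFrame(
        {"snv": snv, "indel": indel, "total": total, "index1": index1, "index2": index2},
        index=profiles.samples,
    )
    assert np.isfinite(out.to_numpy()).all()
    return out


def msi_pcr_call(locus_instability) -> str:
    """MSI phenotype from instability at the five PCR microsatellite loci.

    Instability at >= 2 of the 5 loci is MSI-H, exactly 1 is MSI-L, 0 is MSS.
    """
    loci = [bool(v) for v in locus_instability]
    if len(loci) != 5:
        raise ValueError(f"expected exactly 5 loci, got {len(loci)}")
    unstable = sum(loci)
    if unstable >= 2:
        return MsiStatus.MSI_H.value
    if unstable == 1:
        return MsiStatus.MSI_L.value
    return MsiStatus.MSS.value


def genomic_instability_group(metadata: pd.DataFrame) -> pd.Series:
    """HGI/LGI grouping per sample.

    MSI-H samples and non-MSI POLE proofreading-domain mutants form the
    high-genomic-instability (HGI) group; non-MSI POLE-wildtype samples the
    low (LGI) group.  Samples with unknown MSI or POLE status are excluded
    (warned).
    """
    msi = metadata["msi_status"]
    pole = metadata["pole_status"]
    known = (msi != MsiStatus.UNKNOWN.value) & (pole != PoleStatus.UNKNOWN.value)
    if (~known).any():
        log.warning("excluding %d sample(s) with unknown MSI/POLE status", int((~known).sum()))
    non_msi = msi.isin([MsiStatus.MSI_L.value, MsiStatus.MSS.value])
    hgi = (msi == MsiStatus.MSI_H.value) | (non_msi & (pole == PoleStatus.EXONUCLEASE_MUTANT.value))
    out = pd.Series(np.where(hgi, "HGI", "LGI"), index=metadata["sample_id"], name="instability_group")
    return out[known.to_numpy()]


@dataclass(frozen=True)
class CVOutcome:
    """Pooled cross-validated probabilities with the permutation-calibrated AUC."""

    pooled_probabilities: pd.Series
    auc_0: float
    perm_aucs: np.ndarray
    perm_p: float
    folds: int
    seed: int


def _pooled_cv_probs(
    X: np.ndarray, y: np.ndarray, folds: int, rng: np.random.Generator,
    n_estimators: int, stratified: bool,
) -> np.ndarray:
    splitter_seed = int(rng.integers(2**31))
    cls = StratifiedKFold if stratified else KFold
    kf = cls(n_splits=folds, shuffle=True, random_state=splitter_seed)
    probs = np.empty(len(y))
    for train, test in kf.split(X, y):
        model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=int(rng.integers(2**31))
        )
        model.fit(X[train], y[train])
        probs[test] = model.predict_proba(X[test])[:, list(model.classes_).index(1)]
    return probs


def cv_classify(
    features: pd.DataFrame,
    labels: pd.Series,
    folds: int = 10,
    b: int = 0,
    seed: int = 0,
    n_estimators: int = 500,
    stratified: bool = True,
) -> CVOutcome:
    """Pooled k-fold CV ROC with a label-permutation AUC p-value.

    Labels are binary (1 = positive class).  Each sample is predicted
    exactly once on held-out data; a single AUC is computed over the pooled
    probabilities.  When ``b`` > 0, each permutation shuffles the labels and
    reruns the complete CV, and p = B^-1 #{b : AUC_0 <= AUC_b}.  Folds are
    stratified by class by default so every training split sees both
    classes.  Deterministic under ``seed``.
    """
    y = np.asarray(labels.loc[features.index], dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("labels contain a single class; classification undefined")
    n = len(y)
    max_folds = min(np.bincount(y)) if stratified else n
    if max_folds < folds:
        warnings.warn(f"cohort supports at most {max_folds} folds; reducing fold count from {folds}")
        folds = max_folds
    X = features.to_numpy(float)
    rng = np.random.default_rng(seed)

    probs = _pooled_cv_probs(X, y, folds, rng, n_estimators, stratified)
    auc_0 = float(roc_auc_score(y, probs))

    perm_aucs = np.empty(b)
    for i in range(b):
        y_perm = rng.permutation(y)
        p_perm = _pooled_cv_probs(X, y_perm, folds, rng, n_estimators, stratified)
        perm_aucs[i] = roc_auc_score(y_perm, p_perm)
    perm_p = float(np.mean(auc_0 <= perm_aucs)) if b > 0 else float("nan")

    return CVOutcome(
        pooled_probabilities=pd.Series(probs, index=features.index, name="probability"),
        auc_0=auc_0,
        perm_aucs=perm_aucs,
        perm_p=perm_p,
        folds=folds,
        seed=seed,
    )


def fit_model(
    features: pd.DataFrame, labels: pd.Series, seed: int = 0, n_estimators: int = 500
) -> RandomForestClassifier:
    """Fit the random forest on a full cohort (for external validation)."""
    y = np.asarray(labels.loc[features.index], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    model = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    model.fit(features.to_numpy(float), y)
    model.feature_names_ = list(features.columns)
    return model


def external_validate(
    model: RandomForestClassifier, features: pd.DataFrame, labels: pd.Series
) -> tuple[pd.Series, float]:
    """Apply a trained model to an external cohort without refitting."""
    if list(features.columns) != getattr(model, "feature_names_", list(features.columns)):
        raise ValueError("feature schema mismatch between training and validation cohorts")
    y = np.asarray(labels.loc[features.index], dtype=int)
    if len(y) < 2 or len(np.unique(y)) < 2:
        raise ValueError("external cohort needs both classes and >= 2 samples for a ROC")
    probs = model.predict_proba(features.to_numpy(float))[:, list(model.classes_).index(1)]
    auc = float(roc_auc_score(y, probs))
    return pd.Series(probs, index=features.index, name="probability"), auc


def _delong_variance(y: np.ndarray, probs: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement components for one predictor."""
    pos = probs[y == 1]
    neg = probs[y == 0]
    m, n = len(pos), len(neg)

    def midrank(x: np.ndarray) -> np.ndarray:
        return stats.rankdata(x, method="average")

    all_r = midrank(np.concatenate([pos, neg]))
    pos_r = midrank(pos)
    neg_r = midrank(neg)
    auc = (all_r[:m].sum() / m - (m + 1) / 2.0) / n
    v10 = (all_r[:m] - pos_r) / n            # per-positive placement values
    v01 = 1.0 - (all_r[m:] - neg_r) / m      # per-negative placement values
    return float(auc), v10, v01


def compare_auc(probabilities_1: np.ndarray, probabilities_2: np.ndarray, labels: np.ndarray) -> float:
    """Paired DeLong test p-value for the difference of two correlated AUCs.

    Both probability vectors must score the same samples under the same
    labels.  Identical predictors return p = 1.  Small cohorts (< 10 per
    class) are computed but flagged as low-power.
    """
    p1 = np.asarray(probabilities_1, float)
    p2 = np.asarray(probabilities_2, float)
    y = np.asarray(labels, int)
    if not (len(p1) == len(p2) == len(y)):
        raise ValueError("probability vectors and labels must have equal length")
    if np.array_equal(p1, p2):
        return 1.0
    m = int((y == 1).sum())
    n = int((y == 0).sum())
    if m == 0 or n == 0:
        raise ValueError("both classes required")
    if min(m, n) < 10:
        warnings.warn("fewer than 10 samples per class; paired AUC comparison is low-power")

    auc1, v10_1, v01_1 = _delong_variance(y, p1)
    auc2, v10_2, v01_2 = _delong_variance(y, p2)
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return 1.0
    z = (auc1 - auc2) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))
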