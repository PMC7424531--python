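"""Genome-wide per-gene correlation sweep against total mutation burden.

For each gene the Pearson correlation between its per-sample mutation count
and the per-sample total is computed on raw counts; the gene ranking by
correlation identifies single-gene burden surrogates.  Per-tumor-type sweeps
carry a Bonferroni family-wise-corrected p (raw p times the number of types
tested, capped at 1).  A random gene-set sweep asks whether small multi-gene
sets rival the top single gene.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .tmb import SampleProfiles, profile_samples  # noqa: F401  (re-exported convenience)

SWEEP_COLUMNS = ["gene", "rho", "p_value", "n_samples", "fwer_p", "rank_by_rho"]


def _pearson_vectorized(counts: np.ndarray, total: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson rho and two-sided p of each column of ``counts`` against ``total``."""
    n = counts.shape[0]
    xc = counts - counts.mean(axis=0)
    yc = total - total.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def correlation_sweep(
    profiles: SampleProfiles,
    min_nonzero: int = 1,
    leave_gene_out: bool = False,
    n_strata_for_fwer: int = 1,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of mutation count with total burden.

    The total includes the tested gene's own mutations unless
    ``leave_gene_out``.  Genes with zero count variance (or fewer than
    ``min_nonzero`` mutated samples) are skipped.  Output is ranked by rho
    descending, ties broken by smaller p then gene symbol.
    """
    counts = profiles.counts
    n = len(counts)
    if n < 3:
        raise ValueError(f"correlation sweep needs >= 3 samples, got {n}")
    total = profiles.tmb.to_numpy(float)
    mat = counts.to_numpy(float)
    nonzero = (mat > 0).sum(axis=0)
    variance = mat.var(axis=0)
    eligible = (variance > 0) & (nonzero >= min_nonzero)

    genes = counts.columns[eligible]
    if leave_gene_out:
        rho = np.empty(int(eligible.sum()))
        p = np.empty(int(eligible.sum()))
        for k, j in enumerate(np.flatnonzero(eligible)):
            y = total - mat[:, j]
            if y.std() == 0:
                rho[k], p[k] = np.nan, np.nan
                continue
            r, pv = _pearson_vectorized(mat[:, [j]], y)
            rho[k], p[k] = r[0], pv[0]
    else:
        if total.std() == 0:
            raise ValueError("total burden is constant; sweep undefined")
        rho, p = _pearson_vectorized(mat[:, eligible], total)

    out = pd.DataFrame(
        {
            "gene": genes,
            "rho": rho,
            "p_value": p,
            "n_samples": n,
            "fwer_p": np.minimum(1.0, p * n_strata_for_fwer),
        }
    ).dropna(subset=["rho"])
    out = out.sort_values(["rho", "p_value", "gene"], ascending=[False, True, True]).reset_index(drop=True)
    out["rank_by_rho"] = np.arange(1, len(out) + 1)
    return out


def per_stratum_sweep(
    profiles: SampleProfiles,
    stratum: str = "tumor_type",
    n_strata_for_fwer: int = 33,
    min_nonzero: int = 1,
) -> dict[str, pd.DataFrame]:
    """Run the sweep within each stratum; FWER p = min(1, p x n_strata_for_fwer).

    Strata with fewer than 3 samples are skipped with a warning-level log.
    The default multiplier of 33 corresponds to a pan-cancer panel of 33
    tumor types.
    """
    import logging

    log = logging.getLogger(__name__)
    meta = profiles.metadata
    results: dict[str, pd.DataFrame] = {}
    for value, grp in meta.groupby(stratum):
        if len(grp) < 3:
            log.warning("stratum %s has %d samples (<3); skipped", value, len(grp))
            continue
        idx = grp["sample_id"]
        sub = SampleProfiles(
            counts=profiles.counts.loc[idx],
            snv_counts=profiles.snv_counts.loc[idx],
            indel_counts=profiles.indel_counts.loc[idx],
            tmb=profiles.tmb.loc[idx],
            metadata=grp.reset_index(drop=True),
        )
        results[str(value)] = correlation_sweep(
            sub, min_nonzero=min_nonzero, n_strata_for_fwer=n_strata_for_fwer
        )
    return results


def cds_count_relation(gene_counts_total: pd.Series, annotations: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between CDS length and cohort-wide mutation count."""
    ann = annotations.set_index("gene")
    common = gene_counts_total.index.intersection(ann.index)
    if len(common) < 3:
        raise ValueError(f"CDS/count relation needs >= 3 annotated genes, got {len(common)}")
    x = ann.loc[common, "cds_length"].to_numpy(float)
    y = gene_counts_total.loc[common].to_numpy(float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r = stats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def random_geneset_sweep(
    profiles: SampleProfiles,
    n_sets: int,
    target_labels: pd.Series,
    seed: int,
    set_size_range: tuple[int, int] = (2, 25),
) -> pd.DataFrame:
    """Correlation and label-AUC of randomly drawn gene sets.

    For each of ``n_sets`` random sets (sizes uniform on
    ``set_size_range``), the per-sample combined mutation count is
    correlated with total burden (Pearson) and scored as a classifier of
    the binary ``target_labels`` (ROC AUC).  Deterministic under ``seed``.
    """
    lo, hi = set_size_range
    genes = np.asarray(profiles.genes)
    if hi > len(genes):
        raise ValueError(f"set size {hi} exceeds gene universe {len(genes)}")
    rng = np.random.default_rng(seed)
    labels = target_labels.loc[profiles.samples].to_numpy()
    total = profiles.tmb.to_numpy(float)
    mat = profiles.counts

    rows = []
    for _ in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        combined = mat[list(members)].sum(axis=1).to_numpy(float)
        if combined.std() == 0 or total.std() == 0:
            rho = np.nan
        else:
            rho = float(stats.pearsonr(combined, total).statistic)
        auc = float(roc_auc_score(labels, combined)) if len(np.unique(labels)) == 2 else np.nan
        rows.append(("|".join(sorted(members)), size, rho, auc))
    return pd.DataFrame(rows, columns=["genes", "set_size", "rho_with_tmb", "auc_for_label"])
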