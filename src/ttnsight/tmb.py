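"""Tumor mutation burden and per-gene mutation-rate metrics.

TMB here is a raw count: every SNV and indel in exonic regions and splice
sites qualifies, synonymous mutations included; intronic (and unclassifiable
``Other``) records do not.  Per-gene counts are split into SNV and indel
components, the building blocks of the single-gene surrogate features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vocab import VariantClass

#: Classifications that do not count toward TMB.
NON_QUALIFYING = {VariantClass.INTRON.value, VariantClass.OTHER.value}


def qualifies_for_tmb(variant_classification: str) -> bool:
    """True iff a mutation of this class counts toward TMB."""
    return variant_classification not in NON_QUALIFYING


@dataclass
class SampleProfiles:
    """Per-sample burden and per-gene count matrices for a cohort.

    ``counts``/``snv_counts``/``indel_counts`` are samples x genes integer
    DataFrames over qualifying mutations; ``tmb`` is the per-sample total.
    Invariants (checked at build): tmb equals the row sum of ``counts`` and
    ``counts = snv_counts + indel_counts``.
    """

    counts: pd.DataFrame
    snv_counts: pd.DataFrame
    indel_counts: pd.DataFrame
    tmb: pd.Series
    metadata: pd.DataFrame

    @property
    def samples(self) -> pd.Index:
        return self.counts.index

    @property
    def genes(self) -> pd.Index:
        return self.counts.columns

    def gene_totals(self) -> pd.Series:
        """Cohort-wide mutation count per gene."""
        return self.counts.sum(axis=0)


def profile_samples(mutations: pd.DataFrame, metadata: pd.DataFrame) -> SampleProfiles:
    """Build per-sample TMB and per-gene SNV/indel counts.

    Samples present in the metadata but without mutations get zero rows;
    mutation rows whose sample is absent from the metadata are an error.
    """
    samples = pd.Index(metadata["sample_id"], name="sample_id")
    unknown = set(mutations["sample_id"]) - set(samples)
    if unknown:
        raise ValueError(f"mutation table references samples absent from metadata: {sorted(unknown)[:10]}")

    qual = mutations[mutations["variant_classification"].map(qualifies_for_tmb)]
    genes = pd.Index(sorted(qual["gene"].unique()), name="gene")

    def pivot(df: pd.DataFrame) -> pd.DataFrame:
        tab = df.groupby(["sample_id", "gene"]).size().unstack(fill_value=0)
        return tab.reindex(index=samples, columns=genes, fill_value=0).astype(int)

    counts = pivot(qual)
    snv = pivot(qual[qual["variant_type"] == "SNV"])
    indel = pivot(qual[qual["variant_type"].isin(["INS", "DEL"])])
    tmb = counts.sum(axis=1)

    assert (counts.to_numpy() == (snv + indel).to_numpy()).all()
    assert (tmb.to_numpy() == counts.sum(axis=1).to_numpy()).all()
    return SampleProfiles(counts=counts, snv_counts=snv, indel_counts=indel, tmb=tmb,
                          metadata=metadata.set_index("sample_id", drop=False).loc[samples].reset_index(drop=True))


def normalized_rates(gene_counts_total: pd.Series, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-gene mutation rates normalized by CDS length and by CDS·GC.

    Genes annotated but unmutated are included with rate 0 (required for
    replication-time correlations); counted genes lacking an annotation are
    an error.
    """
    ann = annotations.set_index("gene")
    missing = set(gene_counts_total.index) - set(ann.index)
    if missing:
        raise ValueError(f"genes without annotation: {sorted(missing)[:10]}")
    counts = gene_counts_total.reindex(ann.index, fill_value=0).astype(float)
    out = pd.DataFrame(
        {
            "gene": ann.index,
            "count": counts.to_numpy(),
            "rate_cds": (counts / ann["cds_length"]).to_numpy(),
            "rate_cds_gc": (counts / (ann["cds_length"] * ann["gc_fraction"])).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class FlagsComparison:
    """Paired comparison of CDS-normalized rates: target gene vs other FLAGS vs the rest."""

    median_target: float
    median_flags: float
    median_rest: float
    p_target_vs_flags: float
    p_flags_vs_rest: float


def flags_rate_comparison(
    per_stratum_rates: pd.DataFrame, annotations: pd.DataFrame, target_gene: str
) -> FlagsComparison:
    """Paired Wilcoxon signed-rank comparison of normalized rates across strata.

    ``per_stratum_rates`` is a strata x genes DataFrame of CDS-normalized
    rates (e.g. one row per tumor type).  Each stratum contributes one
    paired observation per group: the target gene's rate, the mean rate of
    the other FLAGS genes, and the mean rate of the remaining genes.
    """
    if len(per_stratum_rates) < 2:
        raise ValueError("paired comparison needs >= 2 strata")
    ann = annotations.set_index("gene")
    flags = [g for g in ann.index[ann["is_flags"]] if g != target_gene and g in per_stratum_rates.columns]
    rest = [g for g in per_stratum_rates.columns if g != target_gene and g not in flags]
    if not flags or not rest:
        raise ValueError("need both FLAGS and non-FLAGS genes in the rate table")
    target = per_stratum_rates[target_gene].to_numpy(float)
    flags_mean = per_stratum_rates[flags].mean(axis=1).to_numpy(float)
    rest_mean = per_stratum_rates[rest].mean(axis=1).to_numpy(float)

    def paired_p(a: np.ndarray, b: np.ndarray) -> float:
        if np.allclose(a, b):
            return 1.0
        return float(stats.wilcoxon(a, b).pvalue)

    return FlagsComparison(
        median_target=float(np.median(target)),
        median_flags=float(np.median(flags_mean)),
        median_rest=float(np.median(rest_mean)),
        p_target_vs_flags=paired_p(target, flags_mean),
        p_flags_vs_rest=paired_p(flags_mean, rest_mean),
    )


def replication_time_association(
    rates: pd.DataFrame, annotations: pd.DataFrame, subset=None, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between CDS-normalized mutation rate and replication time.

    ``subset`` restricts to a gene list (e.g. the FLAGS genes); requires at
    least 3 genes with replication times and non-constant inputs.
    """
    ann = annotations.set_index("gene")
    tab = rates.set_index("gene")[["rate_cds"]].join(ann[["replication_time"]], how="inner")
    if subset is not None:
        tab = tab.loc[tab.index.intersection(pd.Index(subset))]
    tab = tab.dropna()
    if len(tab) < 3:
        raise ValueError(f"replication-time association needs >= 3 annotated genes, got {len(tab)}")
    x = tab["rate_cds"].to_numpy(float)
    y = tab["replication_time"].to_numpy(float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("correlation undefined for constant input")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)
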