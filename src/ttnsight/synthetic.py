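"""Synthetic cohort generator.

Emulates the statistical structure the downstream analyses assume: a
multi-tumor-type cohort with three genomic-instability subgroups — a
low-mutation group (LGI), an indel-enriched hypermutated MSI-H group, and an
SNV-driven ultra-mutated POLE proofreading-mutant group — with per-gene
mutation rates proportional to CDS length and modulated by replication
timing, tumor-only variant calls whose VAFs mix purity-scaled somatic and
germline (~0.5 / ~1.0) components, and an expression matrix in which the
immunostimulatory genes co-vary with mutation status of a tracking gene.

Generation is a pure function of (spec, seed).  A single seed is expanded
into independent substreams per stage, so adding a stage never perturbs the
streams of earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mutation_io import MUTATION_COLUMNS
from .vocab import IS_GENES, MsiStatus, PoleStatus

SUBGROUPS = ("LGI", "MSI_H", "POLE")

# SNV classes drawn for substitutions, with weights close to the empirical
# exome spectrum (missense-dominated, ~quarter synonymous).
_SNV_CLASSES = ("Missense", "Silent", "Nonsense", "Splice_Site")
_SNV_WEIGHTS = (0.66, 0.25, 0.06, 0.03)


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Subgroup mean burdens default to the magnitudes typical of exomes:
    tens of mutations in microsatellite-stable low-instability tumors,
    ~1200 in MSI-H hypermutators and ~5000 in POLE ultra-mutators.  The
    MSI-H group is indel-enriched; POLE indels are nearly absent.
    """

    n_samples: dict[str, int] = field(default_factory=lambda: {"LGI": 60, "MSI_H": 25, "POLE": 5})
    n_genes: int = 2000
    mean_tmb: dict[str, float] = field(default_factory=lambda: {"LGI": 60.0, "MSI_H": 1200.0, "POLE": 5000.0})
    indel_fraction: dict[str, float] = field(default_factory=lambda: {"LGI": 0.05, "MSI_H": 0.30, "POLE": 0.01})
    tmb_dispersion: float = 5.0  # negative-binomial shape; larger = less overdispersed
    cds_log_mean: float = 7.3  # lognormal CDS lengths, median ~1.5 kb
    cds_log_sd: float = 0.8
    tracking_gene: str = "TTN"
    tracking_cds_length: int = 100_000
    replication_time_effect: float = 0.0  # log-rate slope per SD of replication time
    tumor_types: tuple[str, ...] = ("COAD", "READ", "STAD", "UCEC")
    purity: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if sum(self.n_samples.values()) <= 0:
            raise ValueError("at least one sample required")
        for g, v in self.n_samples.items():
            if g not in SUBGROUPS or v < 0:
                raise ValueError(f"bad subgroup size {g}={v}")
        for g, v in self.indel_fraction.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"indel_fraction[{g}] outside [0,1]")
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must lie in (0,1]")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_gene_annotations(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene CDS lengths, GC fractions and replication times.

    The tracking gene receives the largest CDS (its defining property); the
    25 longest remaining genes are marked as FLAGS-like long passenger genes.
    """
    n = spec.n_genes
    genes = [spec.tracking_gene] + [f"G{i:05d}" for i in range(1, n)]
    cds = np.maximum(150, rng.lognormal(spec.cds_log_mean, spec.cds_log_sd, n)).astype(int)
    cds[0] = spec.tracking_cds_length
    cds[1:] = np.minimum(cds[1:], spec.tracking_cds_length - 1)
    gc = np.clip(rng.normal(0.45, 0.06, n), 0.25, 0.75)
    rt = np.clip(rng.normal(50.0, 15.0, n), 5.0, 95.0)
    # long genes replicate late on average (the field's empirical pattern)
    rt += 6.0 * (np.log(cds) - np.log(cds).mean()) / np.log(cds).std()
    df = pd.DataFrame(
        {"gene": genes, "cds_length": cds, "gc_fraction": gc, "replication_time": rt, "is_flags": False}
    )
    flags_idx = df["cds_length"].to_numpy().argsort()[::-1][: min(26, n)]
    df.loc[flags_idx, "is_flags"] = True
    return df


def gene_probabilities(annotations: pd.DataFrame, replication_time_effect: float) -> np.ndarray:
    """Multinomial gene-assignment probabilities: ∝ CDS · exp(effect · z(RT))."""
    cds = annotations["cds_length"].to_numpy(float)
    w = cds.copy()
    if replication_time_effect != 0.0:
        rt = annotations["replication_time"].to_numpy(float)
        z = (rt - rt.mean()) / rt.std()
        w *= np.exp(replication_time_effect * z)
    return w / w.sum()


def generate_mutation_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (mutations, metadata, annotations) for a cohort spec.

    Per-sample totals are negative-binomial around the subgroup mean; genes
    are assigned multinomially with probability proportional to CDS length
    times an optional replication-time modulation; the subgroup indel
    fraction sets the INS/DEL share, split between frameshift (80%) and
    in-frame (20%) events.
    """
    spec.validate()
    rng_ann, rng_meta, rng_counts, rng_classes = _substreams(spec.seed, 4)

    annotations = generate_gene_annotations(spec, rng_ann)
    probs = gene_probabilities(annotations, spec.replication_time_effect)
    genes = annotations["gene"].to_numpy()

    meta_rows = []
    for group in SUBGROUPS:
        for i in range(spec.n_samples.get(group, 0)):
            msi = MsiStatus.MSI_H.value if group == "MSI_H" else MsiStatus.MSS.value
            pole = PoleStatus.EXONUCLEASE_MUTANT.value if group == "POLE" else PoleStatus.WILDTYPE.value
            meta_rows.append(
                (f"{group}_{i:04d}", rng_meta.choice(spec.tumor_types), msi, pole, group)
            )
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "tumor_type", "msi_status", "pole_status", "subgroup"])

    records: list[tuple] = []
    for sample_id, group in zip(metadata["sample_id"], metadata["subgroup"]):
        mean = spec.mean_tmb.get(group, 0.0)
        if mean <= 0:
            continue
        r = spec.tmb_dispersion
        total = int(rng_counts.negative_binomial(r, r / (r + mean)))
        if total == 0:
            continue
        gene_idx = rng_counts.choice(len(genes), size=total, p=probs)
        p_indel = spec.indel_fraction.get(group, 0.0)
        is_indel = rng_classes.random(total) < p_indel
        for gi, indel in zip(gene_idx, is_indel):
            if indel:
                ins = rng_classes.random() < 0.5
                frameshift = rng_classes.random() < 0.8
                cls = ("Frame_Shift_" if frameshift else "In_Frame_") + ("Ins" if ins else "Del")
                vtype = "INS" if ins else "DEL"
            else:
                cls = _SNV_CLASSES[rng_classes.choice(len(_SNV_CLASSES), p=_SNV_WEIGHTS)]
                vtype = "SNV"
            records.append((sample_id, genes[gi], cls, vtype, pd.NA, pd.NA, pd.NA))

    mutations = pd.DataFrame(records, columns=MUTATION_COLUMNS)
    return mutations, metadata, annotations


def generate_variant_calls(
    n_somatic: int,
    n_germline: int,
    purity: float,
    depth_mean: float,
    seed: int,
    pass_fraction: float = 0.7,
    somatic_concentration: float = 500.0,
    germline_hom_fraction: float = 1 / 3,
    indel_fraction: float = 0.15,
) -> pd.DataFrame:
    """Simulate tumor-only variant calls with known somatic/germline truth.

    Somatic allele fractions are Beta-distributed around ``purity/2`` (a
    heterozygous clonal mutation observed at tumor purity); germline calls
    mix heterozygous (~0.5) and homozygous (~1.0) sites.  Observed VAFs add
    binomial read-sampling noise at Poisson depths around ``depth_mean``.
    ``pass_fraction`` of somatic calls carry the PASS caller label; every
    other call is labeled germline_risk, mimicking a caller that flags any
    population-database overlap.
    """
    if not 0.0 < purity <= 1.0:
        raise ValueError("purity must lie in (0,1]")
    if depth_mean < 1:
        raise ValueError("depth_mean must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    n = n_somatic + n_germline
    truth = np.array(["somatic"] * n_somatic + ["germline"] * n_germline)
    mu = purity / 2.0
    true_vaf = np.empty(n)
    true_vaf[:n_somatic] = rng.beta(mu * somatic_concentration, (1 - mu) * somatic_concentration, n_somatic)
    hom = rng.random(n_germline) < germline_hom_fraction
    true_vaf[n_somatic:] = np.where(hom, 1.0, 0.5)

    depth = np.maximum(1, rng.poisson(depth_mean, n))
    alt = rng.binomial(depth, true_vaf)
    vaf = alt / depth

    labels = np.full(n, "germline_risk", dtype=object)
    n_pass = int(round(pass_fraction * n_somatic))
    labels[rng.permutation(n_somatic)[:n_pass]] = "PASS"

    vtype = np.where(rng.random(n) < indel_fraction, np.where(rng.random(n) < 0.5, "INS", "DEL"), "SNV")
    calls = pd.DataFrame(
        {
            "sample_id": "S1",
            "gene": [f"G{i:05d}" for i in rng.integers(0, 5000, n)],
            "variant_type": vtype,
            "filter_label": labels,
            "total_depth": depth,
            "alt_depth": alt,
            "vaf": vaf,
            "in_population_db": False,
            "in_pon": False,
            "is_intronic": False,
            "sift": "unknown",
            "polyphen": "unknown",
            "pole_exonuclease_domain": False,
            "truth": truth,
        }
    )
    return calls


def generate_expression_matrix(
    metadata: pd.DataFrame,
    mutated_samples,
    coupling: float,
    seed: int,
    is_genes=IS_GENES,
    n_background_genes: int = 50,
    base_log2_mean: float = 5.0,
    base_log2_sd: float = 1.0,
) -> pd.DataFrame:
    """Generate a raw genes x samples expression matrix.

    The immunostimulatory genes' log2 expression is shifted upward by
    ``coupling`` in samples belonging to ``mutated_samples``; background
    genes are i.i.d. noise.  Values are returned on the raw scale
    (``2**log2 - 1``), ready for log2(x+1) scoring.
    """
    if len(tuple(is_genes)) == 0:
        raise ValueError("is_genes must be non-empty")
    samples = list(metadata["sample_id"])
    unknown = set(mutated_samples) - set(samples)
    if unknown:
        raise ValueError(f"mutated samples not in metadata: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])

    mut = np.isin(samples, list(mutated_samples))
    genes = list(is_genes) + [f"BG{i:04d}" for i in range(n_background_genes)]
    log2 = rng.normal(base_log2_mean, base_log2_sd, (len(genes), len(samples)))
    log2[: len(tuple(is_genes)), :] += coupling * mut[None, :]
    raw = np.maximum(0.0, 2.0**log2 - 1.0)
    return pd.DataFrame(raw, index=genes, columns=samples)
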