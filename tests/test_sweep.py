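import math

import numpy as np
import pandas as pd
import pytest

from ttnsight.sweep import (
    cds_count_relation,
    correlation_sweep,
    per_stratum_sweep,
    random_geneset_sweep,
)
from ttnsight.synthetic import CohortSpec, generate_mutation_cohort
from ttnsight.tmb import SampleProfiles, profile_samples


def pearson_oracle(x, y):
    """Covariance/SD Pearson rho, coded independently of the sweep."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = math.sqrt(sum((a - mx) ** 2 for a in x))
    sy = math.sqrt(sum((b - my) ** 2 for b in y))
    return cov / (sx * sy)


def _profiles_from_counts(counts: pd.DataFrame, metadata=None) -> SampleProfiles:
    if metadata is None:
        metadata = pd.DataFrame({"sample_id": counts.index, "tumor_type": "COAD",
                                 "msi_status": "MSS", "pole_status": "wildtype"})
    zero = counts * 0
    return SampleProfiles(counts=counts, snv_counts=counts, indel_counts=zero,
                          tmb=counts.sum(axis=1), metadata=metadata.reset_index(drop=True))


class TestCorrelationSweep:
    def test_gene_equal_to_total_has_rho_one(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 50, 20)
        counts = pd.DataFrame({"A": a, "B": 0}, index=[f"S{i}" for i in range(20)])
        counts.index.name = "sample_id"
        sweep = correlation_sweep(_profiles_from_counts(counts))
        assert sweep.set_index("gene").loc["A", "rho"] == pytest.approx(1.0)

    def test_zero_variance_gene_skipped(self):
        counts = pd.DataFrame(
            {"A": [1, 2, 3, 4], "B": [0, 0, 0, 0]}, index=[f"S{i}" for i in range(4)]
        )
        counts.index.name = "sample_id"
        sweep = correlation_sweep(_profiles_from_counts(counts))
        assert "B" not in set(sweep["gene"])

    def test_matches_brute_force_oracle(self, small_cohort):
        _, mutations, metadata, _ = small_cohort
        profiles = profile_samples(mutations, metadata)
        sweep = correlation_sweep(profiles).set_index("gene")
        total = profiles.tmb.to_numpy(float)
        rng = np.random.default_rng(0)
        for gene in rng.choice(sweep.index, 25, replace=False):
            expected = pearson_oracle(profiles.counts[gene].to_list(), list(total))
            assert sweep.loc[gene, "rho"] == pytest.approx(expected, abs=1e-12)

    def test_sample_reordering_invariance(self, small_cohort):
        _, mutations, metadata, _ = small_cohort
        profiles = profile_samples(mutations, metadata)
        shuffled = profile_samples(
            mutations.sample(frac=1.0, random_state=5).reset_index(drop=True),
            metadata.sample(frac=1.0, random_state=6).reset_index(drop=True),
        )
        a = correlation_sweep(profiles).set_index("gene")["rho"]
        b = correlation_sweep(shuffled).set_index("gene")["rho"]
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index(), atol=1e-12)

    def test_too_few_samples_rejected(self):
        counts = pd.DataFrame({"A": [1, 2]}, index=["S0", "S1"])
        counts.index.name = "sample_id"
        with pytest.raises(ValueError):
            correlation_sweep(_profiles_from_counts(counts))

    def test_tracking_gene_ranks_first(self, small_cohort):
        _, mutations, metadata, _ = small_cohort
        profiles = profile_samples(mutations, metadata)
        sweep = correlation_sweep(profiles)
        assert sweep.iloc[0]["gene"] == "TTN"


class TestPerStratumSweep:
    def test_fwer_multiplication_and_cap(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            {"A": rng.integers(0, 30, 30), "B": rng.integers(0, 5, 30)},
            index=[f"S{i}" for i in range(30)],
        )
        counts.index.name = "sample_id"
        meta = pd.DataFrame({"sample_id": counts.index, "tumor_type": ["COAD"] * 15 + ["STAD"] * 15,
                             "msi_status": "MSS", "pole_status": "wildtype"})
        res = per_stratum_sweep(_profiles_from_counts(counts, meta), n_strata_for_fwer=33)
        for sweep in res.values():
            np.testing.assert_allclose(
                sweep["fwer_p"], np.minimum(1.0, sweep["p_value"] * 33), atol=1e-15
            )

    def test_single_stratum_multiplier_one_keeps_raw_p(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame({"A": rng.integers(0, 30, 10)}, index=[f"S{i}" for i in range(10)])
        counts.index.name = "sample_id"
        res = per_stratum_sweep(_profiles_from_counts(counts), n_strata_for_fwer=1)
        sweep = res["COAD"]
        np.testing.assert_allclose(sweep["fwer_p"], sweep["p_value"])

    def test_small_stratum_skipped(self):
        counts = pd.DataFrame({"A": [1, 2, 3, 4, 5]}, index=[f"S{i}" for i in range(5)])
        counts.index.name = "sample_id"
        meta = pd.DataFrame({"sample_id": counts.index,
                             "tumor_type": ["COAD"] * 3 + ["UVM"] * 2,
                             "msi_status": "MSS", "pole_status": "wildtype"})
        res = per_stratum_sweep(_profiles_from_counts(counts, meta))
        assert "UVM" not in res


class TestCdsCountRelation:
    def test_exact_proportionality_gives_rho_one(self):
        ann = pd.DataFrame({"gene": list("ABC"), "cds_length": [1000, 2000, 3000],
                            "gc_fraction": 0.5, "replication_time": 50.0, "is_flags": False})
        counts = pd.Series({"A": 10, "B": 20, "C": 30})
        rho, _ = cds_count_relation(counts, ann)
        assert rho == pytest.approx(1.0)

    def test_synthetic_cohort_strong_relation(self, small_cohort):
        _, mutations, metadata, annotations = small_cohort
        profiles = profile_samples(mutations, metadata)
        rho, p = cds_count_relation(profiles.gene_totals(), annotations)
        assert rho > 0.8 and p < 1e-6

    def test_two_genes_rejected(self):
        ann = pd.DataFrame({"gene": ["A", "B"], "cds_length": [1000, 2000],
                            "gc_fraction": 0.5, "replication_time": 50.0, "is_flags": False})
        with pytest.raises(ValueError):
            cds_count_relation(pd.Series({"A": 1, "B": 2}), ann)


class TestRandomGenesetSweep:
    @pytest.fixture()
    def cohort_profiles(self, small_cohort):
        _, mutations, metadata, _ = small_cohort
        return profile_samples(mutations, metadata)

    def _labels(self, profiles):
        return pd.Series(
            (profiles.metadata["msi_status"] == "MSI_H").astype(int).to_numpy(),
            index=profiles.samples,
        )

    def test_singleton_set_matches_sweep_rho(self, cohort_profiles):
        labels = self._labels(cohort_profiles)
        # force the singleton {TTN} by a size-1 range over a 1-gene universe view
        sweep = correlation_sweep(cohort_profiles).set_index("gene")
        rng_hits = random_geneset_sweep(cohort_profiles, 50, labels, seed=9, set_size_range=(1, 1))
        hit = rng_hits[rng_hits["genes"] == "TTN"]
        if len(hit):
            assert hit.iloc[0]["rho_with_tmb"] == pytest.approx(sweep.loc["TTN", "rho"], abs=1e-12)
        one = rng_hits.iloc[0]
        assert one["rho_with_tmb"] == pytest.approx(
            sweep.loc[one["genes"], "rho"], abs=1e-12
        )

    def test_zero_sets_gives_empty_table(self, cohort_profiles):
        out = random_geneset_sweep(cohort_profiles, 0, self._labels(cohort_profiles), seed=1)
        assert len(out) == 0

    def test_mean_random_pair_rho_below_tracking_gene(self, cohort_profiles):
        labels = self._labels(cohort_profiles)
        sweep = correlation_sweep(cohort_profiles).set_index("gene")
        out = random_geneset_sweep(cohort_profiles, 300, labels, seed=2, set_size_range=(2, 2))
        assert out["rho_with_tmb"].mean() < sweep.loc["TTN", "rho"]

    def test_oversized_sets_rejected(self, cohort_profiles):
        with pytest.raises(ValueError):
            random_geneset_sweep(
                cohort_profiles, 1, self._labels(cohort_profiles), seed=1,
                set_size_range=(2, 10**6),
            )

    def test_deterministic_under_seed(self, cohort_profiles):
        labels = self._labels(cohort_profiles)
        a = random_geneset_sweep(cohort_profiles, 20, labels, seed=5)
        b = random_geneset_sweep(cohort_profiles, 20, labels, seed=5)
        pd.testing.assert_frame_equal(a, b)


def test_tracking_gene_rank_recovery_across_seeds():
    """The burden-tracking gene attains rank 1 by rho in nearly all replicates."""
    wins = 0
    n_rep = 20
    for seed in range(n_rep):
        spec = CohortSpec(
            n_samples={"LGI": 70, "MSI_H": 25, "POLE": 5},
            n_genes=300,
            seed=1000 + seed,
        )
        mutations, metadata, _ = generate_mutation_cohort(spec)
        profiles = profile_samples(mutations, metadata)
        sweep = correlation_sweep(profiles)
        wins += int(sweep.iloc[0]["gene"] == spec.tracking_gene)
    assert wins >= round(0.95 * n_rep)
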