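import pandas as pd
import pytest

from ttnsight.synthetic import CohortSpec, generate_mutation_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed-subgroup cohort shared by read-only tests."""
    spec = CohortSpec(
        n_samples={"LGI": 40, "MSI_H": 15, "POLE": 5},
        n_genes=300,
        seed=1234,
    )
    mutations, metadata, annotations = generate_mutation_cohort(spec)
    return spec, mutations, metadata, annotations


@pytest.fixture()
def toy_mutations():
    """Hand-written 5-record mutation table covering SNV/indel and intron cases."""
    rows = [
        ("S1", "TTN", "Missense", "SNV"),
        ("S1", "TTN", "Silent", "SNV"),
        ("S1", "BRAF", "Frame_Shift_Del", "DEL"),
        ("S1", "TTN", "Intron", "SNV"),
        ("S2", "TP53", "Splice_Site", "SNV"),
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "gene", "variant_classification", "variant_type"])
    for c in ("chrom", "pos", "protein_change"):
        df[c] = pd.NA
    return df


@pytest.fixture()
def toy_metadata():
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "tumor_type": ["COAD", "COAD", "READ"],
            "msi_status": ["MSI_H", "MSS", "MSS"],
            "pole_status": ["wildtype", "wildtype", "exonuclease_mutant"],
        }
    )
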