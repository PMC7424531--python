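"""Synthetic reconstructions of the published validation-cohort summaries.

The original sequencing data are controlled-access; only per-class mutation
counts and cohort composition were published.  These builders reconstruct
mutation tables and metadata with exactly those marginal counts so the
count-based statistics (class percentages, per-sample totals, cohort
fractions) can be exercised.  Everything here is synthetic: sample
assignments, coordinates and any field beyond the published counts are
arbitrary but deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mutation_io import MUTATION_COLUMNS
from .vocab import MsiStatus, PoleStatus

#: Published per-class counts for the 24-sample TTN-panel assay
#: (239 non-intronic somatic alterations).
TTN_PANEL_CLASS_COUNTS: dict[str, int] = {
    "Missense": 156,
    "Silent": 57,
    "Nonsense": 14,
    "Splice_Site": 1,
    "Frame_Shift_Ins": 7,
    "Frame_Shift_Del": 4,
}

#: Published per-class counts for the 382-gene targeted panel
#: (1381 protein-coding-region somatic alterations, RNA class included).
TNGS_CLASS_COUNTS: dict[str, int] = {
    "Missense": 705,
    "Frame_Shift_Del": 257,
    "Silent": 251,
    "Nonsense": 90,
    "Frame_Shift_Ins": 49,
    "Splice_Site": 19,
    "In_Frame_Ins": 4,
    "RNA": 4,
    "In_Frame_Del": 1,
    "Nonstop": 1,
}

_CLASS_TO_TYPE = {
    "Frame_Shift_Ins": "INS",
    "In_Frame_Ins": "INS",
    "Frame_Shift_Del": "DEL",
    "In_Frame_Del": "DEL",
}


def _table_from_counts(class_counts: dict[str, int], gene: str, n_samples: int, prefix: str) -> pd.DataFrame:
    """Expand a class histogram into a mutation table spread over samples round-robin."""
    rows = []
    i = 0
    for cls, count in class_counts.items():
        vtype = _CLASS_TO_TYPE.get(cls, "SNV")
        for _ in range(count):
            rows.append((f"{prefix}{(i % n_samples) + 1:02d}", gene, cls, vtype, pd.NA, pd.NA, pd.NA))
            i += 1
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def ttn_panel_mutations(n_samples: int = 24) -> pd.DataFrame:
    """Synthetic 239-record TTN-panel mutation table matching the published class counts."""
    return _table_from_counts(TTN_PANEL_CLASS_COUNTS, "TTN", n_samples, "AMC")


def tngs_mutations(n_samples: int = 24) -> pd.DataFrame:
    """Synthetic 1381-record targeted-panel table matching the published class counts.

    Gene symbols are placeholders (the target gene is absent from that panel).
    """
    return _table_from_counts(TNGS_CLASS_COUNTS, "PANEL_GENE", n_samples, "AMC")


def amc_cohort_metadata() -> pd.DataFrame:
    """Synthetic 24-sample colorectal validation-cohort metadata.

    Composition matches the published description: 14 MSI-H (3 of them
    mucinous adenocarcinomas), 10 MSS with one POLE-pathogenic case.
    """
    rows = []
    for i in range(1, 25):
        msi = MsiStatus.MSI_H.value if i <= 14 else MsiStatus.MSS.value
        pole = PoleStatus.EXONUCLEASE_MUTANT.value if i == 24 else PoleStatus.WILDTYPE.value
        histology = "mucinous" if i <= 3 else "conventional"
        rows.append((f"AMC{i:02d}", "CRC", msi, pole, histology))
    return pd.DataFrame(rows, columns=["sample_id", "tumor_type", "msi_status", "pole_status", "histology"])


def tcga_crc_metadata() -> pd.DataFrame:
    """Synthetic 556-sample colorectal reference-cohort metadata.

    Composition matches the published marginals: 75 MSI-H, 477 non-MSI,
    4 with unavailable MSI status.
    """
    status = np.repeat(
        [MsiStatus.MSI_H.value, MsiStatus.MSS.value, MsiStatus.UNKNOWN.value], [75, 477, 4]
    )
    return pd.DataFrame(
        {
            "sample_id": [f"TCGA{i:04d}" for i in range(1, 557)],
            "tumor_type": "CRC",
            "msi_status": status,
            "pole_status": PoleStatus.UNKNOWN.value,
        }
    )


def composition_percent(metadata: pd.DataFrame, column: str, value: str, decimals: int = 1) -> float:
    """Percentage of rows with ``metadata[column] == value``, rounded."""
    if len(metadata) == 0:
        raise ValueError("empty metadata")
    return round(100.0 * (metadata[column] == value).mean(), decimals)
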