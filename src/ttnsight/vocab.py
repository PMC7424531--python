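"""Controlled vocabularies for mutation classes, variant types and sample labels.

The mutation-class vocabulary follows the MAF convention (TCGA MC3 dialect),
collapsed to the categories the count-based statistics distinguish.  Anything
outside the known set maps to ``Other`` so that a malformed class never
silently inflates a burden estimate.
"""

from __future__ import annotations

from enum import Enum


class VariantClass(str, Enum):
    """Functional classification of a somatic mutation."""

    MISSENSE = "Missense"
    SILENT = "Silent"
    NONSENSE = "Nonsense"
    SPLICE_SITE = "Splice_Site"
    FRAME_SHIFT_INS = "Frame_Shift_Ins"
    FRAME_SHIFT_DEL = "Frame_Shift_Del"
    IN_FRAME_INS = "In_Frame_Ins"
    IN_FRAME_DEL = "In_Frame_Del"
    NONSTOP = "Nonstop"
    RNA = "RNA"
    INTRON = "Intron"
    OTHER = "Other"


class VariantType(str, Enum):
    """Sequence-level type of a variant."""

    SNV = "SNV"
    INS = "INS"
    DEL = "DEL"


class MsiStatus(str, Enum):
    """Microsatellite-instability phenotype (PCR or reference call)."""

    MSI_H = "MSI_H"
    MSI_L = "MSI_L"
    MSS = "MSS"
    UNKNOWN = "unknown"


class PoleStatus(str, Enum):
    """POLE proofreading (exonuclease) domain mutation status."""

    EXONUCLEASE_MUTANT = "exonuclease_mutant"
    WILDTYPE = "wildtype"
    UNKNOWN = "unknown"


#: TCGA MC3 / vcf2maf Variant_Classification values mapped onto the
#: collapsed vocabulary.  Unlisted values map to Other.
CLASS_SYNONYMS: dict[str, VariantClass] = {
    "Missense_Mutation": VariantClass.MISSENSE,
    "Missense": VariantClass.MISSENSE,
    "Silent": VariantClass.SILENT,
    "Synonymous": VariantClass.SILENT,
    "Nonsense_Mutation": VariantClass.NONSENSE,
    "Nonsense": VariantClass.NONSENSE,
    "Splice_Site": VariantClass.SPLICE_SITE,
    "Frame_Shift_Ins": VariantClass.FRAME_SHIFT_INS,
    "Frame_Shift_Del": VariantClass.FRAME_SHIFT_DEL,
    "In_Frame_Ins": VariantClass.IN_FRAME_INS,
    "In_Frame_Del": VariantClass.IN_FRAME_DEL,
    "Nonstop_Mutation": VariantClass.NONSTOP,
    "Nonstop": VariantClass.NONSTOP,
    "RNA": VariantClass.RNA,
    "Intron": VariantClass.INTRON,
    "Other": VariantClass.OTHER,
}

#: MAF Variant_Type values.  Multi-nucleotide substitutions are substitutions
#: for counting purposes and collapse onto SNV.
TYPE_SYNONYMS: dict[str, VariantType] = {
    "SNP": VariantType.SNV,
    "SNV": VariantType.SNV,
    "DNP": VariantType.SNV,
    "TNP": VariantType.SNV,
    "ONP": VariantType.SNV,
    "INS": VariantType.INS,
    "DEL": VariantType.DEL,
}

#: Classifications implying an insertion / deletion; used to validate the
#: class/type consistency invariant.
INS_CLASSES = {VariantClass.FRAME_SHIFT_INS, VariantClass.IN_FRAME_INS}
DEL_CLASSES = {VariantClass.FRAME_SHIFT_DEL, VariantClass.IN_FRAME_DEL}

#: The six immunostimulatory-signature genes.
IS_GENES = ("IFNG", "IL2", "IL12A", "IL12B", "IL15", "TNF")

#: The five microsatellite PCR loci, in conventional order.
MSI_PCR_LOCI = ("BAT-25", "BAT-26", "D5S346", "D2S123", "D17S250")
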