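"""Published *Paraponera clavata* reference data.

Poneratoxin (δ-paraponeritoxin) precursor segments, the mature isoform
sequences used for identity/similarity comparisons, the reported processing
masses, the published cysteine-scaffold catalogue of predicted toxin-like
peptides, and the full list of published toxin names. These serve as
ground-truth inputs for validation and worked examples; they are data, not
computed results.
"""

from __future__ import annotations

__all__ = [
    "PONERATOXIN_SIGNAL",
    "PONERATOXIN_PROPEPTIDE",
    "PC1E_MATURE_GK",
    "PC1E_MATURE",
    "PC1D_MATURE",
    "PC1E_PRECURSOR",
    "PC1E_OBSERVED_MASS",
    "SCAFFOLD_CATALOG",
    "PUBLISHED_TOXIN_NAMES",
]

#: 24-residue signal peptide of the δ-paraponeritoxin-Pc1e precursor.
PONERATOXIN_SIGNAL = "MRIGKLILISVAIIAIMISDPVKS"

#: 14-residue propeptide between signal peptide and mature toxin.
PONERATOXIN_PROPEPTIDE = "EAVAKPSAEAVSEA"

#: Mature δ-paraponeritoxin-Pc1e as encoded (27 aa): the classic 25-residue
#: poneratoxin with an Ala->Val substitution at mature position 23 and the
#: C-terminal Gly-Lys amidation signal still attached.
PC1E_MATURE_GK = "FLPLLILGSLLMTPPVIQAIHDVQRGK"

#: Mature δ-paraponeritoxin-Pc1e after C-terminal GK cleavage (25 aa),
#: the processing state observed in venom.
PC1E_MATURE = PC1E_MATURE_GK[:-2]

#: Peruvian isoform δ-paraponeritoxin-Pc1d (25 aa); differs from the
#: GK-trimmed Pc1e by the single conservative V->A exchange at position 23.
PC1D_MATURE = "FLPLLILGSLLMTPPVIQAIHDAQR"

#: Full 65-residue precursor (signal + propeptide + mature-with-GK).
PC1E_PRECURSOR = PONERATOXIN_SIGNAL + PONERATOXIN_PROPEPTIDE + PC1E_MATURE_GK

#: MALDI-TOF mass (Da) measured for mature poneratoxin in crude venom.
PC1E_OBSERVED_MASS = 2783.4

#: Published catalogue of predicted toxin-like peptides:
#: (cysteine count, scaffold string, mature length, TPM).
SCAFFOLD_CATALOG: tuple[tuple[int, str, int, float], ...] = (
    (4, "x_8CCx_1Cx_19Cx_5", 37, 772.0),
    (4, "x_1CCx_34Cx_1Cx_1", 41, 18.4),
    (4, "x_5CCx_1Cx_16Cx_14", 40, 16.5),
    (4, "CCx_23Cx_7Cx_6", 40, 13.0),
    (4, "x_14CCx_11Cx_7Cx_33", 69, 10.8),
    (4, "CCx_1Cx_27Cx_12", 44, 7.1),
    (4, "x_3CCx_6Cx_15Cx_9", 37, 2.2),
    (4, "x_6CCx_7Cx_11Cx_8", 36, 0.76),
    (4, "x_8CCx_5Cx_12Cx_6", 35, 0.3),
    (6, "Cx_6Cx_5CCx_4Cx_6Cx_29", 56, 43.8),
    (6, "x_18Cx_6Cx_3CCx_8Cx_24Cx_7", 72, 9.3),
    (6, "x_7Cx_8Cx_21CCx_5Cx_22Cx_20", 89, 5.9),
    (6, "Cx_6Cx_5CCx_4Cx_6Cx_29", 56, 3.9),
    (6, "x_8Cx_6Cx_5CCx_4Cx_6Cx_25", 60, 3.4),
    (6, "x_8Cx_6Cx_5CCx_4Cx_6Cx_7", 42, 2.6),
    (8, "x_14Cx_9Cx_3Cx_5Cx_5CCx_3Cx_4Cx_26", 77, 1.76),
    (10, "x_10Cx_5Cx_4CCx_11Cx_9Cx_28Cx_1Cx_5Cx_6Cx_1", 90, 12.67),
)

#: Every toxin name published for P. clavata under the rational
#: nomenclature (transcriptome top-expressed list and proteome toxin list),
#: spellings preserved verbatim.
PUBLISHED_TOXIN_NAMES: tuple[str, ...] = (
    # transcriptome: top expressed toxin and toxin-like transcripts
    "δ-Paraponeritoxin-Pc1e_1",
    "δ-Paraponeritoxin-Pc1e_2",
    "δ-Paraponeritoxin-Pc1e_3",
    "δ-Paraponeritoxin-Pc1e_4",
    "Phospholipase-A2-1a_1-P-clavata",
    "Translationally-controlled-tumor-protein-1a-P-clavata",
    "Icarapin-1a-P-clavata",
    "Serine-protease-1a-P-clavata",
    "Serine-protease-2a-P-clavata",
    "Arginine-kinase-1a_1-P-clavata",
    "U_1_-Paraponeritoxin-Pc1a",
    "Serine-protease-3a-P-clavata",
    "Serine-protease-4a-P-clavata",
    "Venom-allergen3-1a-P-clavata",
    "Cysteine-rich protein-1a-P-clavata",
    "Serine-protease-1b-P-clavata",
    "Serine-protease-5a-P-clavata",
    "Disintegrin-and-metalloproteinase-domain-containing-protein-1a-P-clavata",
    "Disintegrin-and-metalloproteinase-domain-containing-protein-2a-P-clavata",
    "Lysosomal-aspartic-protease-1a-P-clavata",
    "Defensin-2-like-1a-P-clavata",
    "Serine-protease-inhibitor-1a-P-clavata",
    "Serine-protease-6a-P-clavata",
    "Serine-protease-7a-P-clavata",
    "Serine-protease-8a-P-clavata",
    "Cathepsin-L-1a-P-clavata",
    # proteome: toxins identified by proteomic analysis
    "Hyalyronidase-1a_1-P-clavata",
    "Hyalyronidase-1a_2-P-clavata",
    "Hyalyronidase-1a_3-P-clavata",
    "Hyalyronidase-1a_4-P-clavata",
    "Hyalyronidase-1a_5-P-clavata",
    "Hyalyronidase-1a_6-P-clavata",
    "Hyalyronidase-1a_7-P-clavata",
    "Hyalyronidase-1a_8-P-clavata",
    "Venom-dipeptidyl-peptidase-1a_1-P-clavata",
    "Venom-dipeptidyl-peptidase-1a_2-P-clavata",
    "δ-Paraponeritoxin-Pc1e_5",
    "δ-Paraponeritoxin-Pc1e_6",
    "Phospholipase-A2-1a_2-P-clavata",
    "Venom-allergen3-1b-P-clavata",
    "Carboxypeptidase-Q-1a_1-P-clavata",
    "Carboxypeptidase-Q-1a_2-P-clavata",
    "Arginine-kinase-1a_2-P-clavata",
    "Pancreatic-lipase-1a-P-clavata",
    "Pancreatic-lipase-1b-P-clavata",
    "Matrix-metalloproteinase-14-like-1a-P-clavata",
    "Alaserpin-X5-like-1a-P-clavata",
    "Pancreatic-triacylglycerol-lipase-X1-like-1a-P-clavata",
    "Pancreatic-triacylglycerol-lipase-X1-like-2a-P-clavata",
    "Pancreatic-triacylglycerol-lipase-X1-like-3a-P-clavata",
    "Venom-acid-phosphatase-1a-P-clavata",
    "Iron-zinc-purple-acid phosphatase-like-1a_1-P-clavata",
    "Iron-zinc-purple-acid phosphatase-like-1a_2-P-clavata",
    "Alkaline-phosphatase-1a_1-P-clavata",
    "Alkaline-phosphatase-1a_2-P-clavata",
    "Neprilysin-11-isoform-X2-1a_1-P-clavata",
    "Neprilysin-11--isoform-X2-1a_2-P-clavata",
    "Matrix-metalloproteinase-14-like-2a-P-clavata",
    "Protein-5NUC-1a-P-clavata",
    "Icarapin-1a-P-clavata",
    "Cytosolic-dipeptidase-1a-P-clavata",
    "Phenoloxidase-2-like-1a-P-clavata",
)
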