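"""Published summary counts of the curated osteogenesis imperfecta cohort.

The original 129-patient analyzable cohort (59 Gly-substitution
missense, 70 frameshift/nonsense/splicing) was summarized per phenotype
as a percentage-present within each variation class plus per-class
totals. The 2x2 counts below are reconstructed from those printed
summaries (e.g. bone deformity: 80% of 45 Gly cases present -> 36/9;
58.5% of 53 quantitative cases -> 31/22) and serve as the table-mode
input for reproducing the published association screen without
individual-level data.

Notes on the source summary:

* The blue-sclera row prints a quantitative-class total of 72 although
  that class has only 70 patients and the printed percentage is
  consistent with 70; the count here uses 70.
* The COL1A1/COL1A2 row's printed totals and percentages are mutually
  inconsistent (percentages imply n = 59, total prints 58), so its
  counts are not uniquely recoverable and it is omitted.
"""

from __future__ import annotations

#: phenotype -> (gly_present, gly_absent, quant_present, quant_absent)
PHENOTYPE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "bone_deformity": (36, 9, 31, 22),
    "hypermobile_joints": (10, 2, 3, 0),
    "dense_metaphyseal_bands": (9, 2, 1, 1),
    "vertebral_anomalies": (23, 22, 15, 33),
    "vertebral_fracture": (8, 12, 8, 11),
    "osteopenia": (1, 0, 2, 0),
    "dentinogenesis_imperfecta": (29, 22, 19, 35),
    "blue_sclera": (41, 17, 54, 16),
    "hearing_loss": (7, 43, 10, 44),
    "walking_with_assistance": (9, 20, 0, 42),
    "triangular_face": (8, 23, 7, 35),
    "popcorn_calcification": (3, 9, 0, 2),
}

#: variation class (gly, quantitative) x OI type (I, III, IV); type II excluded
SUBTYPE_COUNTS: tuple[tuple[int, int, int], ...] = ((9, 9, 20), (40, 1, 9))

#: variation class x sex (F, M)
SEX_COUNTS: tuple[tuple[int, int], ...] = ((32, 27), (41, 29))

#: dentinogenesis imperfecta (rows: present/absent) x bone deformity (cols)
COOCCURRENCE_DI_BONE_DEFORMITY: tuple[tuple[int, int], ...] = ((40, 7), (27, 24))

#: dentinogenesis imperfecta (rows: present/absent) x vertebral anomalies (cols)
COOCCURRENCE_DI_VERTEBRAL_ANOMALIES: tuple[tuple[int, int], ...] = ((23, 20), (15, 35))

#: size of the analyzable cohort and its class composition
N_ANALYZABLE = 129
CLASS_COUNTS = {"gly_missense": 59, "quantitative": 70, "other": 26}

#: experimentally confirmed pathogenic genes (network seed set)
SEED_GENES: tuple[str, ...] = (
    "COL1A1", "COL1A2", "BMP1", "CRTAP", "P3H1", "PPIB", "TMEM38B",
    "SERPINH1", "FKBP10", "PLOD2", "IFITM5", "SERPINF1", "WNT1",
    "CREB3L1", "SP7", "SPARC", "MBTPS2", "P4HB", "PLS3", "SEC24D",
)

#: Pfam collagen triple-helix repeat interval on the alpha-1(I) chain
TRIPLE_HELIX_REPEAT = (1079, 1137)
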