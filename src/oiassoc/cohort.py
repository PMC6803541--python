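"""Patient records, variation classification, and contingency-table builders.

A curated brittle-bone-disease (osteogenesis imperfecta) cohort is a
list of :class:`PatientRecord` objects. Each variation is assigned to
one of two analyzable classes: Gly-substitution missenses (qualitative
collagen defects, a glycine of the Gly-Xaa-Yaa repeat replaced) and
the quantitative group (frameshift / nonsense / splicing changes that
reduce the amount of normal type I collagen). Phenotype status is
tri-state — present, absent, or unknown — and unknowns are removed per
phenotype (pairwise deletion), so every tested table can have its own
denominators, exactly as in curated literature cohorts where charts
rarely record every feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import DomainError, HGVSParseError, VocabularyError
from .exact import ContingencyTable

#: The 12 standardized phenotype labels, in reporting order.
PHENOTYPES: tuple[str, ...] = (
    "bone_deformity",
    "hypermobile_joints",
    "dense_metaphyseal_bands",
    "vertebral_anomalies",
    "vertebral_fracture",
    "osteopenia",
    "dentinogenesis_imperfecta",
    "blue_sclera",
    "hearing_loss",
    "walking_with_assistance",
    "triangular_face",
    "popcorn_calcification",
)

OI_TYPES = ("I", "II", "III", "IV", "unknown")
SEXES = ("F", "M", "unknown")
EFFECTS = ("missense", "frameshift", "nonsense", "splicing", "unknown")

#: Effect labels producing a quantitative collagen defect.
QUANTITATIVE_EFFECTS = frozenset({"frameshift", "nonsense", "splicing"})


class VariationClass(Enum):
    GLY_MISSENSE = "gly_missense"
    QUANTITATIVE = "quantitative"
    NON_GLY_MISSENSE = "non_gly_missense"
    UNKNOWN = "unknown"


@dataclass
class PatientRecord:
    """One curated case.

    ``phenotypes`` maps a vocabulary label to True (present), False
    (absent) or None (unknown / not recorded). Labels absent from the
    map are treated as unknown.
    """

    patient_id: str
    gene: str = "unknown"
    hgvs_c: str | None = None
    hgvs_p: str | None = None
    effect: str = "unknown"
    oi_type: str = "unknown"
    sex: str = "unknown"
    phenotypes: dict[str, bool | None] = field(default_factory=dict)
    gly_override: bool | None = None  # curator-supplied Gly-substitution flag
    variation_class: VariationClass | None = None

    def __post_init__(self) -> None:
        if self.oi_type not in OI_TYPES:
            raise DomainError(f"patient {self.patient_id}: invalid oi_type {self.oi_type!r}")
        if self.sex not in SEXES:
            raise DomainError(f"patient {self.patient_id}: invalid sex {self.sex!r}")
        if self.effect not in EFFECTS:
            raise DomainError(f"patient {self.patient_id}: invalid effect {self.effect!r}")
        bad = set(self.phenotypes) - set(PHENOTYPES)
        if bad:
            raise VocabularyError(
                f"patient {self.patient_id}: phenotype labels outside vocabulary: {sorted(bad)}"
            )


def classify_variation(effect: str, hgvs_p: str | None,
                       gly_override: bool | None = None) -> VariationClass:
    """Assign a variation to one of the two analyzable classes.

    Missense changes are split on the reference residue of the protein
    HGVS string: glycine gives GLY_MISSENSE, anything else
    NON_GLY_MISSENSE. Frameshift, nonsense and splicing changes form
    the QUANTITATIVE class regardless of protein notation. A curator
    flag (``gly_override``) substitutes for a missing HGVS string on
    missense records, since literature-curated cases often lack
    machine-readable notation.
    """
    if effect in QUANTITATIVE_EFFECTS:
        return VariationClass.QUANTITATIVE
    if effect == "missense":
        if hgvs_p:
            from .variants import GlySubstitution, parse_protein_hgvs

            parsed = parse_protein_hgvs(hgvs_p)
            if not isinstance(parsed, GlySubstitution):
                raise HGVSParseError(
                    f"effect is missense but {hgvs_p!r} is not a substitution"
                )
            return (VariationClass.GLY_MISSENSE if parsed.is_gly
                    else VariationClass.NON_GLY_MISSENSE)
        if gly_override is not None:
            return (VariationClass.GLY_MISSENSE if gly_override
                    else VariationClass.NON_GLY_MISSENSE)
        return VariationClass.UNKNOWN
    return VariationClass.UNKNOWN


def classify_records(records: list[PatientRecord]) -> list[PatientRecord]:
    """Populate ``variation_class`` on every record, in place."""
    for rec in records:
        rec.variation_class = classify_variation(rec.effect, rec.hgvs_p, rec.gly_override)
    return records


@dataclass
class FilterReport:
    retained: int
    excluded: dict[str, int]  # class name -> count


def filter_analyzable(records: list[PatientRecord]) -> tuple[list[PatientRecord], FilterReport]:
    """Keep only Gly-missense and quantitative cases, preserving order.

    Returns the retained records plus a count report of what was
    excluded by class.
    """
    kept: list[PatientRecord] = []
    excluded: dict[str, int] = {}
    for rec in records:
        cls = rec.variation_class
        if cls is None:
            cls = classify_variation(rec.effect, rec.hgvs_p, rec.gly_override)
            rec.variation_class = cls
        if cls in (VariationClass.GLY_MISSENSE, VariationClass.QUANTITATIVE):
            kept.append(rec)
        else:
            excluded[cls.value] = excluded.get(cls.value, 0) + 1
    return kept, FilterReport(retained=len(kept), excluded=excluded)


def _class_index(rec: PatientRecord) -> int | None:
    if rec.variation_class is VariationClass.GLY_MISSENSE:
        return 0
    if rec.variation_class is VariationClass.QUANTITATIVE:
        return 1
    return None


def build_phenotype_table(records: list[PatientRecord], phenotype: str) -> ContingencyTable:
    """2x2 table of variation class against one phenotype.

    Patients whose status for this phenotype is unknown are dropped for
    this table only (pairwise deletion); other records are unaffected.
    """
    if phenotype not in PHENOTYPES:
        raise VocabularyError(f"unknown phenotype label {phenotype!r}")
    cells = np.zeros((2, 2), dtype=np.int64)
    for rec in records:
        i = _class_index(rec)
        if i is None:
            continue
        status = rec.phenotypes.get(phenotype)
        if status is None:
            continue
        cells[i, 0 if status else 1] += 1
    return ContingencyTable(
        cells,
        row_labels=("gly_missense", "quantitative"),
        col_labels=("present", "absent"),
    )


def build_subtype_table(records: list[PatientRecord]) -> ContingencyTable:
    """2x3 table of variation class against clinical subtypes I / III / IV.

    Type II (perinatal lethal) and untyped patients are excluded: too
    few type II cases survive to be curated for this kind of analysis.
    """
    col_of = {"I": 0, "III": 1, "IV": 2}
    cells = np.zeros((2, 3), dtype=np.int64)
    for rec in records:
        i = _class_index(rec)
        if i is None or rec.oi_type not in col_of:
            continue
        cells[i, col_of[rec.oi_type]] += 1
    return ContingencyTable(
        cells,
        row_labels=("gly_missense", "quantitative"),
        col_labels=("I", "III", "IV"),
    )


def build_gene_table(records: list[PatientRecord]) -> ContingencyTable:
    """2x2 table of variation class against affected gene (COL1A1 / COL1A2)."""
    col_of = {"COL1A1": 0, "COL1A2": 1}
    cells = np.zeros((2, 2), dtype=np.int64)
    for rec in records:
        i = _class_index(rec)
        if i is None or rec.gene not in col_of:
            continue
        cells[i, col_of[rec.gene]] += 1
    return ContingencyTable(
        cells,
        row_labels=("gly_missense", "quantitative"),
        col_labels=("COL1A1", "COL1A2"),
    )


def build_sex_table(records: list[PatientRecord]) -> ContingencyTable:
    """2x2 table of variation class against patient sex."""
    col_of = {"F": 0, "M": 1}
    cells = np.zeros((2, 2), dtype=np.int64)
    for rec in records:
        i = _class_index(rec)
        if i is None or rec.sex not in col_of:
            continue
        cells[i, col_of[rec.sex]] += 1
    return ContingencyTable(
        cells,
        row_labels=("gly_missense", "quantitative"),
        col_labels=("F", "M"),
    )
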