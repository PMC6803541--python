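"""Variant pathogenicity prioritization for the collagen genes.

A multi-stage cascade over annotated missense variants of COL1A1 and
COL1A2:

1. predictor-score thresholds (SIFT, PolyPhen-2 HumVar, CADD, GERP++),
2. novelty against clinical variant catalogues,
3. population allele-frequency absence (gnomAD-style and a second
   population source),
4. residue conservation across an ortholog multiple sequence alignment,
5. mapping into annotated protein regions (the collagen triple-helix
   repeat domain and the lethal clusters S1-S8 of the alpha-2(I)
   chain).

Each variant exits the cascade with the furthest stage it reached and a
final class, so the stage counts are non-increasing along the retained
branch.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoordinateError, DomainError, HGVSParseError

# ---------------------------------------------------------------------------
# protein HGVS parsing

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*", "Sec": "U",
}
_AA3_PATTERN = "|".join(_AA3_TO_1)

_RE_SUB_1 = re.compile(r"^([A-Z])(\d+)([A-Z*])$")
_RE_SUB_3 = re.compile(rf"^({_AA3_PATTERN})(\d+)({_AA3_PATTERN})$")
_RE_NONSUB = re.compile(
    rf"^(?:[A-Z]|{_AA3_PATTERN})\d+.*(fs|del|dup|ins|ext|=)", re.IGNORECASE
)


@dataclass(frozen=True)
class GlySubstitution:
    """A single amino-acid substitution parsed from protein HGVS."""

    ref_residue: str
    position: int
    alt_residue: str

    @property
    def is_gly(self) -> bool:
        return self.ref_residue == "G"


@dataclass(frozen=True)
class NotASubstitution:
    """Typed result for frameshift / nonsense / other non-substitution HGVS."""

    raw: str
    kind: str  # nonsense | frameshift | indel | synonymous | other


def parse_protein_hgvs(hgvs_p: str) -> GlySubstitution | NotASubstitution:
    """Parse ``p.<ref><pos><alt>`` in one- or three-letter code.

    Frameshift, nonsense, indel and synonymous notations return a typed
    :class:`NotASubstitution`; genuinely unparseable strings raise
    :class:`HGVSParseError` naming the offending string.
    """
    if not hgvs_p:
        raise HGVSParseError("empty protein HGVS string")
    body = hgvs_p.strip()
    if body.startswith("p."):
        body = body[2:]
    body = body.strip("()")

    m = _RE_SUB_3.match(body)
    if m:
        ref, pos, alt = _AA3_TO_1[m.group(1)], int(m.group(2)), _AA3_TO_1[m.group(3)]
    else:
        m = _RE_SUB_1.match(body)
        if m:
            ref, pos, alt = m.group(1), int(m.group(2)), m.group(3)
        else:
            m = _RE_NONSUB.match(body)
            if m:
                kind = {"fs": "frameshift", "del": "indel", "dup": "indel",
                        "ins": "indel", "ext": "other", "=": "synonymous"}[m.group(1).lower()]
                return NotASubstitution(hgvs_p, kind)
            raise HGVSParseError(f"cannot parse protein HGVS string {hgvs_p!r}")
    if pos < 1:
        raise HGVSParseError(f"residue positions are 1-based: {hgvs_p!r}")
    if alt in ("*", "X"):
        return NotASubstitution(hgvs_p, "nonsense")
    if alt == ref:
        return NotASubstitution(hgvs_p, "synonymous")
    return GlySubstitution(ref, pos, alt)


# ---------------------------------------------------------------------------
# score filtering


@dataclass(frozen=True)
class FilterThresholds:
    """Predictor-score cutoffs defining "possibly pathogenic".

    Defaults are the strictest settings of the four annotation tools:
    a SIFT score of exactly 0, a PolyPhen-2 HumVar score of exactly 1,
    CADD phred strictly above 30 and GERP++ RS strictly above 5.
    """

    sift_eq: float = 0.0
    polyphen_eq: float = 1.0
    cadd_gt: float = 30.0
    gerp_gt: float = 5.0


@dataclass
class VariantAnnotation:
    """One annotated candidate substitution."""

    gene: str
    hgvs_c: str
    hgvs_p: str
    sift: float | None = None
    polyphen2_hvar: float | None = None
    cadd_phred: float | None = None
    gerp_rs: float | None = None
    af_source1: float | None = None
    af_source2: float | None = None
    known_pathogenic: bool = False


def _missing(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def score_filter_reasons(v: VariantAnnotation,
                         thresholds: FilterThresholds = FilterThresholds()) -> list[str]:
    """Reasons a variant fails the score filter; empty list means pass.

    Exact-value criteria (SIFT, PolyPhen-2) are compared after rounding
    to 3 decimals so that annotation-file float formatting (0.999 vs
    0.9990) cannot flip a call; the CADD and GERP++ bounds are strict.
    """
    reasons: list[str] = []
    for name, value in (("sift", v.sift), ("polyphen2_hvar", v.polyphen2_hvar),
                        ("cadd_phred", v.cadd_phred), ("gerp_rs", v.gerp_rs)):
        if _missing(value):
            reasons.append(f"missing:{name}")
    if reasons:
        return reasons
    if round(v.sift, 3) != round(thresholds.sift_eq, 3):
        reasons.append("sift")
    if round(v.polyphen2_hvar, 3) != round(thresholds.polyphen_eq, 3):
        reasons.append("polyphen2_hvar")
    if not v.cadd_phred > thresholds.cadd_gt:
        reasons.append("cadd")
    if not v.gerp_rs > thresholds.gerp_gt:
        reasons.append("gerp")
    return reasons


def apply_score_filters(variants: list[VariantAnnotation],
                        thresholds: FilterThresholds = FilterThresholds()
                        ) -> tuple[list[VariantAnnotation], list[tuple[VariantAnnotation, list[str]]]]:
    """Partition variants into (passed, failed-with-reasons)."""
    passed, failed = [], []
    for v in variants:
        reasons = score_filter_reasons(v, thresholds)
        if reasons:
            failed.append((v, reasons))
        else:
            passed.append(v)
    return passed, failed


def novelty_and_frequency_check(v: VariantAnnotation) -> str:
    """Classify a variant as ``known``, ``novel_rare`` or ``novel_seen``.

    A variant already reported pathogenic in a clinical catalogue is
    ``known``; an unreported variant absent (or at zero frequency) from
    both population sources is ``novel_rare``; an unreported variant
    with any observed population frequency is ``novel_seen``.
    """
    if v.known_pathogenic:
        return "known"
    for af in (v.af_source1, v.af_source2):
        if not _missing(af) and af > 0:
            return "novel_seen"
    return "novel_rare"


# ---------------------------------------------------------------------------
# conservation


@dataclass
class ConservationResult:
    conserved: bool
    fraction: float
    column: dict[str, str]  # species / record id -> residue at the column


def conservation_check(alignment, position: int, min_fraction: float = 1.0) -> ConservationResult:
    """Test conservation of the human residue at ``position``.

    The human sequence must be the first alignment record; alignment
    columns are located by walking that row and skipping its gaps
    (residue coordinates are 1-based). The site is conserved when the
    fraction of rows carrying the human reference residue at the mapped
    column is at least ``min_fraction`` (default: full identity).
    """
    if len(alignment) == 0:
        raise DomainError("empty alignment")
    if not 0 <= min_fraction <= 1:
        raise DomainError(f"min_fraction must lie in [0, 1], got {min_fraction}")
    human = str(alignment[0].seq)
    col = None
    residue_index = 0
    for j, ch in enumerate(human):
        if ch == "-":
            continue
        residue_index += 1
        if residue_index == position:
            col = j
            break
    if col is None:
        raise CoordinateError(
            f"position {position} beyond human sequence length {residue_index}"
        )
    ref = human[col].upper()
    column = {rec.id: str(rec.seq)[col].upper() for rec in alignment}
    matches = sum(1 for res in column.values() if res == ref)
    fraction = matches / len(alignment)
    return ConservationResult(fraction >= min_fraction, fraction, column)


# ---------------------------------------------------------------------------
# protein regions


@dataclass(frozen=True)
class Region:
    start: int  # 1-based inclusive
    end: int
    label: str
    category: str  # domain | lethal_cluster

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise DomainError(f"region {self.label!r}: start {self.start} > end {self.end}")
        if self.category not in ("domain", "lethal_cluster"):
            raise DomainError(f"region {self.label!r}: unknown category {self.category!r}")


@dataclass
class ProteinRegionMap:
    """Per-gene annotated residue intervals, non-overlapping per category."""

    regions: dict[str, list[Region]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, regs in self.regions.items():
            by_cat: dict[str, list[Region]] = {}
            for r in regs:
                by_cat.setdefault(r.category, []).append(r)
            for cat, group in by_cat.items():
                group = sorted(group, key=lambda r: r.start)
                for a, b in zip(group, group[1:]):
                    if b.start <= a.end:
                        raise DomainError(
                            f"{gene}: overlapping {cat} regions {a.label!r} and {b.label!r}"
                        )


def map_to_regions(gene: str, position: int, regions: ProteinRegionMap) -> list[str]:
    """Labels of all regions of ``gene`` containing ``position`` (inclusive)."""
    if gene not in regions.regions:
        warnings.warn(f"no region annotation for gene {gene}", stacklevel=2)
        return []
    return [r.label for r in regions.regions[gene] if r.start <= position <= r.end]


# ---------------------------------------------------------------------------
# the full cascade


#: Stages in cascade order; each retained variant records the furthest reached.
STAGES = ("scores", "novelty", "frequency", "conservation", "region")


@dataclass
class CandidateRow:
    gene: str
    hgvs_c: str
    hgvs_p: str
    position: int | None
    stage_reached: str
    final_class: str  # candidate_in_region | conserved_no_region | filtered
    reason: str
    conserved_fraction: float | None = None
    regions: tuple[str, ...] = ()


@dataclass
class CandidateReport:
    rows: list[CandidateRow]

    @property
    def stage_counts(self) -> dict[str, int]:
        """Cascade flow counts: score-passers, known, novel-rare, conserved, in-region."""
        rows = self.rows
        passed = [r for r in rows if r.reason != "score_fail" and r.reason != "not_missense"]
        known = [r for r in passed if r.reason == "known_reported"]
        novel = [r for r in passed if r.stage_reached in ("conservation", "region")
                 or r.reason == "not_conserved"]
        conserved = [r for r in rows if r.final_class in ("candidate_in_region",
                                                          "conserved_no_region")]
        in_region = [r for r in rows if r.final_class == "candidate_in_region"]
        return {
            "passed_scores": len(passed),
            "known": len(known),
            "novel_rare": len(novel),
            "conserved": len(conserved),
            "in_region": len(in_region),
        }

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{
                "gene": r.gene, "hgvs_c": r.hgvs_c, "hgvs_p": r.hgvs_p,
                "position": r.position, "stage_reached": r.stage_reached,
                "final_class": r.final_class, "reason": r.reason,
                "conserved_fraction": r.conserved_fraction,
                "regions": ";".join(r.regions),
            } for r in self.rows]
        )


def prioritize_variants(variants: list[VariantAnnotation],
                        thresholds: FilterThresholds = FilterThresholds(),
                        alignments: dict | None = None,
                        regions: ProteinRegionMap | None = None,
                        min_fraction: float = 1.0) -> CandidateReport:
    """Run the full cascade and classify every variant.

    ``alignments`` maps gene symbol to an ortholog multiple sequence
    alignment whose first record is the human sequence. Output rows are
    deterministically ordered by (gene, residue position); classes
    partition the input.
    """
    alignments = alignments or {}
    regions = regions or ProteinRegionMap()
    rows: list[CandidateRow] = []

    for v in variants:
        parsed = None
        position = None
        try:
            parsed = parse_protein_hgvs(v.hgvs_p) if v.hgvs_p else None
        except HGVSParseError as exc:
            raise HGVSParseError(f"{v.gene} {v.hgvs_c}: {exc}") from exc
        if isinstance(parsed, GlySubstitution):
            position = parsed.position

        def finish(stage: str, cls: str, reason: str,
                   fraction: float | None = None, labels: tuple[str, ...] = ()) -> None:
            rows.append(CandidateRow(v.gene, v.hgvs_c, v.hgvs_p, position,
                                     stage, cls, reason, fraction, labels))

        if not isinstance(parsed, GlySubstitution):
            finish("scores", "filtered", "not_missense")
            continue
        if score_filter_reasons(v, thresholds):
            finish("scores", "filtered", "score_fail")
            continue
        status = novelty_and_frequency_check(v)
        if status == "known":
            finish("novelty", "filtered", "known_reported")
            continue
        if status == "novel_seen":
            finish("frequency", "filtered", "population_frequency")
            continue
        if v.gene not in alignments:
            raise DomainError(f"no ortholog alignment provided for gene {v.gene}")
        cons = conservation_check(alignments[v.gene], position, min_fraction)
        if not cons.conserved:
            finish("conservation", "filtered", "not_conserved", cons.fraction)
            continue
        labels = tuple(map_to_regions(v.gene, position, regions))
        if labels:
            finish("region", "candidate_in_region", "candidate", cons.fraction, labels)
        else:
            finish("region", "conserved_no_region", "candidate", cons.fraction)

    rows.sort(key=lambda r: (r.gene, r.position if r.position is not None else -1, r.hgvs_p))
    return CandidateReport(rows)
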