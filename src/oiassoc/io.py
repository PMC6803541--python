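"""Readers and writers for every file dialect the pipeline speaks.

All tabular files are UTF-8, tab-delimited with a mandatory header and
``NA`` for missing values. Pathway collections use the GMT gene-set
format; alignments use FASTA. Write-then-read round-trips reproduce the
in-memory structures exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .cohort import PHENOTYPES, PatientRecord
from .errors import SchemaError
from .exact import ScreenReport
from .network import PathwayCollection
from .variants import ProteinRegionMap, Region, VariantAnnotation

_NA = "NA"

# ---------------------------------------------------------------------------
# cohort


_COHORT_COLUMNS = ["patient_id", "gene", "hgvs_c", "hgvs_p", "effect", "oi_type", "sex"]


def read_cohort(path) -> list[PatientRecord]:
    """Read a patient cohort TSV: fixed columns then one column per phenotype."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _COHORT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: cohort file missing required column {col!r}")
    has_override = "gly_override" in df.columns
    records = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        pid = row["patient_id"]
        if pid in seen:
            raise SchemaError(f"{path} row {idx + 2}: duplicate patient_id {pid!r}")
        seen.add(pid)
        phenotypes: dict[str, bool | None] = {}
        for phen in PHENOTYPES:
            if phen not in df.columns:
                continue
            cell = row[phen].strip()
            if cell in ("", _NA):
                phenotypes[phen] = None
            elif cell in ("1", "0"):
                phenotypes[phen] = cell == "1"
            else:
                raise SchemaError(
                    f"{path} row {idx + 2}: phenotype {phen} must be 1, 0 or NA, got {cell!r}"
                )
        override = None
        if has_override and row["gly_override"].strip() not in ("", _NA):
            override = row["gly_override"].strip() == "1"
        def cell(col: str, absent):
            value = row[col].strip()
            return absent if value in ("", _NA) else value

        records.append(PatientRecord(
            patient_id=pid,
            gene=cell("gene", "unknown"),
            hgvs_c=cell("hgvs_c", None),
            hgvs_p=cell("hgvs_p", None),
            effect=cell("effect", "unknown"),
            oi_type=cell("oi_type", "unknown"),
            sex=cell("sex", "unknown"),
            phenotypes=phenotypes,
            gly_override=override,
        ))
    return records


def write_cohort(records: list[PatientRecord], path) -> None:
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id, "gene": rec.gene,
            "hgvs_c": rec.hgvs_c or _NA, "hgvs_p": rec.hgvs_p or _NA,
            "effect": rec.effect, "oi_type": rec.oi_type, "sex": rec.sex,
        }
        for phen in PHENOTYPES:
            status = rec.phenotypes.get(phen)
            row[phen] = _NA if status is None else ("1" if status else "0")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Read a pre-tabulated association counts TSV (table mode)."""
    df = pd.read_csv(path, sep="\t")
    required = ["phenotype", "gly_present", "gly_absent", "other_present", "other_absent"]
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: counts file missing required column {col!r}")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variants

_VARIANT_COLUMNS = {
    "gene": "gene", "hgvs_c": "hgvs_c", "hgvs_p": "hgvs_p",
    "SIFT_score": "sift", "Polyphen2_HVAR_score": "polyphen2_hvar",
    "CADD_phred": "cadd_phred", "GERP++_RS": "gerp_rs",
    "AF_gnomAD": "af_source1", "AF_CMDB": "af_source2",
    "known_pathogenic": "known_pathogenic",
}


def read_variants(path) -> list[VariantAnnotation]:
    """Read an annotation-style variant TSV (dbNSFP-like column names)."""
    df = pd.read_csv(path, sep="\t", na_values=[_NA])
    for col in _VARIANT_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: variant file missing required column {col!r}")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col, attr in _VARIANT_COLUMNS.items():
            value = row[col]
            if attr == "known_pathogenic":
                value = bool(value) and str(value).lower() not in ("0", "false")
            elif attr in ("gene", "hgvs_c", "hgvs_p"):
                value = str(value)
            else:
                value = None if pd.isna(value) else float(value)
            kwargs[attr] = value
        out.append(VariantAnnotation(**kwargs))
    return out


def write_variants(variants: list[VariantAnnotation], path) -> None:
    rows = []
    for v in variants:
        rows.append({
            "gene": v.gene, "hgvs_c": v.hgvs_c, "hgvs_p": v.hgvs_p,
            "SIFT_score": v.sift, "Polyphen2_HVAR_score": v.polyphen2_hvar,
            "CADD_phred": v.cadd_phred, "GERP++_RS": v.gerp_rs,
            "AF_gnomAD": v.af_source1, "AF_CMDB": v.af_source2,
            "known_pathogenic": int(v.known_pathogenic),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=_NA)


def read_msa(path, fmt: str = "fasta") -> MultipleSeqAlignment:
    return AlignIO.read(path, fmt)


def write_msa(alignment: MultipleSeqAlignment, path, fmt: str = "fasta") -> None:
    AlignIO.write(alignment, path, fmt)


def read_regions(path) -> ProteinRegionMap:
    """Read a region map TSV: gene, start, end, label, category."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "start", "end", "label", "category"):
        if col not in df.columns:
            raise SchemaError(f"{path}: region file missing required column {col!r}")
    regions: dict[str, list[Region]] = {}
    for _, row in df.iterrows():
        regions.setdefault(str(row.gene), []).append(
            Region(int(row.start), int(row.end), str(row.label), str(row.category))
        )
    return ProteinRegionMap(regions)


def write_regions(regions: ProteinRegionMap, path) -> None:
    rows = [{"gene": gene, "start": r.start, "end": r.end,
             "label": r.label, "category": r.category}
            for gene, regs in regions.regions.items() for r in regs]
    pd.DataFrame(rows, columns=["gene", "start", "end", "label", "category"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# network


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("gene_a", "gene_b", "confidence", "relevance"):
        if col not in df.columns:
            raise SchemaError(f"{path}: edge file missing required column {col!r}")
    return df


def write_edges(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines and # comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path, universe=None) -> PathwayCollection:
    """Read a GMT gene-set file.

    Each line is ``name <tab> description <tab> member...``. If no
    explicit ``universe`` is given, the union of all members is used.
    """
    sets: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"{path} line {lineno}: GMT lines need name, "
                              "description and at least one member")
        name, _desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise SchemaError(f"{path} line {lineno}: pathway {name!r} has no members")
        sets[name] = frozenset(members)
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return PathwayCollection(sets, frozenset(universe))


def write_gmt(pathways: PathwayCollection, path) -> None:
    lines = [f"{name}\tna\t" + "\t".join(sorted(members))
             for name, members in sorted(pathways.sets.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(path) -> pd.DataFrame:
    """Read a gene x tissue expression TSV (first column: gene symbols)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if (df.values < 0).any():
        raise SchemaError(f"{path}: expression values must be nonnegative")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


# ---------------------------------------------------------------------------
# reports


def screen_report_frame(report: ScreenReport) -> pd.DataFrame:
    rows = []
    for r in report.rows:
        counts = r.table.counts
        if counts.shape == (2, 2):
            a, b = int(counts[0, 0]), int(counts[0, 1])
            c, d = int(counts[1, 0]), int(counts[1, 1])
            pct_gly = 100 * a / (a + b) if a + b else np.nan
            pct_other = 100 * c / (c + d) if c + d else np.nan
            totals = f"{a + b}/{c + d}"
        else:
            pct_gly = pct_other = np.nan
            totals = "/".join(str(int(x)) for x in r.table.row_sums)
        rows.append({
            "label": r.label, "pct_gly": pct_gly, "pct_other": pct_other,
            "totals": totals, "counts": str(r.table.as_list()),
            "p_value": float(f"{r.result.p_value:.4g}"),
            "significant": r.significant, "degenerate": r.result.degenerate,
            "method": r.result.method,
        })
    return pd.DataFrame(rows)


def write_screen_report(report: ScreenReport, tsv_path, json_path=None) -> None:
    """Write a screen as TSV (4 significant digits) and optionally full-precision JSON."""
    screen_report_frame(report).to_csv(tsv_path, sep="\t", index=False, na_rep=_NA)
    if json_path is not None:
        payload = {
            "alpha": report.alpha,
            "tests": [{
                "label": r.label,
                "counts": r.table.as_list(),
                "row_labels": list(r.table.row_labels),
                "col_labels": list(r.table.col_labels),
                "p_value": r.result.p_value,
                "alternative": r.result.alternative,
                "method": r.result.method,
                "significant": r.significant,
                "degenerate": r.result.degenerate,
            } for r in report.rows],
        }
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
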