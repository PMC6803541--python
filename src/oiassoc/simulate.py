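"""Synthetic-data generators for every stage of the pipeline.

Three generators, all seeded and byte-reproducible:

* :func:`gen_cohort` draws patient records whose class mix, per-class
  phenotype penetrances, missingness and subtype composition default to
  the published cohort's summary statistics, so power and calibration
  studies run under the original study conditions.
* :func:`gen_variant_fixture` constructs a variant table, ortholog
  alignment and region map that push exactly the requested number of
  variants through each stage of the pathogenicity cascade (a
  constructive inverse of the cascade).
* :func:`gen_network_fixture` plants candidate genes in a scored PPI
  network with correlated expression profiles, plus decoys violating
  exactly one selection criterion each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import reference
from .cohort import PHENOTYPES, PatientRecord
from .errors import SpecError
from .network import PathwayCollection, build_ppi_graph
from .variants import ProteinRegionMap, Region, VariantAnnotation

# ---------------------------------------------------------------------------
# cohort generator


def _default_penetrance() -> dict[str, tuple[float, float]]:
    out = {}
    for phen, (a, b, c, d) in reference.PHENOTYPE_COUNTS.items():
        out[phen] = (a / (a + b), c / (c + d))
    return out


def _default_missing() -> dict[str, float]:
    n = reference.N_ANALYZABLE
    return {phen: 1.0 - sum(counts) / n
            for phen, counts in reference.PHENOTYPE_COUNTS.items()}


def _default_subtypes() -> dict[str, dict[str, float]]:
    # per-class categorical over subtype, from the published composition:
    # 38 typed Gly cases split 9/9/20 over I/III/IV, 50 typed quantitative
    # cases split 40/1/9, one type II case, remainder untyped.
    return {
        "gly_missense": {"I": 9 / 59, "III": 9 / 59, "IV": 20 / 59, "unknown": 21 / 59},
        "quantitative": {"I": 40 / 70, "II": 1 / 70, "III": 1 / 70, "IV": 9 / 70,
                         "unknown": 19 / 70},
        "other": {"unknown": 1.0},
    }


@dataclass
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults are the published cohort's composition: 155 curated
    patients mixing 59 Gly-missense, 70 quantitative and 26 other
    records; per-phenotype penetrances and missing rates reproducing
    the published per-class percentages and varying denominators.
    """

    n_patients: int = 155
    class_mix: dict[str, float] = field(default_factory=lambda: {
        "gly_missense": 59 / 155, "quantitative": 70 / 155, "other": 26 / 155,
    })
    penetrance: dict[str, tuple[float, float]] = field(default_factory=_default_penetrance)
    missing_rate: dict[str, float] = field(default_factory=_default_missing)
    subtype_dist: dict[str, dict[str, float]] = field(default_factory=_default_subtypes)
    #: probability of female sex per class (gly, quantitative)
    p_female: tuple[float, float] = (32 / 59, 41 / 70)
    #: probability the variant lies in COL1A1 per class (gly, quantitative)
    p_col1a1: tuple[float, float] = (24 / 59, 68 / 70)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise SpecError("n_patients must be nonnegative")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise SpecError("class mix must sum to 1")
        for phen, (pg, po) in self.penetrance.items():
            if not (0 <= pg <= 1 and 0 <= po <= 1):
                raise SpecError(f"penetrance for {phen} outside [0, 1]")
        for phen, m in self.missing_rate.items():
            if not 0 <= m <= 1:
                raise SpecError(f"missing rate for {phen} outside [0, 1]")
        for cls, dist in self.subtype_dist.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise SpecError(f"subtype distribution for {cls} must sum to 1")


_GLY_ALTS = "DSRCVA"


def gen_cohort(spec: CohortSpec | None = None) -> list[PatientRecord]:
    """Draw a reproducible synthetic patient cohort."""
    spec = spec or CohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    classes = list(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        cls = classes[rng.choice(len(classes), p=probs)]
        subtype_dist = spec.subtype_dist.get(cls, {"unknown": 1.0})
        subtype_labels = list(subtype_dist)
        oi_type = subtype_labels[rng.choice(len(subtype_labels),
                                            p=[subtype_dist[s] for s in subtype_labels])]
        if cls == "gly_missense":
            pf, p1 = spec.p_female[0], spec.p_col1a1[0]
            pos = 3 * int(rng.integers(5, 330)) + 1  # Gly frame of the helix
            alt = _GLY_ALTS[int(rng.integers(len(_GLY_ALTS)))]
            effect, hgvs_p = "missense", f"p.G{pos}{alt}"
        elif cls == "quantitative":
            pf, p1 = spec.p_female[1], spec.p_col1a1[1]
            effect = ("frameshift", "nonsense", "splicing")[int(rng.integers(3))]
            hgvs_p = None
        else:
            pf, p1 = 0.5, 0.5
            if rng.random() < 0.5:
                effect, hgvs_p = "missense", f"p.P{3 * int(rng.integers(5, 330)) + 2}L"
            else:
                effect, hgvs_p = "unknown", None
        gene = "COL1A1" if rng.random() < p1 else "COL1A2"
        sex = "F" if rng.random() < pf else "M"
        phenotypes: dict[str, bool | None] = {}
        for phen in PHENOTYPES:
            if rng.random() < spec.missing_rate.get(phen, 0.0):
                phenotypes[phen] = None
            else:
                pg, po = spec.penetrance.get(phen, (0.5, 0.5))
                p = pg if cls == "gly_missense" else po
                phenotypes[phen] = bool(rng.random() < p)
        records.append(PatientRecord(
            patient_id=f"P{i + 1:04d}", gene=gene, hgvs_c=None, hgvs_p=hgvs_p,
            effect=effect, oi_type=oi_type, sex=sex, phenotypes=phenotypes,
        ))
    return records


def null_cohort_spec(n_patients: int = 200, penetrance: float = 0.5,
                     missing_rate: float = 0.0, seed: int = 0) -> CohortSpec:
    """A cohort with no class-phenotype dependence, for calibration studies."""
    return CohortSpec(
        n_patients=n_patients,
        class_mix={"gly_missense": 0.5, "quantitative": 0.5, "other": 0.0},
        penetrance={p: (penetrance, penetrance) for p in PHENOTYPES},
        missing_rate={p: missing_rate for p in PHENOTYPES},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# variant cascade fixture

_ORTHOLOG_SPECIES = (
    "Homo_sapiens", "Pan_troglodytes", "Papio_anubis", "Macaca_mulatta",
    "Mus_musculus", "Xenopus_laevis", "Caenorhabditis_elegans",
)

_PASSING_SCORES = dict(sift=0.0, polyphen2_hvar=1.0, cadd_phred=33.0, gerp_rs=5.6)


@dataclass
class VariantFixture:
    variants: list[VariantAnnotation]
    alignment: MultipleSeqAlignment
    regions: ProteinRegionMap
    truth: dict


def gen_variant_fixture(stage_counts: tuple[int, int, int, int, int],
                        seed: int = 0, n_score_fail: int = 8,
                        gene: str = "COL1A1") -> VariantFixture:
    """Construct inputs whose cascade flow equals ``stage_counts`` exactly.

    ``stage_counts`` is (score-passers, known, novel-rare, conserved,
    in-region); any score-passer that is neither known nor novel-rare
    is given a nonzero population frequency. The synthetic protein is a
    Gly-Xaa-Yaa repeat so every planted substitution sits on the
    glycine frame.
    """
    n_pass, n_known, n_novel, n_cons, n_region = stage_counts
    if min(stage_counts) < 0:
        raise SpecError("stage counts must be nonnegative")
    if n_known + n_novel > n_pass:
        raise SpecError("known + novel-rare cannot exceed the score-passers")
    if n_cons > n_novel or n_region > n_cons:
        raise SpecError("stage counts must be non-increasing along the cascade branch")

    rng = np.random.default_rng(seed)
    n_seen = n_pass - n_known - n_novel
    # category order fixes the position layout: in-region first so one
    # contiguous interval can serve as the annotated domain
    categories = (["in_region"] * n_region
                  + ["conserved_no_region"] * (n_cons - n_region)
                  + ["not_conserved"] * (n_novel - n_cons)
                  + ["novel_seen"] * n_seen
                  + ["known"] * n_known
                  + ["score_fail"] * n_score_fail)
    positions = [4 + 3 * i for i in range(len(categories))]
    length = (positions[-1] + 2) if positions else 9
    human = ("GPP" * (length // 3 + 1))[:length]

    seqs = {sp: list(human) for sp in _ORTHOLOG_SPECIES}
    variants: list[VariantAnnotation] = []
    truth_rows = []
    for cat, pos in zip(categories, positions):
        alt = _GLY_ALTS[int(rng.integers(len(_GLY_ALTS)))]
        v = VariantAnnotation(
            gene=gene, hgvs_c=f"c.G{3 * pos - 2}A", hgvs_p=f"p.G{pos}{alt}",
            **_PASSING_SCORES,
        )
        if cat == "score_fail":
            v.cadd_phred = float(rng.uniform(5, 30))  # fails the strict bound
        elif cat == "known":
            v.known_pathogenic = True
        elif cat == "novel_seen":
            v.af_source1 = float(rng.uniform(1e-4, 1e-2))
        elif cat == "not_conserved":
            # one non-human ortholog diverges at this column
            sp = _ORTHOLOG_SPECIES[1 + int(rng.integers(len(_ORTHOLOG_SPECIES) - 1))]
            seqs[sp][pos - 1] = "A"
        variants.append(v)
        truth_rows.append({"hgvs_p": v.hgvs_p, "position": pos, "category": cat})

    alignment = MultipleSeqAlignment(
        [SeqRecord(Seq("".join(seqs[sp])), id=sp, description="") for sp in _ORTHOLOG_SPECIES]
    )
    region_list = []
    if n_region:
        region_list.append(Region(positions[0], positions[n_region - 1],
                                  "collagen_triple_helix_repeat", "domain"))
    regions = ProteinRegionMap({gene: region_list})
    truth = {"stage_counts": {"passed_scores": n_pass, "known": n_known,
                              "novel_rare": n_novel, "conserved": n_cons,
                              "in_region": n_region},
             "variants": truth_rows, "seed": seed}
    return VariantFixture(variants, alignment, regions, truth)


# ---------------------------------------------------------------------------
# network fixture


@dataclass
class NetworkSpec:
    """Study conditions for a planted-candidate network fixture."""

    n_seeds: int = 20
    n_planted: int = 3
    n_decoy_low_conf: int = 4
    n_decoy_single_seed: int = 4
    n_decoy_uncorrelated: int = 4
    n_background: int = 10
    n_tissues: int = 30
    noise_scale: float = 0.2
    marker_tissue: str = "transformed_fibroblasts"
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_seeds, self.n_planted, self.n_decoy_low_conf,
                  self.n_decoy_single_seed, self.n_decoy_uncorrelated,
                  self.n_background, self.n_tissues)
        if min(counts) < 0:
            raise SpecError("all fixture counts must be nonnegative")
        if self.n_seeds < 2:
            raise SpecError("need at least two seed genes")
        if self.noise_scale < 0:
            raise SpecError("noise scale must be nonnegative")


@dataclass
class NetworkFixture:
    edges: pd.DataFrame
    seeds: set[str]
    pathways: PathwayCollection
    expression: pd.DataFrame
    truth: dict

    @property
    def graph(self):
        return build_ppi_graph(self.edges)


def gen_network_fixture(spec: NetworkSpec | None = None) -> NetworkFixture:
    """Plant candidates and per-criterion decoys in a scored PPI network.

    Planted genes have >= 2 seed edges at confidence = relevance = 1 and
    an expression profile that is a noisy multiplicative copy of the
    seed median. Each decoy violates exactly one criterion: edge score
    below the bound, a single qualifying seed edge, or an uncorrelated
    expression profile.
    """
    spec = spec or NetworkSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.n_seeds == len(reference.SEED_GENES):
        seeds = list(reference.SEED_GENES)
    else:
        seeds = [f"SEED{i:02d}" for i in range(1, spec.n_seeds + 1)]
    planted = [f"PLANT{i:02d}" for i in range(1, spec.n_planted + 1)]
    d_low = [f"DLOW{i:02d}" for i in range(1, spec.n_decoy_low_conf + 1)]
    d_single = [f"DSINGLE{i:02d}" for i in range(1, spec.n_decoy_single_seed + 1)]
    d_uncorr = [f"DUNCORR{i:02d}" for i in range(1, spec.n_decoy_uncorrelated + 1)]
    background = [f"BG{i:02d}" for i in range(1, spec.n_background + 1)]
    all_genes = seeds + planted + d_low + d_single + d_uncorr + background

    edges = []

    def pick_seeds(k: int) -> list[str]:
        return [seeds[j] for j in rng.choice(len(seeds), size=k, replace=False)]

    for g in planted:
        for s in pick_seeds(int(rng.integers(2, min(4, spec.n_seeds) + 1))):
            edges.append((g, s, 1.0, 1.0))
    for g in d_uncorr:
        for s in pick_seeds(2):
            edges.append((g, s, 1.0, 1.0))
    for g in d_single:
        (s,) = pick_seeds(1)
        edges.append((g, s, 1.0, 1.0))
    for g in d_low:
        for s in pick_seeds(2):
            edges.append((g, s, float(rng.uniform(0.7, 0.99)), 1.0))
    for g in background:
        (s,) = pick_seeds(1)
        edges.append((g, s, float(rng.uniform(0.2, 0.7)), float(rng.uniform(0.2, 0.9))))
    # a few seed-seed interactions, as in any disease-gene subnetwork
    for _ in range(min(10, spec.n_seeds)):
        a, b = pick_seeds(2)
        edges.append((a, b, 1.0, 1.0))
    edge_df = pd.DataFrame(edges, columns=["gene_a", "gene_b", "confidence", "relevance"])

    # pathway collection: seed-heavy sets are significant; background-only
    # sets are not; planted[0] rides along in one significant pathway so the
    # pathway-membership route (set B) is exercised.
    sets: dict[str, frozenset[str]] = {}
    k1 = min(8, spec.n_seeds)
    sets["collagen_biosynthesis"] = frozenset(seeds[:k1])
    members = set(seeds[k1:k1 + min(8, spec.n_seeds - k1)])
    if planted:
        members.add(planted[0])
    if members:
        sets["matrix_assembly"] = frozenset(members)
    if background:
        sets["housekeeping"] = frozenset(background)
    pathways = PathwayCollection(sets, frozenset(all_genes))

    tissues = [spec.marker_tissue] + [f"tissue_{i:02d}" for i in range(1, spec.n_tissues)]
    base = rng.lognormal(mean=1.0, sigma=1.0, size=spec.n_tissues)
    base[0] = base.max() * 2.0  # marker tissue dominates the consensus profile

    def noisy(profile: np.ndarray, sigma: float) -> np.ndarray:
        return profile * rng.lognormal(mean=0.0, sigma=sigma, size=len(profile))

    expr_rows = {}
    for s in seeds:
        expr_rows[s] = noisy(base, 0.3)
    consensus = np.median(np.array([expr_rows[s] for s in seeds]), axis=0)
    for g in planted + d_single + d_low:
        expr_rows[g] = noisy(consensus, spec.noise_scale)
    for g in d_uncorr + background:
        expr_rows[g] = rng.lognormal(mean=1.0, sigma=1.0, size=spec.n_tissues)
    expr = pd.DataFrame.from_dict(expr_rows, orient="index", columns=tissues)
    expr.index.name = "gene"

    truth = {
        "planted": planted,
        "decoys": {"low_confidence": d_low, "single_seed": d_single,
                   "uncorrelated_expression": d_uncorr},
        "background": background,
        "marker_tissue": spec.marker_tissue,
        "seed": spec.seed,
    }
    return NetworkFixture(edge_df, set(seeds), pathways, expr, truth)
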