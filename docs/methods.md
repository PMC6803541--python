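# Methods

## Statistical model

All association questions are posed as independence tests on
contingency tables with both margins treated as fixed, so the null
distribution of any cell is hypergeometric and p-values are exact
(no asymptotic approximation — appropriate for a 129-patient rare-disease
cohort with several sparse phenotypes).

**Hypergeometric core.** `log_hypergeom_pmf` evaluates the mass
function from a growable table of log-factorials, entirely in log
space; tail and two-sided sums are accumulated with log-sum-exp and the
final p is clipped to [0, 1]. This keeps tables such as the
walking-with-assistance row (a zero cell, p ≈ 1.3e-4) and the subtype
2×3 test (p ≈ 1.5e-7) accurate to full double precision.

**Two-sided convention.** The two-sided p-value is the total
probability of all tables, with the observed margins, whose probability
does not exceed the observed table's (minimum-likelihood convention).
Probabilities within a relative tolerance of 1e-7 of the observed one
count as ties. This is the convention of R's `fisher.test`, which is
what published genotype–phenotype screens in this field report, so
printed p-values are reproduced digit for digit. One-sided tests sum
the appropriate tail of the top-left cell.

**r×c enumeration.** The general test enumerates every table with the
observed margins by recursive row-major cell assignment; each free cell
ranges between the bounds implied by its remaining row and column
totals, and the last row/column are forced. The enumeration is
deterministic and exact; a configurable bound on the table total
(default 500) guards against combinatorial blow-up, raising a resource
error rather than silently degrading. For 2×2 inputs it agrees with the
dedicated 2×2 route to 1e-12 (tested), giving two independent
implementations of the same statistic.

**Degenerate tables** (any zero margin) are reported with p = 1 and an
explicit flag; the screen never drops them silently. No
multiple-testing correction is applied by default, mirroring standard
practice for small curated screens at α = 0.05; a Benjamini–Hochberg
helper is provided as a clearly optional extension.

## Cohort model

Patient phenotype status is tri-state (present / absent / unknown) and
every per-phenotype table uses pairwise deletion: patients with
unrecorded status are excluded from that table only. This reproduces
the varying denominators of literature-curated cohorts, where charts
rarely record all 12 standardized phenotypes. Variation classes:
missense with a glycine reference residue (parsed from protein HGVS, or
a curator-supplied flag when only free text exists) versus
frameshift/nonsense/splicing; all other records are excluded from the
association stage. Clinical subtype II (perinatal lethal) is excluded
from the subtype test — too few such cases survive to be curated.

The reconstructed published counts in `oiassoc.reference` resolve two
internal inconsistencies of the printed summary: the blue-sclera
quantitative-class total (printed 72, taken as 70, consistent with the
class size and the printed percentage), and the affected-gene row,
whose totals and percentages cannot both be right and which is
therefore omitted from the reconstruction.

## Variant cascade

Stages run in a fixed order — predictor scores, catalogue novelty,
population frequency, conservation, region mapping — and each variant
records the furthest stage reached plus a final class
(`candidate_in_region`, `conserved_no_region`, or `filtered` with a
reason), so the classes partition the input and stage counts are
non-increasing along the retained branch.

Numerical choices: the SIFT/PolyPhen equality criteria are compared
after rounding both sides to 3 decimals, so annotation-file float
formatting cannot flip a call; the CADD (> 30) and GERP++ (> 5) bounds
are strict, exactly as the annotation tools' own cutoffs state them.
"Highly conserved" is not standardized; the default is the strictest
reading — the human reference residue identical across all aligned
species (min_fraction = 1.0, configurable) at the single aligned
column, with the human sequence as the mandatory first alignment record
and gap-aware 1-based coordinate mapping. The lethal clusters S1–S8 of
the α2(I) chain have no published residue coordinates (figures show
them graphically), so they are required configuration input; tests use
a synthetic stand-in interval and assert only the containment of the
two reported residues (778, 781).

## Network prioritizer

Partners are non-seed genes with at least one edge meeting both score
bounds (defaults: confidence = relevance = 1.0, the maximum). Set A
keeps partners with ≥ 2 distinct seed neighbors; set B keeps partners
belonging to a pathway whose seed enrichment is significant at
α = 0.05, where enrichment is an upper-tail hypergeometric with the
pathway collection's declared universe as background (the urn a
gene-set tool would use, not the PPI node set). "Similar tissue
expression pattern" is operationalized as two conditions: Spearman
rank correlation ≥ 0.5 against the element-wise median profile of the
seeds, and expression in every designated marker tissue (default:
transformed fibroblasts, the collagen-secreting cell type) above the
candidate's own median across tissues. Both thresholds are
configurable; ranking ties break lexicographically by gene symbol for
reproducibility.

## Synthetic data: what it emulates and what it does not

`gen_cohort` defaults to the published study conditions: 155 patients
mixing 59/70/26 across the classes, per-phenotype penetrance pairs and
missing rates that reproduce the published per-class percentages and
denominators, and the published subtype/sex/gene composition. Patients
are drawn i.i.d.; the generator does not model within-family
correlation, recurrent hotspot mutations, or curation bias, so passing
tests show the statistical machinery is calibrated and powered under
the stated composition — not that any particular biological association
is real. Measured under these defaults, the screen flags walking with
assistance, the subtype contrast and the affected gene in > 90% of
replicates, while bone deformity and dentinogenesis imperfecta (whose
published p-values sit just below 0.05) are flagged in roughly half —
the published effect sizes simply do not support more power at n = 129,
and the tests assert that computed reality.

`gen_variant_fixture` is a constructive inverse of the cascade: given
target stage counts it plants exactly that many variants per branch
(scores failed via an out-of-bounds CADD value; known via the catalogue
flag; observed-frequency via a nonzero allele frequency; conservation
broken by mutating one non-human ortholog at the site's column; region
membership via one contiguous domain interval). The synthetic protein
is a Gly-Pro-Pro repeat, so every planted substitution sits on the
glycine frame of a collagen helix.

`gen_network_fixture` plants candidates with ≥ 2 maximum-score seed
edges and expression drawn as a multiplicative log-normal copy
(σ = 0.2 by default) of the seed median profile — the simplest noise
model that preserves nonnegativity and rank structure — plus decoys
violating exactly one criterion each (sub-maximal edge score, single
seed neighbor, or an independent expression profile). Planted recovery
therefore measures the flow's selectivity, not performance on real
interactome data, whose score distributions and degree structure are
far more heterogeneous.

## Problem sizes and tolerances

Deterministic checks (published-table p-values, region mapping) are
exact to the printed precision. Stochastic checks use: 500 null
cohorts of n = 200 for type-I calibration (realized rate ≈ 0.047,
slightly conservative, as expected of exact tests at finite n); 100
network fixtures for planted recovery (≥ 95% required; observed
97–100% across seeds); 200,000 permutation draws for the Monte-Carlo
cross-check of the two-sided p (agreement within 3 standard errors);
and 200 random tables for the 2×2 versus r×c route comparison
(tolerance 1e-12).

## Known limitations

* The exact r×c test is enumeration-only; no Monte-Carlo fallback for
  large tables is provided (the bound raises instead).
* HGVS parsing covers substitutions and recognizes (without modelling)
  frameshift/nonsense/indel/synonymous notation; complex alleles are
  out of scope.
* The enrichment background must be declared; GMT files carry no
  universe, and the CLI falls back to the union of pathway members,
  seeds, graph nodes and expression genes.
* Expression similarity is a global rank correlation; it does not model
  tissue-specific co-regulation or batch structure in real expression
  compendia.
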