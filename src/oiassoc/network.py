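"""Guilt-by-association candidate-gene prioritization.

Starting from a set of seed genes with confirmed pathogenic status, the
flow selects high-confidence interaction partners from a scored PPI
network, keeps partners interacting with at least two seeds (set A),
runs a self-contained hypergeometric gene-set enrichment of the seeds
over a pathway collection and keeps partners belonging to a significant
pathway (set B), and finally filters the union A ∪ B on tissue
expression: a candidate must rank-correlate with the element-wise
median expression profile of the seeds and be highly expressed in the
designated marker tissues (for collagenopathies, transformed
fibroblasts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .errors import DomainError
from .exact import log_hypergeom_pmf, _logsumexp


# ---------------------------------------------------------------------------
# domain types


def build_ppi_graph(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected PPI graph from an edge table.

    Expects columns gene_a, gene_b, confidence, relevance. Self-loops
    are dropped; duplicate edges are merged keeping the maximum of each
    score.
    """
    required = {"gene_a", "gene_b", "confidence", "relevance"}
    missing = required - set(edges.columns)
    if missing:
        raise DomainError(f"edge table missing columns: {sorted(missing)}")
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        conf, rel = float(row.confidence), float(row.relevance)
        if not (0 <= conf <= 1 and 0 <= rel <= 1):
            raise DomainError(f"edge {a}-{b}: scores must lie in [0, 1]")
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            g[a][b]["relevance"] = max(g[a][b]["relevance"], rel)
        else:
            g.add_edge(a, b, confidence=conf, relevance=rel)
    return g


@dataclass
class PathwayCollection:
    """Named gene sets over a declared background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        self.universe = frozenset(self.universe)
        if not self.universe:
            raise DomainError("pathway universe is empty")
        for name, members in self.sets.items():
            if not members:
                raise DomainError(f"pathway {name!r} is empty")
            stray = members - self.universe
            if stray:
                raise DomainError(
                    f"pathway {name!r} has members outside the universe: {sorted(stray)[:5]}"
                )


# ---------------------------------------------------------------------------
# partner selection


def select_partners(graph: nx.Graph, seeds: set[str],
                    min_conf: float = 1.0, min_rel: float = 1.0) -> dict[str, set[str]]:
    """Non-seed genes with at least one qualifying edge to a seed.

    An edge qualifies when its confidence and relevance both meet the
    bounds (defaults: the maximum score 1.0 for both, keeping only the
    most reliable interactions). Returns partner -> set of qualifying
    seed neighbors.
    """
    if not seeds:
        raise DomainError("seed set is empty")
    if not (0 <= min_conf <= 1 and 0 <= min_rel <= 1):
        raise DomainError("score bounds must lie in [0, 1]")
    seeds = set(seeds)
    partners: dict[str, set[str]] = {}
    for s in seeds & set(graph.nodes):
        for nbr, attrs in graph[s].items():
            if nbr in seeds:
                continue
            if attrs["confidence"] >= min_conf and attrs["relevance"] >= min_rel:
                partners.setdefault(nbr, set()).add(s)
    return partners


def set_a(partner_map: dict[str, set[str]], min_seed_degree: int = 2) -> set[str]:
    """Partners interacting with at least ``min_seed_degree`` distinct seeds."""
    if min_seed_degree < 1:
        raise DomainError("min_seed_degree must be >= 1")
    return {g for g, ss in partner_map.items() if len(ss) >= min_seed_degree}


# ---------------------------------------------------------------------------
# pathway enrichment


def hypergeometric_enrichment(seeds: set[str], pathways: PathwayCollection,
                              alpha: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of the seeds in each pathway.

    For a pathway of size K in a universe of N genes and a seed list of
    size n (restricted to the universe; offenders are dropped with a
    warning), the p-value is P(X >= k) for the observed overlap k,
    computed by an explicit tail sum of the hypergeometric mass.
    P-values are uncorrected, mirroring common enrichment practice for
    small curated seed sets; rows are flagged significant at ``alpha``.
    """
    stray = set(seeds) - pathways.universe
    if stray:
        warnings.warn(
            f"{len(stray)} seed gene(s) outside the pathway universe dropped: "
            f"{sorted(stray)[:5]}", stacklevel=2,
        )
    inside = set(seeds) & pathways.universe
    N = len(pathways.universe)
    n = len(inside)
    records = []
    for name, members in sorted(pathways.sets.items()):
        K = len(members)
        k = len(members & inside)
        lo = max(0, n + K - N)
        hi = min(n, K)
        if k <= lo:
            p = 1.0
        else:
            tail = [log_hypergeom_pmf(i, K, n, N) for i in range(k, hi + 1)]
            p = min(1.0, float(np.exp(_logsumexp(np.array(tail)))))
        records.append({"pathway": name, "size": K, "overlap": k,
                        "p_value": p, "significant": p < alpha})
    return pd.DataFrame(records)


def set_b(partner_map: dict[str, set[str]], pathways: PathwayCollection,
          enrichment: pd.DataFrame) -> set[str]:
    """Partners that belong to at least one significant pathway."""
    significant = set(enrichment.loc[enrichment["significant"], "pathway"])
    keep: set[str] = set()
    for name in significant:
        keep |= pathways.sets[name] & set(partner_map)
    return keep


# ---------------------------------------------------------------------------
# expression filtering


def expression_filter(candidates: set[str], seeds: set[str], expr: pd.DataFrame,
                      marker_tissues: tuple[str, ...], rho_min: float = 0.5
                      ) -> tuple[set[str], pd.DataFrame]:
    """Keep candidates whose tissue profile looks like the seed consensus.

    A candidate is kept when (a) the Spearman rank correlation between
    its profile and the element-wise median profile of the seeds is at
    least ``rho_min``, and (b) its expression in every marker tissue
    exceeds its own median across tissues. Candidates missing from the
    matrix are dropped with a warning, never silently.
    """
    seeds_in = [s for s in sorted(seeds) if s in expr.index]
    if len(seeds_in) < 2:
        raise DomainError("need at least two seed genes present in the expression matrix")
    for t in marker_tissues:
        if t not in expr.columns:
            raise DomainError(f"marker tissue {t!r} not in expression matrix")
    if (expr.values < 0).any():
        raise DomainError("expression values must be nonnegative")

    consensus = expr.loc[seeds_in].median(axis=0)
    kept: set[str] = set()
    records = []
    for g in sorted(candidates):
        if g not in expr.index:
            warnings.warn(f"candidate {g} absent from expression matrix; dropped",
                          stacklevel=2)
            continue
        profile = expr.loc[g]
        rho = float(spearmanr(profile.values, consensus.values).statistic)
        own_median = float(profile.median())
        ratios = {t: (float(profile[t]) / own_median if own_median > 0 else np.inf)
                  for t in marker_tissues}
        marker_ok = all(float(profile[t]) > own_median for t in marker_tissues)
        ok = rho >= rho_min and marker_ok
        if ok:
            kept.add(g)
        records.append({"gene": g, "rho": rho, "marker_ok": marker_ok, "kept": ok,
                        **{f"ratio_{t}": r for t, r in ratios.items()}})
    return kept, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# full flow


@dataclass(frozen=True)
class NetworkConfig:
    min_conf: float = 1.0
    min_rel: float = 1.0
    min_seed_degree: int = 2
    alpha: float = 0.05
    rho_min: float = 0.5
    marker_tissues: tuple[str, ...] = ("transformed_fibroblasts",)


@dataclass
class CandidateGeneReport:
    """Result of the full prioritization flow, with per-gene provenance."""

    table: pd.DataFrame  # one row per candidate surviving expression filtering
    partners: dict[str, set[str]]
    a: set[str]
    b: set[str]
    enrichment: pd.DataFrame
    expression_detail: pd.DataFrame

    @property
    def final(self) -> list[str]:
        return list(self.table["gene"])


def prioritize_genes(graph: nx.Graph, seeds: set[str], pathways: PathwayCollection,
                     expr: pd.DataFrame, config: NetworkConfig = NetworkConfig()
                     ) -> CandidateGeneReport:
    """Run the full network flow: partners -> A ∪ B -> expression filter.

    The report is ordered by (descending seed degree, descending rank
    correlation, gene symbol) so repeated runs are reproducible.
    """
    partners = select_partners(graph, seeds, config.min_conf, config.min_rel)
    a = set_a(partners, config.min_seed_degree)
    enrichment = hypergeometric_enrichment(seeds, pathways, config.alpha)
    b = set_b(partners, pathways, enrichment)
    union = a | b
    if not union:
        empty = pd.DataFrame(columns=["gene", "seed_degree", "seeds", "in_set_a",
                                      "in_set_b", "rho"])
        return CandidateGeneReport(empty, partners, a, b, enrichment,
                                   pd.DataFrame(columns=["gene", "rho", "kept"]))
    kept, detail = expression_filter(union, seeds, expr, config.marker_tissues,
                                     config.rho_min)
    rho_of = dict(zip(detail["gene"], detail["rho"])) if len(detail) else {}
    rows = []
    for g in sorted(kept):
        rows.append({
            "gene": g,
            "seed_degree": len(partners.get(g, ())),
            "seeds": ";".join(sorted(partners.get(g, ()))),
            "in_set_a": g in a,
            "in_set_b": g in b,
            "rho": rho_of.get(g, np.nan),
        })
    table = pd.DataFrame(rows, columns=["gene", "seed_degree", "seeds",
                                        "in_set_a", "in_set_b", "rho"])
    if len(table):
        table = table.sort_values(
            by=["seed_degree", "rho", "gene"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return CandidateGeneReport(table, partners, a, b, enrichment, detail)
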