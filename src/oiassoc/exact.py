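"""Exact inference on contingency tables.

The statistical core of the package: a log-space hypergeometric mass
function, Fisher's exact test for 2x2 tables (two-sided and one-sided),
and an exact test for general r x c tables by complete enumeration of
all tables with the observed margins.

The two-sided p-value follows the minimum-likelihood convention: it is
the total null probability of every table (with the same margins) whose
probability does not exceed that of the observed table, up to a small
relative tolerance that absorbs floating-point noise. This is the
convention used by the standard R ``fisher.test`` implementation, so
p-values printed by mainstream genotype-phenotype studies are
reproduced digit for digit.

All probabilities are accumulated in log space (streaming logaddexp)
and the final p-value is clipped to [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, EnumerationBoundError, VocabularyError

# Relative tolerance when comparing table probabilities to the observed
# one; absorbs round-off so ties are counted as "no more probable".
REL_TOL = 1e-7
_LOG_TIE = math.log1p(REL_TOL)

# ---------------------------------------------------------------------------
# log-factorial table


class _LogFactorial:
    """Growable table of log k! values, shared by every test in a process."""

    def __init__(self) -> None:
        self._table = np.zeros(2, dtype=float)

    def _grow(self, n: int) -> None:
        old = self._table
        start = len(old)
        size = max(n + 1, 2 * start)
        new = np.empty(size, dtype=float)
        new[:start] = old
        new[start:] = np.log(np.arange(start, size, dtype=float))
        np.cumsum(new[start - 1:], out=new[start - 1:])
        self._table = new

    def __call__(self, n: int) -> float:
        if n < 0:
            raise DomainError(f"log-factorial of negative value {n}")
        if n >= len(self._table):
            self._grow(n)
        return float(self._table[n])


_logfact = _LogFactorial()


def log_hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """Log of the hypergeometric mass P(X = k).

    X counts successes in ``n`` draws without replacement from a
    population of ``N`` items of which ``K`` are successes.

    Raises
    ------
    DomainError
        If the parameters are inconsistent or ``k`` lies outside the
        support ``[max(0, n + K - N), min(n, K)]``.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DomainError(f"invalid hypergeometric parameters K={K}, n={n}, N={N}")
    lo, hi = max(0, n + K - N), min(n, K)
    if not lo <= k <= hi:
        raise DomainError(f"k={k} outside hypergeometric support [{lo}, {hi}]")
    lf = _logfact
    return (
        lf(K) - lf(k) - lf(K - k)
        + lf(N - K) - lf(n - k) - lf(N - K - n + k)
        - (lf(N) - lf(n) - lf(N - n))
    )


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ContingencyTable:
    """An r x c table of nonnegative integer counts with axis labels.

    Margins are always derived from ``counts``, never stored.
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise DomainError("contingency table must be two-dimensional")
        if (self.counts < 0).any():
            raise DomainError("contingency table entries must be nonnegative")
        r, c = self.counts.shape
        if not self.row_labels:
            self.row_labels = tuple(f"row{i}" for i in range(r))
        if not self.col_labels:
            self.col_labels = tuple(f"col{j}" for j in range(c))

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def degenerate(self) -> bool:
        """True when any row or column margin is zero (test undefined)."""
        return bool((self.row_sums == 0).any() or (self.col_sums == 0).any())

    def as_list(self) -> list[list[int]]:
        return self.counts.tolist()


@dataclass
class TestResult:
    """Outcome of one exact test."""

    p_value: float
    alternative: str  # two_sided | greater | less
    method: str  # exact_2x2 | exact_rxc_enumeration
    tables_enumerated: int
    degenerate: bool = False


@dataclass
class ScreenRow:
    """One line of a cohort-wide association screen."""

    label: str
    table: ContingencyTable
    result: TestResult
    significant: bool


@dataclass
class ScreenReport:
    """All tests run over a cohort, with the significance level used."""

    rows: list[ScreenRow]
    alpha: float

    def significant_labels(self) -> list[str]:
        return [r.label for r in self.rows if r.significant]

    def p_values(self) -> dict[str, float]:
        return {r.label: r.result.p_value for r in self.rows}


# ---------------------------------------------------------------------------
# 2x2 exact test


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    return ContingencyTable(np.asarray(table))


def fisher_2x2(table, alternative: str = "two_sided") -> TestResult:
    """Fisher's exact test on a 2x2 table.

    ``alternative`` is ``two_sided`` (minimum-likelihood convention),
    ``greater`` (enrichment of the top-left cell) or ``less``. A table
    with a zero margin is flagged degenerate and returns p = 1.
    """
    t = _as_table(table)
    if t.counts.shape != (2, 2):
        raise DomainError(f"fisher_2x2 requires a 2x2 table, got {t.counts.shape}")
    if alternative not in ("two_sided", "greater", "less"):
        raise DomainError(f"unknown alternative {alternative!r}")
    if t.degenerate:
        return TestResult(1.0, alternative, "exact_2x2", 1, degenerate=True)

    a = int(t.counts[0, 0])
    K = int(t.row_sums[0])  # first row total
    n = int(t.col_sums[0])  # first column total
    N = t.total
    lo, hi = max(0, n + K - N), min(n, K)
    ks = np.arange(lo, hi + 1)
    logp = np.array([log_hypergeom_pmf(int(k), K, n, N) for k in ks])
    log_obs = logp[a - lo]

    if alternative == "two_sided":
        mask = logp <= log_obs + _LOG_TIE
    elif alternative == "greater":
        mask = ks >= a
    else:
        mask = ks <= a
    p = float(np.exp(_logsumexp(logp[mask])))
    return TestResult(min(max(p, 0.0), 1.0), alternative, "exact_2x2", len(ks))


def _logsumexp(values: np.ndarray) -> float:
    if len(values) == 0:
        return -np.inf
    m = float(np.max(values))
    return m + math.log(float(np.sum(np.exp(values - m))))


# ---------------------------------------------------------------------------
# r x c exact test by complete enumeration


def fisher_rxc(table, max_total: int = 500) -> TestResult:
    """Exact test on an r x c table by complete enumeration.

    Every table with the observed margins is generated by recursive
    row-major cell assignment with feasibility pruning; the two-sided
    p-value is the total probability of tables no more probable than
    the observed one. Agrees with :func:`fisher_2x2` on 2x2 inputs.
    """
    t = _as_table(table)
    r, c = t.counts.shape
    if r < 2 or c < 2:
        raise DomainError("exact r x c test requires at least a 2x2 table")
    if t.degenerate:
        return TestResult(1.0, "two_sided", "exact_rxc_enumeration", 1, degenerate=True)
    N = t.total
    if N > max_total:
        raise EnumerationBoundError(
            f"table total {N} exceeds enumeration bound {max_total}; "
            "a Monte-Carlo p-value mode would be required for tables this large"
        )

    lf = _logfact
    row_sums = [int(x) for x in t.row_sums]
    col_sums = [int(x) for x in t.col_sums]
    # log P(table) = sum(log r_i!) + sum(log c_j!) - log N! - sum(log n_ij!)
    log_const = sum(lf(x) for x in row_sums) + sum(lf(x) for x in col_sums) - lf(N)
    log_obs = log_const - sum(lf(int(x)) for x in t.counts.ravel())

    tie = log_obs + _LOG_TIE
    acc = -np.inf  # running log-sum of qualifying table probabilities
    count = 0

    col_rem = col_sums[:]

    def recurse(row: int, neg_lf_cells: float) -> None:
        nonlocal acc, count
        if row == r - 1:
            # last row fully determined by remaining column margins
            logp = log_const + neg_lf_cells - sum(lf(x) for x in col_rem)
            count += 1
            if logp <= tie:
                nonlocal_acc_update(logp)
            return
        fill_row(row, 0, row_sums[row], neg_lf_cells)

    def nonlocal_acc_update(logp: float) -> None:
        nonlocal acc
        acc = np.logaddexp(acc, logp)

    def fill_row(row: int, col: int, rem: int, neg_lf_cells: float) -> None:
        if col == c - 1:
            # last cell of the row is forced
            if rem <= col_rem[col]:
                col_rem[col] -= rem
                recurse(row + 1, neg_lf_cells - lf(rem))
                col_rem[col] += rem
            return
        tail_capacity = sum(col_rem[col + 1:])
        lo = max(0, rem - tail_capacity)
        hi = min(rem, col_rem[col])
        for x in range(lo, hi + 1):
            col_rem[col] -= x
            fill_row(row, col + 1, rem - x, neg_lf_cells - lf(x))
            col_rem[col] += x

    recurse(0, 0.0)
    p = float(np.exp(acc))
    return TestResult(min(max(p, 0.0), 1.0), "two_sided", "exact_rxc_enumeration", count)


# ---------------------------------------------------------------------------
# cohort-wide screens


def association_screen(records=None, counts=None, alpha: float = 0.05) -> ScreenReport:
    """Screen variation class against every phenotype, subtype, gene and sex.

    Either ``records`` (a list of analyzable patient records) or
    ``counts`` (a pre-tabulated pandas DataFrame with columns
    phenotype, gly_present, gly_absent, other_present, other_absent)
    must be given. Each phenotype gets a two-sided 2x2 test; a cohort
    additionally gets the subtype 2x3 enumeration test and 2x2 tests on
    gene (COL1A1 vs COL1A2) and sex. Degenerate tables are reported
    with a flag, never dropped silently.
    """
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if (records is None) == (counts is None):
        raise DomainError("provide exactly one of records or counts")

    rows: list[ScreenRow] = []

    def add(label: str, tab: ContingencyTable, result: TestResult) -> None:
        rows.append(ScreenRow(label, tab, result, bool(result.p_value < alpha and not result.degenerate)))

    if counts is not None:
        required = {"phenotype", "gly_present", "gly_absent", "other_present", "other_absent"}
        missing = required - set(counts.columns)
        if missing:
            raise VocabularyError(f"counts table missing columns: {sorted(missing)}")
        for _, row in counts.iterrows():
            tab = ContingencyTable(
                [[int(row.gly_present), int(row.gly_absent)],
                 [int(row.other_present), int(row.other_absent)]],
                row_labels=("gly_missense", "quantitative"),
                col_labels=("present", "absent"),
            )
            add(str(row.phenotype), tab, fisher_2x2(tab))
        return ScreenReport(rows, alpha)

    # cohort mode
    from . import cohort as _cohort

    for phenotype in _cohort.PHENOTYPES:
        tab = _cohort.build_phenotype_table(records, phenotype)
        add(phenotype, tab, fisher_2x2(tab))
    subtype = _cohort.build_subtype_table(records)
    add("oi_type", subtype, fisher_rxc(subtype))
    gene = _cohort.build_gene_table(records)
    add("gene", gene, fisher_2x2(gene))
    sex = _cohort.build_sex_table(records)
    add("sex", sex, fisher_2x2(sex))
    return ScreenReport(rows, alpha)


def cooccurrence_screen(records=None, counts=None, phenotype_a: str | None = None,
                        phenotype_b: str | None = None) -> TestResult:
    """One-sided test for co-occurrence of phenotype ``a`` given ``b``.

    Builds the 2x2 table (b present / b absent) x (a present / a absent)
    over patients with known status on both phenotypes, and tests for
    enrichment of ``a`` among carriers of ``b`` (alternative greater).
    A pre-tabulated 2x2 ``counts`` array may be given instead of records.
    """
    if counts is not None:
        return fisher_2x2(_as_table(counts), alternative="greater")

    from . import cohort as _cohort

    if phenotype_a is None or phenotype_b is None:
        raise DomainError("phenotype_a and phenotype_b are required in cohort mode")
    if phenotype_a == phenotype_b:
        raise DomainError("co-occurrence of a phenotype with itself is undefined")
    for label in (phenotype_a, phenotype_b):
        if label not in _cohort.PHENOTYPES:
            raise VocabularyError(f"unknown phenotype label {label!r}")

    cells = np.zeros((2, 2), dtype=np.int64)
    for rec in records:
        a = rec.phenotypes.get(phenotype_a)
        b = rec.phenotypes.get(phenotype_b)
        if a is None or b is None:
            continue
        cells[0 if b else 1, 0 if a else 1] += 1
    tab = ContingencyTable(
        cells,
        row_labels=(f"{phenotype_b}+", f"{phenotype_b}-"),
        col_labels=(f"{phenotype_a}+", f"{phenotype_a}-"),
    )
    return fisher_2x2(tab, alternative="greater")


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional extension column)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m, dtype=float)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p_values[idx] * m / rank)
        adj[idx] = running
    return adj.tolist()
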