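"""Subject-level rare-variant enrichment statistics.

The central object is the carrier matrix: a subjects x genes binary
indicator of whether a subject carries at least one QC-passing variant in a
gene.  Collapsing to carrier indicators makes the statistical units
independent people rather than correlated variant observations, which is
what licenses a Fisher exact test per gene.

Per gene, the 2x2 table

    =============  ========  ===========
    .              carriers  non-carriers
    cases          a         b
    controls       c         d
    =============  ========  ===========

is tested one-sided for enrichment in cases (hypergeometric upper tail
``P(X >= a)``); effect sizes are Woolf odds ratios ``ad/bc`` with
log-normal confidence intervals, falling back to the Haldane-Anscombe +0.5
correction when any cell is zero.  Group prevalences carry Wilson score
intervals.  Family-wise control is Bonferroni over the number of testable
genes; false-discovery control is Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .cohort import Cohort, CohortError, Group

__all__ = [
    "CarrierMatrix",
    "ContingencyTable2x2",
    "GeneResult",
    "ScanResult",
    "ObservationCounts",
    "build_carrier_matrix",
    "observation_ratio",
    "gene_contingency",
    "fisher_one_sided",
    "woolf_or_ci",
    "wilson_ci",
    "bonferroni_threshold",
    "bh_fdr",
    "genome_wide_scan",
]

Z95 = norm.ppf(0.975)  # exact normal quantile, not 1.96 rounded


@dataclass
class CarrierMatrix:
    """Binary subjects x genes carrier indicators."""

    subject_ids: list[str]
    gene_symbols: list[str]
    cells: np.ndarray  # shape (n_subjects, n_genes), dtype int8, values {0,1}

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (len(self.subject_ids), len(self.gene_symbols)):
            raise CohortError("carrier matrix dimensions do not match id lists")
        if not np.isin(self.cells, (0, 1)).all():
            raise CohortError("carrier matrix cells must be binary")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=self.subject_ids,
                            columns=self.gene_symbols)

    def column(self, gene: str) -> np.ndarray:
        try:
            j = self.gene_symbols.index(gene)
        except ValueError:
            raise CohortError(f"gene {gene!r} not in carrier matrix") from None
        return self.cells[:, j]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier counts: a/b case carriers/non-carriers, c/d control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise CohortError("contingency counts must be nonnegative")

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class GeneResult:
    gene_symbol: str
    table: ContingencyTable2x2
    p_one_sided: float
    prevalence_case: float
    prevalence_control: float
    wilson_case: tuple[float, float]
    wilson_control: tuple[float, float]
    odds_ratio: Optional[float]
    or_ci_95: Optional[tuple[float, float]]
    or_corrected: bool = False
    tier: str = "not_significant"  # genome_wide | nominal | not_significant
    q_value: Optional[float] = None


@dataclass
class ScanResult:
    results: list[GeneResult]
    m_tests: int
    alpha: float = 0.05

    @property
    def bonferroni_threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.m_tests)

    @property
    def n_nominal(self) -> int:
        return sum(r.tier in ("nominal", "genome_wide") for r in self.results)

    @property
    def n_genome_wide(self) -> int:
        return sum(r.tier == "genome_wide" for r in self.results)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "gene": r.gene_symbol,
                "a": r.table.a, "b": r.table.b,
                "c": r.table.c, "d": r.table.d,
                "prev_case": r.prevalence_case,
                "prev_ctrl": r.prevalence_control,
                "wilson_case_lo": r.wilson_case[0],
                "wilson_case_hi": r.wilson_case[1],
                "wilson_ctrl_lo": r.wilson_control[0],
                "wilson_ctrl_hi": r.wilson_control[1],
                "p": r.p_one_sided,
                "q": r.q_value,
                "or": r.odds_ratio,
                "or_ci_lo": None if r.or_ci_95 is None else r.or_ci_95[0],
                "or_ci_hi": None if r.or_ci_95 is None else r.or_ci_95[1],
                "or_corrected": r.or_corrected,
                "tier": r.tier,
            })
        return pd.DataFrame(rows)


@dataclass
class ObservationCounts:
    """Observation-level vs subject-level size diagnostic.

    ``ratio`` divides raw case observations by control observations; the
    companion ``subject_ratio`` is cases over controls, and
    ``ratio_of_ratios`` is their quotient (observations-per-case over
    observations-per-control).  Both views are reported explicitly.
    """

    case_observations: int
    control_observations: int
    n_cases: int
    n_controls: int

    @property
    def ratio(self) -> Optional[float]:
        if self.control_observations == 0:
            return None
        return self.case_observations / self.control_observations

    @property
    def subject_ratio(self) -> Optional[float]:
        if self.n_controls == 0:
            return None
        return self.n_cases / self.n_controls

    @property
    def ratio_of_ratios(self) -> Optional[float]:
        if self.ratio is None or not self.subject_ratio:
            return None
        return self.ratio / self.subject_ratio


def build_carrier_matrix(cohort: Cohort) -> CarrierMatrix:
    """Collapse calls to binary subject x gene carrier indicators.

    Subject order follows the cohort's subject list; genes are sorted
    lexicographically.  Idempotent: rebuilding from an already-binarized
    matrix changes nothing.
    """
    subject_ids = [s.subject_id for s in cohort.subjects]
    genes = sorted({c.gene_symbol for c in cohort.calls})
    cells = np.zeros((len(subject_ids), len(genes)), dtype=np.int8)
    if cohort.calls:
        srow = {sid: i for i, sid in enumerate(subject_ids)}
        gcol = {g: j for j, g in enumerate(genes)}
        for call in cohort.calls:
            cells[srow[call.subject_id], gcol[call.gene_symbol]] = 1
    return CarrierMatrix(subject_ids=subject_ids, gene_symbols=genes,
                         cells=cells)


def observation_ratio(cohort: Cohort) -> ObservationCounts:
    """Count subject-variant observations per group.

    With many variants per subject, observation counts exceed subject
    counts by an order of magnitude; treating observations as independent
    would inflate the effective sample size by ``ratio`` relative to the
    subject-level design.
    """
    case_ids = {s.subject_id for s in cohort.subjects if s.group is Group.CASE}
    n_case_obs = sum(1 for c in cohort.calls if c.subject_id in case_ids)
    return ObservationCounts(
        case_observations=n_case_obs,
        control_observations=len(cohort.calls) - n_case_obs,
        n_cases=cohort.n_cases,
        n_controls=cohort.n_controls,
    )


def gene_contingency(
    matrix: CarrierMatrix,
    labels: Mapping[str, Group],
    gene: str,
) -> ContingencyTable2x2:
    """Build the per-gene 2x2 carrier table from the carrier matrix."""
    col = matrix.column(gene)
    is_case = np.array(
        [labels[s] is Group.CASE for s in matrix.subject_ids], dtype=bool)
    a = int(col[is_case].sum())
    c = int(col[~is_case].sum())
    return ContingencyTable2x2(
        a=a, b=int(is_case.sum()) - a,
        c=c, d=int((~is_case).sum()) - c,
    )


def fisher_one_sided(table: ContingencyTable2x2) -> float:
    """One-sided Fisher exact p for enrichment in cases.

    The hypergeometric upper tail ``P(X >= a)`` with population
    ``N = a+b+c+d``, ``K = a+c`` carriers and ``n = a+b`` case draws.
    Depletion is never tested; the alternative is fixed as
    carriers-enriched-in-cases.
    """
    if table.n_cases == 0 or table.n_controls == 0:
        raise CohortError("both group margins must be positive")
    p = float(hypergeom.sf(table.a - 1, table.n_total,
                           table.a + table.c, table.n_cases))
    return min(p, 1.0)


def fisher_one_sided_vector(
    a: np.ndarray, n_cases: int, c: np.ndarray, n_controls: int
) -> np.ndarray:
    """Vectorized one-sided Fisher p over per-gene carrier counts."""
    a = np.asarray(a)
    c = np.asarray(c)
    N = n_cases + n_controls
    return np.minimum(hypergeom.sf(a - 1, N, a + c, n_cases), 1.0)


def woolf_or_ci(
    table: ContingencyTable2x2, level: float = 0.95
) -> tuple[Optional[float], Optional[tuple[float, float]], bool]:
    """Woolf odds ratio with log-normal CI.

    Returns ``(odds_ratio, (low, high), corrected)``.  With all cells
    positive the estimate is ``ad/bc`` and the CI is
    ``exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))``.  If any cell is
    zero, 0.5 is added to every cell first (Haldane-Anscombe) and the
    result flagged ``corrected=True``.  With no carriers in either group
    (``a = c = 0``) the odds ratio is undefined and ``(None, None, False)``
    is returned.
    """
    if table.n_cases == 0 or table.n_controls == 0:
        raise CohortError("both group margins must be positive")
    if table.a == 0 and table.c == 0:
        return None, None, False
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = norm.ppf(0.5 + level / 2)
    ci = (or_ * math.exp(-z * se), or_ * math.exp(z * se))
    return or_, ci, corrected


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion ``k/n``."""
    if n <= 0:
        raise CohortError("wilson_ci requires n > 0")
    if not 0 <= k <= n:
        raise CohortError("wilson_ci requires 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
    # boundary cases are exact analytically; guard against float residue
    if k == 0:
        lo = 0.0
    if k == n:
        hi = 1.0
    return float(lo), float(hi)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold ``alpha / m``."""
    if m < 1:
        raise CohortError("bonferroni_threshold requires m >= 1")
    if not 0 < alpha < 1:
        raise CohortError("alpha must lie in (0,1)")
    return alpha / m


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise CohortError("p-values must lie in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def _tier(p: float, alpha: float, m: int) -> str:
    if p < bonferroni_threshold(alpha, m):
        return "genome_wide"
    if p < alpha:
        return "nominal"
    return "not_significant"


def genome_wide_scan(
    matrix: CarrierMatrix,
    labels: Mapping[str, Group],
    alpha: float = 0.05,
) -> ScanResult:
    """Exact-test scan across every gene with at least one carrier.

    Genes carried by nobody are untestable and excluded from the multiple-
    testing burden ``m``; genes carried only by controls remain testable
    (their one-sided p is ~1).  Results are sorted by ascending p with ties
    broken lexicographically by gene symbol.
    """
    is_case = np.array(
        [labels[s] is Group.CASE for s in matrix.subject_ids], dtype=bool)
    n1 = int(is_case.sum())
    n2 = len(matrix.subject_ids) - n1
    if n1 == 0 or n2 == 0:
        raise CohortError("scan requires at least one case and one control")
    cells = matrix.cells
    a_vec = cells[is_case].sum(axis=0)
    c_vec = cells[~is_case].sum(axis=0)
    testable = (a_vec + c_vec) > 0
    m = int(testable.sum())
    results: list[GeneResult] = []
    if m == 0:
        return ScanResult(results=[], m_tests=0, alpha=alpha)
    p_vec = fisher_one_sided_vector(a_vec[testable], n1, c_vec[testable], n2)
    q_vec = bh_fdr(p_vec)
    genes = [g for g, t in zip(matrix.gene_symbols, testable) if t]
    for gene, a, c, p, q in zip(
            genes, a_vec[testable], c_vec[testable], p_vec, q_vec):
        table = ContingencyTable2x2(a=int(a), b=n1 - int(a),
                                    c=int(c), d=n2 - int(c))
        or_, ci, corrected = woolf_or_ci(table)
        results.append(GeneResult(
            gene_symbol=gene,
            table=table,
            p_one_sided=float(p),
            prevalence_case=table.a / n1,
            prevalence_control=table.c / n2,
            wilson_case=wilson_ci(table.a, n1),
            wilson_control=wilson_ci(table.c, n2),
            odds_ratio=or_,
            or_ci_95=ci,
            or_corrected=corrected,
            tier=_tier(float(p), alpha, m),
            q_value=float(q),
        ))
    results.sort(key=lambda r: (r.p_one_sided, r.gene_symbol))
    return ScanResult(results=results, m_tests=m, alpha=alpha)
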