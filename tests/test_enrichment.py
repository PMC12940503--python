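"""Carrier matrix construction, exact tests, effect sizes and the scan."""

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famburden import (
    Cohort,
    CohortError,
    GeneSpec,
    Group,
    SimulationConfig,
    Subject,
    generate_cohort_with_ledger,
)
from famburden.enrichment import (
    ContingencyTable2x2,
    bh_fdr,
    bonferroni_threshold,
    build_carrier_matrix,
    fisher_one_sided,
    gene_contingency,
    genome_wide_scan,
    observation_ratio,
    wilson_ci,
    woolf_or_ci,
)

from conftest import make_call, matrix_from_counts


# -------------------------------------------------------------- Fisher test


def enumerate_fisher_upper_tail(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric upper tail.

    Sums C(K, x) * C(N-K, n-x) / C(N, n) over x >= a by direct
    combinatorial enumeration.
    """
    N, K, n = a + b + c + d, a + c, a + b
    total = math.comb(N, n)
    x_max = min(K, n)
    return sum(
        math.comb(K, x) * math.comb(N - K, n - x) for x in range(a, x_max + 1)
    ) / total


@pytest.mark.parametrize("name,expected_p", [
    ("FLG-AS1", 7.67e-9),
    ("PCDHGA1", 8.28e-9),
    ("SYNE1", 8.21e-8),
    ("OBSCN", 6.02e-7),
    ("collagen", 1.06e-5),
    ("hla", 2.23e-5),
    ("mitochondrial", 2.29e-3),
    ("fracture_mito", 2.11e-2),
    ("MT-ATP6_fracture", 8.91e-3),
])
def test_fisher_reproduces_published_gene_pvalues(printed_tables, name,
                                                  expected_p):
    p = fisher_one_sided(printed_tables[name])
    assert p == pytest.approx(expected_p, rel=5e-3)


def test_fisher_equals_enumeration_oracle_on_all_small_tables():
    """Exhaustive agreement with direct combinatorial enumeration for
    every 2x2 table with N <= 12 and positive margins."""
    checked = 0
    for a, b, c, d in product(range(13), repeat=4):
        if a + b + c + d > 12 or a + b == 0 or c + d == 0:
            continue
        table = ContingencyTable2x2(a, b, c, d)
        assert fisher_one_sided(table) == pytest.approx(
            enumerate_fisher_upper_tail(a, b, c, d), abs=1e-12)
        checked += 1
    assert checked > 1000


def test_fisher_no_carriers_gives_p_one():
    assert fisher_one_sided(ContingencyTable2x2(0, 86, 0, 30)) == 1.0


def test_fisher_monotone_nonincreasing_in_case_carriers():
    """Moving a carrier from controls to cases (fixed margins) can only
    strengthen one-sided enrichment evidence."""
    total_carriers, n1, n2 = 20, 30, 25
    ps = []
    for a in range(total_carriers + 1):
        c = total_carriers - a
        if a > n1 or c > n2:
            continue
        ps.append(fisher_one_sided(
            ContingencyTable2x2(a, n1 - a, c, n2 - c)))
    assert all(p2 <= p1 + 1e-15 for p1, p2 in zip(ps, ps[1:]))


def test_fisher_rejects_empty_margin():
    with pytest.raises(CohortError):
        fisher_one_sided(ContingencyTable2x2(0, 0, 3, 5))


def test_negative_counts_rejected():
    with pytest.raises(CohortError):
        ContingencyTable2x2(-1, 2, 3, 4)


# ------------------------------------------------------------- Woolf OR/CI


@pytest.mark.parametrize("name,expected_or", [
    ("FLG-AS1", 20.8),
    ("SYNE1", 12.4),
    ("OBSCN", 30.4),
    ("PCDHGA1", 16.5),
    ("HSPG2", 12.1),
    ("collagen", 8.4),
    ("hla", 6.8),
    ("mitochondrial", 7.1),
    ("fracture_mito", 4.2),
    ("MT-ATP6_fracture", 8.3),
])
def test_woolf_reproduces_published_odds_ratios(printed_tables, name,
                                                expected_or):
    or_, _, corrected = woolf_or_ci(printed_tables[name])
    assert not corrected
    assert or_ == pytest.approx(expected_or, abs=0.05)


def test_woolf_ci_bounds_match_published_values(printed_tables):
    _, ci, _ = woolf_or_ci(printed_tables["FLG-AS1"])
    assert ci[0] == pytest.approx(5.8, abs=0.05)
    _, ci, _ = woolf_or_ci(printed_tables["fracture_mito"])
    assert ci == (pytest.approx(1.2, abs=0.05), pytest.approx(14.6, abs=0.05))


def test_haldane_anscombe_correction_arithmetic():
    """(10,10,0,20): +0.5 everywhere gives (10.5*20.5)/(10.5*0.5) = 41."""
    or_, _, corrected = woolf_or_ci(ContingencyTable2x2(10, 10, 0, 20))
    assert corrected
    assert or_ == pytest.approx(41.0)


def test_no_carriers_or_undefined():
    or_, ci, corrected = woolf_or_ci(ContingencyTable2x2(0, 86, 0, 30))
    assert or_ is None and ci is None and not corrected


def test_correction_applied_only_when_zero_cell_exists(printed_tables):
    for name in ("FLG-AS1", "collagen", "hla"):
        _, _, corrected = woolf_or_ci(printed_tables[name])
        assert not corrected
    _, _, corrected = woolf_or_ci(printed_tables["RELN"])
    assert corrected


# ------------------------------------------------------------ Wilson / BH


def test_wilson_boundaries():
    lo, _ = wilson_ci(0, 30)
    assert lo == 0.0
    _, hi = wilson_ci(30, 30)
    assert hi == 1.0


def test_wilson_contains_point_estimate_and_beats_wald():
    lo, hi = wilson_ci(60, 86)
    p_hat = 60 / 86
    assert lo < p_hat < hi
    z = 1.959963984540054
    wald_half = z * math.sqrt(p_hat * (1 - p_hat) / 86)
    assert (hi - lo) < 2 * wald_half


def test_wilson_rejects_invalid_inputs():
    with pytest.raises(CohortError):
        wilson_ci(1, 0)
    with pytest.raises(CohortError):
        wilson_ci(5, 3)


def test_bonferroni_threshold_values():
    # the exact quotient is 3.7648e-6; the published figure rounds to 3.77
    assert bonferroni_threshold(0.05, 13_281) == pytest.approx(3.77e-6,
                                                               abs=0.01e-6)
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.01, 100) == pytest.approx(1e-4)
    with pytest.raises(CohortError):
        bonferroni_threshold(0.05, 0)


def test_bh_fdr_step_up():
    q = bh_fdr([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_fdr([0.3])[0] == pytest.approx(0.3)
    assert bh_fdr([]).size == 0


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(1e-12, 1.0, allow_nan=False), min_size=1,
                max_size=50))
def test_bh_q_values_bounded_and_dominate_p(ps):
    q = bh_fdr(ps)
    assert (q <= 1.0 + 1e-12).all()
    assert (q >= np.asarray(ps) - 1e-12).all()


# --------------------------------------------------------- carrier matrix


def test_carrier_matrix_binarizes_multiple_calls():
    subjects = [Subject("S1", "F1", Group.CASE),
                Subject("S2", "F1", Group.CONTROL)]
    calls = [make_call("S1", "COL5A1", "9", 1000 + i) for i in range(7)]
    matrix = build_carrier_matrix(Cohort(subjects=subjects, calls=calls))
    assert matrix.to_frame().loc["S1", "COL5A1"] == 1
    assert matrix.to_frame().loc["S2", "COL5A1"] == 0


def test_carrier_matrix_empty_cohort():
    subjects = [Subject("S1", "F1", Group.CASE)]
    matrix = build_carrier_matrix(Cohort(subjects=subjects))
    assert matrix.cells.shape == (1, 0)


def test_carrier_matrix_column_sums_match_generator_ledger():
    config = SimulationConfig(
        genes=(GeneSpec("G1", 0.2, 3.0), GeneSpec("G2", 0.3, 1.0)),
        seed=7)
    cohort, ledger = generate_cohort_with_ledger(config)
    matrix = build_carrier_matrix(cohort)
    for gene in matrix.gene_symbols:
        expected = ledger.case_carriers[gene] + ledger.control_carriers[gene]
        assert matrix.column(gene).sum() == expected


# ------------------------------------------------------ observation ratio


def test_observation_ratio_of_study_scale_counts():
    """143,422 case vs 7,565 control observations is ~19-fold, against a
    subject-level 86/30."""
    subjects = [Subject("CASE", "F1", Group.CASE),
                Subject("CTRL", "F2", Group.CONTROL)]
    # miniature cohort with the same per-group observation imbalance
    calls = [make_call("CASE", "G", "1", 1000 + i) for i in range(19)] + \
            [make_call("CTRL", "G", "1", 5000)]
    obs = observation_ratio(Cohort(subjects=subjects, calls=calls))
    assert obs.ratio == pytest.approx(19.0)
    # the printed study-scale counts, checked on the dataclass directly
    from famburden.enrichment import ObservationCounts
    study = ObservationCounts(143_422, 7_565, 86, 30)
    assert study.ratio == pytest.approx(18.96, abs=0.01)
    assert study.subject_ratio == pytest.approx(86 / 30)
    assert study.ratio_of_ratios == pytest.approx(6.61, abs=0.01)


def test_observation_ratio_equal_counts_and_recount(small_cohort):
    obs = observation_ratio(small_cohort)
    case_ids = {s.subject_id for s in small_cohort.subjects
                if s.group is Group.CASE}
    assert obs.case_observations == sum(
        1 for c in small_cohort.calls if c.subject_id in case_ids)
    assert obs.case_observations + obs.control_observations == len(
        small_cohort.calls)


def test_observation_ratio_zero_controls_flagged():
    subjects = [Subject("S1", "F1", Group.CASE)]
    obs = observation_ratio(Cohort(subjects=subjects,
                                   calls=[make_call("S1")]))
    assert obs.ratio is None


# ---------------------------------------------------------- contingency


def test_gene_contingency_matches_published_carrier_counts():
    matrix, labels = matrix_from_counts({"FLG-AS1": (60, 3)}, 86, 30)
    table = gene_contingency(matrix, labels, "FLG-AS1")
    assert (table.a, table.b, table.c, table.d) == (60, 26, 3, 27)


def test_gene_contingency_absent_gene_and_errors():
    matrix, labels = matrix_from_counts({"G": (0, 0)}, 5, 4)
    table = gene_contingency(matrix, labels, "G")
    assert (table.a, table.b, table.c, table.d) == (0, 5, 0, 4)
    with pytest.raises(CohortError):
        gene_contingency(matrix, labels, "MISSING")


def test_gene_contingency_complement_symmetry():
    matrix, labels = matrix_from_counts({"G": (12, 4)}, 20, 10)
    table = gene_contingency(matrix, labels, "G")
    flipped = matrix_from_counts({"G": (20 - 12, 10 - 4)}, 20, 10)[0]
    flipped_table = gene_contingency(flipped, labels, "G")
    assert (flipped_table.a, flipped_table.b) == (table.b, table.a)
    assert (flipped_table.c, flipped_table.d) == (table.d, table.c)


# ------------------------------------------------------------------ scan


def test_scan_of_published_top_genes_is_genome_wide_at_study_m():
    """The seven published genome-wide genes all beat 0.05/13,281."""
    counts = {"FLG-AS1": (60, 3), "PCDHGA1": (66, 5), "SYNE1": (68, 7),
              "RELN": (41, 0), "OBSCN": (44, 1), "HSPG2": (56, 4),
              "KRT74": (56, 4)}
    matrix, labels = matrix_from_counts(counts, 86, 30)
    scan = genome_wide_scan(matrix, labels)
    threshold = bonferroni_threshold(0.05, 13_281)
    assert scan.m_tests == 7
    assert all(r.p_one_sided < threshold for r in scan.results)


def test_scan_single_gene_threshold_is_alpha():
    matrix, labels = matrix_from_counts({"G": (4, 1)}, 10, 10)
    scan = genome_wide_scan(matrix, labels, alpha=0.05)
    assert scan.m_tests == 1
    assert scan.bonferroni_threshold == 0.05


def test_scan_excludes_zero_carrier_genes_from_m():
    matrix, labels = matrix_from_counts({"CARRIED": (4, 1),
                                         "EMPTY": (0, 0)}, 10, 10)
    scan = genome_wide_scan(matrix, labels)
    assert scan.m_tests == 1
    assert [r.gene_symbol for r in scan.results] == ["CARRIED"]


def test_scan_control_only_gene_is_tested_with_high_p():
    matrix, labels = matrix_from_counts({"CTRLONLY": (0, 5)}, 10, 10)
    scan = genome_wide_scan(matrix, labels)
    assert scan.m_tests == 1
    assert scan.results[0].p_one_sided > 0.99


def test_scan_requires_both_groups():
    matrix, _ = matrix_from_counts({"G": (2, 0)}, 5, 0)
    labels = {s: Group.CASE for s in matrix.subject_ids}
    with pytest.raises(CohortError):
        genome_wide_scan(matrix, labels)


def test_scan_orders_by_p_with_lexicographic_ties():
    matrix, labels = matrix_from_counts(
        {"ZZZ": (5, 1), "AAA": (5, 1), "MMM": (9, 0)}, 10, 10)
    scan = genome_wide_scan(matrix, labels)
    assert [r.gene_symbol for r in scan.results] == ["MMM", "AAA", "ZZZ"]
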