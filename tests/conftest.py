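import numpy as np
import pytest

from famburden import (
    Cohort,
    Consequence,
    Fracture,
    GeneSpec,
    Group,
    Sex,
    SimulationConfig,
    Subject,
    TrioRole,
    VariantCall,
    generate_cohort,
)
from famburden.enrichment import CarrierMatrix, ContingencyTable2x2

# Published per-gene and per-pathway 2x2 carrier tables
# (case carriers, case non-carriers, control carriers, control non-carriers)
PRINTED_TABLES = {
    "FLG-AS1": (60, 26, 3, 27),
    "PCDHGA1": (66, 20, 5, 25),
    "SYNE1": (68, 18, 7, 23),
    "RELN": (41, 45, 0, 30),
    "OBSCN": (44, 42, 1, 29),
    "HSPG2": (56, 30, 4, 26),
    "KRT74": (56, 30, 4, 26),
    "collagen": (54, 32, 5, 25),
    "hla": (64, 22, 9, 21),
    "mitochondrial": (29, 57, 2, 28),
    "fracture_mito": (11, 10, 6, 23),
    "MT-ATP6_fracture": (8, 13, 2, 27),
}


@pytest.fixture(scope="session")
def printed_tables():
    return {k: ContingencyTable2x2(*v) for k, v in PRINTED_TABLES.items()}


def make_call(subject_id="S1", gene="GENE1", chrom="1", pos=1000,
              ref="A", alt="C", consequence=Consequence.MISSENSE, **kw):
    return VariantCall(subject_id=subject_id, gene_symbol=gene, chrom=chrom,
                       pos=pos, ref=ref, alt=alt, consequence=consequence,
                       **kw)


@pytest.fixture
def call_factory():
    return make_call


def matrix_from_counts(counts: dict[str, tuple[int, int]],
                       n_cases: int, n_controls: int):
    """Carrier matrix with given per-gene (case, control) carrier counts.

    Case carriers fill the first rows of the case block, control carriers
    the first rows of the control block.
    """
    subject_ids = [f"CASE{i:03d}" for i in range(n_cases)] + \
                  [f"CTRL{i:03d}" for i in range(n_controls)]
    genes = sorted(counts)
    cells = np.zeros((len(subject_ids), len(genes)), dtype=np.int8)
    for j, g in enumerate(genes):
        a, c = counts[g]
        cells[:a, j] = 1
        cells[n_cases:n_cases + c, j] = 1
    labels = {s: (Group.CASE if s.startswith("CASE") else Group.CONTROL)
              for s in subject_ids}
    return CarrierMatrix(subject_ids=subject_ids, gene_symbols=genes,
                         cells=cells), labels


@pytest.fixture
def study_matrix_factory():
    return matrix_from_counts


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic 43-family synthetic cohort with one enriched gene."""
    config = SimulationConfig(
        genes=(GeneSpec("ENRICHED", 0.167, 8.4),
               GeneSpec("NULLGENE", 0.25, 1.0)),
        seed=42,
    )
    return generate_cohort(config)


@pytest.fixture
def tiny_cohort():
    """Hand-built 6-subject, 2-family cohort."""
    subjects = [
        Subject("A1", "FAMA", Group.CASE, trio_role=TrioRole.MOTHER,
                sex=Sex.F),
        Subject("A2", "FAMA", Group.CONTROL, trio_role=TrioRole.FATHER,
                sex=Sex.M),
        Subject("A3", "FAMA", Group.CASE,
                fracture=Fracture.PEDIATRIC_FRACTURE,
                trio_role=TrioRole.CHILD),
        Subject("B1", "FAMB", Group.CASE, trio_role=TrioRole.MOTHER,
                sex=Sex.F),
        Subject("B2", "FAMB", Group.CONTROL, trio_role=TrioRole.OTHER),
        Subject("B3", "FAMB", Group.CASE, trio_role=TrioRole.CHILD),
    ]
    calls = [
        make_call("A1", "COL5A1", "9", 1000),
        make_call("A3", "COL5A1", "9", 1000),
        make_call("A3", "COL5A1", "9", 1001, ref="G", alt="T"),
        make_call("B1", "SYNE1", "6", 5000),
        make_call("B3", "TTN", "2", 9000),
    ]
    return Cohort(subjects=subjects, calls=calls)
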