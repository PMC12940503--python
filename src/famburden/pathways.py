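"""Pathway-level prevalence statistics over curated gene sets.

A subject is a pathway carrier if they carry a qualifying variant in *any*
member gene, so the pathway carrier vector is the elementwise OR of the
member-gene carrier columns and pathway prevalence is always at least the
largest single-gene prevalence among members.

Five built-in sets covering the biological systems most relevant to
heritable connective-tissue fragility ship as a GMT resource:
HLA/adaptive-immune, collagen biosynthesis, mitochondrially encoded
respiratory chain, structural/cytoskeletal, and the protocadherin gamma
cluster.  User GMT files may extend or override them.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import numpy as np

from .cohort import CohortError, GeneSet, Group
from .enrichment import (
    CarrierMatrix,
    ContingencyTable2x2,
    GeneResult,
    fisher_one_sided,
    wilson_ci,
    woolf_or_ci,
)
from .io import read_gene_sets

__all__ = [
    "builtin_pathways",
    "pathway_carrier_vector",
    "pathway_enrichment",
]


def builtin_pathways() -> list[GeneSet]:
    """Load the five built-in pathway gene sets (immutable copies)."""
    ref = resources.files("famburden.data").joinpath("builtin_pathways.gmt")
    with resources.as_file(ref) as path:
        return read_gene_sets(path)


def pathway_carrier_vector(
    matrix: CarrierMatrix, gene_set: GeneSet
) -> np.ndarray:
    """Per-subject binary indicator of carrying >=1 variant in the set.

    Member genes absent from the matrix contribute nothing.
    """
    if len(gene_set) == 0:
        raise CohortError("empty gene set")
    member = set(gene_set.genes)
    cols = [j for j, g in enumerate(matrix.gene_symbols) if g in member]
    if not cols:
        return np.zeros(len(matrix.subject_ids), dtype=np.int8)
    return (matrix.cells[:, cols].max(axis=1)).astype(np.int8)


def pathway_enrichment(
    matrix: CarrierMatrix,
    labels: Mapping[str, Group],
    gene_set: GeneSet,
) -> GeneResult:
    """Fisher/Woolf/Wilson statistics on the pathway carrier vector."""
    vec = pathway_carrier_vector(matrix, gene_set)
    is_case = np.array(
        [labels[s] is Group.CASE for s in matrix.subject_ids], dtype=bool)
    n1 = int(is_case.sum())
    n2 = len(matrix.subject_ids) - n1
    if n1 == 0 or n2 == 0:
        raise CohortError("pathway test requires both groups")
    a = int(vec[is_case].sum())
    c = int(vec[~is_case].sum())
    table = ContingencyTable2x2(a=a, b=n1 - a, c=c, d=n2 - c)
    p = fisher_one_sided(table)
    or_, ci, corrected = woolf_or_ci(table)
    return GeneResult(
        gene_symbol=gene_set.name,
        table=table,
        p_one_sided=p,
        prevalence_case=a / n1,
        prevalence_control=c / n2,
        wilson_case=wilson_ci(a, n1),
        wilson_control=wilson_ci(c, n2),
        odds_ratio=or_,
        or_ci_95=ci,
        or_corrected=corrected,
    )
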