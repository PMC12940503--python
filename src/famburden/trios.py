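"""Complex-inheritance pattern detection in sequenced parent-parent-child
trios.

Three patterns are recognized: classical compound heterozygosity (a child
carrying two distinct heterozygous variants in the same gene, one of
unambiguous maternal origin and one of unambiguous paternal origin),
trans-heterozygous pathway disruption (maternally and paternally inherited
variants in *different* genes of the same biological pathway), and additive
damage load (the child's total damage score exceeds a caller-supplied
threshold with positive contributions from both parental sides).

Parental origin is assigned by exact (chrom, pos, ref, alt) match against
each parent's calls — no phasing inference.  A variant present in both
parents is ambiguous and never satisfies either side of an inheritance
pattern; a variant present in neither parent is de novo.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .cohort import Cohort, CohortError, GeneSet, Subject, TrioRole, VariantCall
from .damage import DamageWeights, damage_score_variant

__all__ = [
    "Trio",
    "PatternHit",
    "resolve_trios",
    "assign_parental_origin",
    "detect_compound_het",
    "detect_trans_het_pathway",
    "detect_additive_load",
]

ORIGINS = ("maternal", "paternal", "both", "de_novo")


@dataclass
class Trio:
    child: Subject
    mother: Subject
    father: Subject
    child_calls: list[VariantCall]
    mother_calls: list[VariantCall]
    father_calls: list[VariantCall]

    def __post_init__(self) -> None:
        ids = {self.child.subject_id, self.mother.subject_id,
               self.father.subject_id}
        if len(ids) != 3:
            raise CohortError("trio members must be three distinct subjects")
        fams = {self.child.family_id, self.mother.family_id,
                self.father.family_id}
        if len(fams) != 1:
            raise CohortError("trio members must share a family_id")
        if self.child.trio_role is not TrioRole.CHILD:
            raise CohortError("trio child must have trio_role=child")


@dataclass
class PatternHit:
    pattern: str  # compound_het | trans_het_pathway | additive_load
    trio_child: str
    genes: tuple[str, ...]
    origins: dict[tuple, str] = field(default_factory=dict)
    variant_keys: tuple[tuple, ...] = ()
    load: Optional[float] = None


def resolve_trios(cohort: Cohort) -> list[Trio]:
    """Extract every complete mother-father-child trio from a cohort.

    In families with several children, each child forms its own trio with
    the same parents.
    """
    trios: list[Trio] = []
    for fam_id, members in cohort.families().items():
        mothers = [s for s in members if s.trio_role is TrioRole.MOTHER]
        fathers = [s for s in members if s.trio_role is TrioRole.FATHER]
        children = [s for s in members if s.trio_role is TrioRole.CHILD]
        if len(mothers) == 1 and len(fathers) == 1:
            for child in children:
                trios.append(Trio(
                    child=child, mother=mothers[0], father=fathers[0],
                    child_calls=cohort.calls_for(child.subject_id),
                    mother_calls=cohort.calls_for(mothers[0].subject_id),
                    father_calls=cohort.calls_for(fathers[0].subject_id),
                ))
    return trios


def _locus_key(call: VariantCall) -> tuple:
    return (call.chrom, call.pos, call.ref, call.alt)


def assign_parental_origin(trio: Trio, child_variant: VariantCall) -> str:
    """Classify a child variant as maternal / paternal / both / de_novo."""
    key = _locus_key(child_variant)
    in_mother = any(_locus_key(c) == key for c in trio.mother_calls)
    in_father = any(_locus_key(c) == key for c in trio.father_calls)
    if in_mother and in_father:
        return "both"
    if in_mother:
        return "maternal"
    if in_father:
        return "paternal"
    return "de_novo"


def _child_by_gene(trio: Trio) -> dict[str, list[VariantCall]]:
    by_gene: dict[str, list[VariantCall]] = {}
    for call in sorted(trio.child_calls, key=_locus_key):
        by_gene.setdefault(call.gene_symbol, []).append(call)
    return by_gene


def detect_compound_het(trio: Trio) -> list[PatternHit]:
    """Genes where the child carries a het maternal-only and a het
    paternal-only variant.

    Variants seen in both parents are ambiguous and satisfy neither side;
    homozygous child genotypes are not compound heterozygosity.
    """
    hits: list[PatternHit] = []
    for gene, calls in _child_by_gene(trio).items():
        het = [c for c in calls if c.zygosity.value == "het"]
        if len(het) < 2:
            continue
        origins = {_locus_key(c): assign_parental_origin(trio, c)
                   for c in het}
        maternal = [c for c in het if origins[_locus_key(c)] == "maternal"]
        paternal = [c for c in het if origins[_locus_key(c)] == "paternal"]
        if maternal and paternal:
            support = tuple(sorted(
                {_locus_key(c) for c in maternal + paternal}))
            hits.append(PatternHit(
                pattern="compound_het",
                trio_child=trio.child.subject_id,
                genes=(gene,),
                origins={k: origins[k] for k in support},
                variant_keys=support,
            ))
    return hits


def detect_trans_het_pathway(
    trio: Trio, gene_sets: Sequence[GeneSet]
) -> list[PatternHit]:
    """Gene sets where maternal-only and paternal-only variants hit two
    *different* member genes."""
    hits: list[PatternHit] = []
    by_gene = _child_by_gene(trio)
    for gene_set in gene_sets:
        maternal_genes: dict[str, list[tuple]] = {}
        paternal_genes: dict[str, list[tuple]] = {}
        origins: dict[tuple, str] = {}
        for gene in sorted(set(by_gene) & set(gene_set.genes)):
            for call in by_gene[gene]:
                origin = assign_parental_origin(trio, call)
                origins[_locus_key(call)] = origin
                if origin == "maternal":
                    maternal_genes.setdefault(gene, []).append(
                        _locus_key(call))
                elif origin == "paternal":
                    paternal_genes.setdefault(gene, []).append(
                        _locus_key(call))
        qualifying = [
            (gm, gp) for gm, gp in itertools.product(
                maternal_genes, paternal_genes)
            if gm != gp
        ]
        if qualifying:
            genes = tuple(sorted({g for pair in qualifying for g in pair}))
            support = tuple(sorted(
                k for g in genes
                for k in maternal_genes.get(g, []) + paternal_genes.get(g, [])
            ))
            hits.append(PatternHit(
                pattern="trans_het_pathway",
                trio_child=trio.child.subject_id,
                genes=genes,
                origins={k: origins[k] for k in support},
                variant_keys=support,
            ))
    return hits


def detect_additive_load(
    trio: Trio,
    weights: DamageWeights | None = None,
    threshold: float | None = None,
) -> Optional[PatternHit]:
    """Flag a child whose total damage load reaches ``threshold`` with
    positive maternal and paternal contributions.

    ``threshold`` is mandatory: no principled default exists for where
    combined mutational load becomes clinically meaningful, so the caller
    must choose one explicitly.
    """
    if threshold is None or threshold <= 0:
        raise CohortError(
            "detect_additive_load requires an explicit positive threshold")
    w = weights or DamageWeights()
    total = 0.0
    side_scores = {"maternal": 0.0, "paternal": 0.0}
    origins: dict[tuple, str] = {}
    genes: set[str] = set()
    for call in trio.child_calls:
        score = damage_score_variant(call, w)
        total += score
        origin = assign_parental_origin(trio, call)
        origins[_locus_key(call)] = origin
        if origin in side_scores:
            side_scores[origin] += score
        if score > 0:
            genes.add(call.gene_symbol)
    if (total >= threshold and side_scores["maternal"] > 0
            and side_scores["paternal"] > 0):
        return PatternHit(
            pattern="additive_load",
            trio_child=trio.child.subject_id,
            genes=tuple(sorted(genes)),
            origins=origins,
            variant_keys=tuple(sorted(origins)),
            load=total,
        )
    return None
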