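"""Synthetic family-structured case-control cohort generation.

Because individual-level genomic data from family studies of this kind
cannot be shared, every downstream stage of the package is exercised on
synthetic cohorts that emulate the study design: 43 families totalling
~116 subjects (86 cases, 30 intrafamilial controls), per-gene carrier
prevalences with configurable case odds ratios, within-family genotype
correlation via parental transmission, a pediatric-fracture subphenotype
with its own within-case odds ratios, and fully annotated variant calls
that pass default QC.

Disease status is assigned first at the subject level to match target
fractions, and genotypes are then drawn conditional on status
(case-control sampling); the configured odds ratios are therefore exact
generative targets rather than emergent properties of a liability model.

Under ``transmission`` mode, founders draw carrier status at their group's
carrier probability; each founder variant is transmitted to each child
independently with probability 1/2, and the child's carrier status is then
"topped up" (or thinned) with independent draws so the marginal carrier
probability exactly matches the child's group target while preserving
within-family correlation through shared transmitted variants.

All randomness flows from a single integer seed through one NumPy
generator; the documented default seed is 42.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .cohort import (
    ClinVar,
    Cohort,
    CohortError,
    Consequence,
    Fracture,
    GeneSet,
    Group,
    Sex,
    Subject,
    TrioRole,
    VariantCall,
    Zygosity,
)

__all__ = [
    "AnnotationProfile",
    "GeneSpec",
    "SimulationConfig",
    "TrioPlant",
    "CarrierLedger",
    "generate_cohort",
    "generate_cohort_with_ledger",
    "generate_null_cohort",
    "generate_trio_fixtures",
    "study_like_gene_specs",
]

_BASES = np.array(list("ACGT"))

_CSQ_ORDER = [
    Consequence.MISSENSE, Consequence.SYNONYMOUS, Consequence.SPLICE_REGION,
    Consequence.OTHER, Consequence.INFRAME_INDEL, Consequence.STOP_GAIN,
    Consequence.FRAMESHIFT, Consequence.CANONICAL_SPLICE,
]
_CLINVAR_ORDER = [
    ClinVar.ABSENT, ClinVar.VUS, ClinVar.LB, ClinVar.B, ClinVar.LP, ClinVar.P,
]


@dataclass(frozen=True)
class AnnotationProfile:
    """Distributions used to dress carrier variants with annotations.

    Defaults reflect a rare-variant exome export: mostly missense and
    synonymous consequences, ClinVar mostly absent/VUS, ~15% of variants
    novel (absent from the population reference), the rest log-uniform in
    allele frequency below the 0.2 rarity ceiling, and occasional
    homozygous genotypes.
    """

    consequence_weights: tuple[float, ...] = (
        0.50, 0.15, 0.10, 0.07, 0.05, 0.05, 0.05, 0.03)
    clinvar_weights: tuple[float, ...] = (0.70, 0.20, 0.04, 0.03, 0.02, 0.01)
    p_novel: float = 0.15
    af_range: tuple[float, float] = (1e-4, 0.19)
    p_hom: float = 0.05

    def __post_init__(self) -> None:
        if len(self.consequence_weights) != len(_CSQ_ORDER):
            raise CohortError("need one weight per consequence class")
        if len(self.clinvar_weights) != len(_CLINVAR_ORDER):
            raise CohortError("need one weight per ClinVar class")


@dataclass(frozen=True)
class GeneSpec:
    """Generative parameters for one gene.

    ``case_odds_ratio`` relates non-fracture cases to controls;
    ``fracture_odds_ratio`` multiplies the case odds again for
    pediatric-fracture cases, so within-case fracture contrasts are exact
    targets too.
    """

    gene_symbol: str
    control_carrier_prob: float
    case_odds_ratio: float = 1.0
    fracture_odds_ratio: float = 1.0
    mean_variants_per_carrier: float = 1.5
    chrom: Optional[str] = None
    annotation_profile: AnnotationProfile = field(
        default_factory=AnnotationProfile)

    def __post_init__(self) -> None:
        if not 0.0 < self.control_carrier_prob < 1.0:
            raise CohortError(
                f"gene {self.gene_symbol}: control_carrier_prob must lie "
                "in (0,1)")
        if self.case_odds_ratio < 0 or self.fracture_odds_ratio < 0:
            raise CohortError(
                f"gene {self.gene_symbol}: odds ratios must be nonnegative")
        if self.mean_variants_per_carrier < 1.0:
            raise CohortError(
                f"gene {self.gene_symbol}: mean_variants_per_carrier >= 1")
        # validate implied probabilities up front
        self.case_carrier_prob
        self.fracture_carrier_prob

    @property
    def case_carrier_prob(self) -> float:
        return _shift_prob_by_or(
            self.control_carrier_prob, self.case_odds_ratio,
            self.gene_symbol)

    @property
    def fracture_carrier_prob(self) -> float:
        return _shift_prob_by_or(
            self.case_carrier_prob, self.fracture_odds_ratio,
            self.gene_symbol)


def _shift_prob_by_or(p0: float, odds_ratio: float, gene: str) -> float:
    odds = odds_ratio * p0 / (1.0 - p0)
    p1 = odds / (1.0 + odds)
    if not 0.0 < p1 < 1.0:
        raise CohortError(
            f"gene {gene}: implied carrier probability {p1} outside (0,1)")
    return p1


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of a synthetic family cohort."""

    genes: tuple[GeneSpec, ...]
    n_families: int = 43
    family_size_probs: tuple[float, float, float, float] = (
        0.15, 0.20, 0.45, 0.20)  # sizes 1..4; mean 2.7 ~= 116/43
    case_fraction_target: float = 86 / 116
    pediatric_fracture_fraction_of_cases: float = 21 / 86
    family_correlation_mode: str = "transmission"  # or "independent"
    contaminate_fraction: float = 0.0
    seed: int = 42

    def __post_init__(self) -> None:
        if not self.genes:
            raise CohortError("config needs at least one gene")
        if self.n_families < 1:
            raise CohortError("n_families must be >= 1")
        probs = np.asarray(self.family_size_probs, dtype=float)
        if probs.min() < 0 or not math.isclose(probs.sum(), 1.0,
                                               rel_tol=1e-9):
            raise CohortError("family_size_probs must be a distribution")
        for frac in (self.case_fraction_target,
                     self.pediatric_fracture_fraction_of_cases,
                     self.contaminate_fraction):
            if not 0.0 <= frac <= 1.0:
                raise CohortError("fractions must lie in [0,1]")
        if self.family_correlation_mode not in ("transmission",
                                                "independent"):
            raise CohortError(
                f"unknown correlation mode {self.family_correlation_mode!r}")


@dataclass
class CarrierLedger:
    """Generator bookkeeping: true carrier counts per gene and group."""

    case_carriers: dict[str, int] = field(default_factory=dict)
    control_carriers: dict[str, int] = field(default_factory=dict)


# ----------------------------------------------------------------- subjects

_ROLE_LAYOUTS = {
    1: (TrioRole.OTHER,),
    2: (TrioRole.MOTHER, TrioRole.CHILD),
    3: (TrioRole.MOTHER, TrioRole.FATHER, TrioRole.CHILD),
    4: (TrioRole.MOTHER, TrioRole.FATHER, TrioRole.CHILD, TrioRole.CHILD),
}


def _make_subjects(config: SimulationConfig,
                   rng: np.random.Generator) -> list[Subject]:
    subjects: list[Subject] = []
    sizes = rng.choice([1, 2, 3, 4], size=config.n_families,
                       p=config.family_size_probs)
    counter = 0
    for fam_idx, size in enumerate(sizes):
        fam_id = f"FAM{fam_idx + 1:03d}"
        for role in _ROLE_LAYOUTS[int(size)]:
            counter += 1
            is_case = rng.random() < config.case_fraction_target
            fracture = Fracture.NONE
            if is_case and (rng.random()
                            < config.pediatric_fracture_fraction_of_cases):
                fracture = Fracture.PEDIATRIC_FRACTURE
            if role is TrioRole.MOTHER:
                sex = Sex.F
            elif role is TrioRole.FATHER:
                sex = Sex.M
            else:
                sex = Sex.F if rng.random() < 0.523 else Sex.M
            subjects.append(Subject(
                subject_id=f"S{counter:04d}",
                family_id=fam_id,
                group=Group.CASE if is_case else Group.CONTROL,
                fracture=fracture,
                sex=sex,
                trio_role=role,
            ))
    return subjects


def _target_probs(spec: GeneSpec, subjects: Sequence[Subject]) -> np.ndarray:
    out = np.empty(len(subjects))
    for i, s in enumerate(subjects):
        if s.group is Group.CONTROL:
            out[i] = spec.control_carrier_prob
        elif s.fracture is Fracture.PEDIATRIC_FRACTURE:
            out[i] = spec.fracture_carrier_prob
        else:
            out[i] = spec.case_carrier_prob
    return out


# ----------------------------------------------------------------- variants

_CUMSUM_CACHE: dict[tuple, np.ndarray] = {}


def _sample_categorical(rng: np.random.Generator,
                        weights: tuple[float, ...]) -> int:
    cum = _CUMSUM_CACHE.get(weights)
    if cum is None:
        cum = np.cumsum(weights)
        _CUMSUM_CACHE[weights] = cum
    return int(np.searchsorted(cum, rng.random() * cum[-1]))


class _VariantFactory:
    """Allocates unique variant identities (locus + alleles) per gene."""

    def __init__(self, rng: np.random.Generator):
        self._rng = rng
        self._counters: dict[str, int] = {}

    def new_variant(self, gene: str, gene_index: int,
                    chrom: str, profile: AnnotationProfile) -> dict:
        k = self._counters.get(gene, 0)
        self._counters[gene] = k + 1
        rng = self._rng
        ref_i = int(rng.integers(4))
        alt_i = (ref_i + 1 + int(rng.integers(3))) % 4
        csq = _CSQ_ORDER[_sample_categorical(
            rng, profile.consequence_weights)]
        clinvar = _CLINVAR_ORDER[_sample_categorical(
            rng, profile.clinvar_weights)]
        if rng.random() < profile.p_novel:
            af = None
        else:
            lo, hi = profile.af_range
            af = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
        return {
            "gene_symbol": gene,
            "chrom": chrom,
            "pos": 1000 + gene_index * 100_000 + k,
            "ref": str(_BASES[ref_i]),
            "alt": str(_BASES[alt_i]),
            "consequence": csq,
            "clinvar": clinvar,
            "gnomad_af": af,
        }


def _qc_fields(rng: np.random.Generator, zygosity: Zygosity,
               contaminate: bool) -> dict:
    fields = {
        "qual": float(rng.uniform(50, 1000)),
        "depth": int(rng.integers(15, 80)),
        "vaf": float(rng.uniform(0.30, 0.70)) if zygosity is Zygosity.HET
        else float(rng.uniform(0.85, 1.0)),
        "mapping_quality": float(rng.uniform(50, 60)),
        "strand_bias_p": float(rng.uniform(0.01, 1.0)),
    }
    if contaminate:
        which = int(rng.integers(5))
        if which == 0:
            fields["qual"] = float(rng.uniform(0, 29.9))
        elif which == 1:
            fields["depth"] = int(rng.integers(0, 10))
        elif which == 2:
            fields["vaf"] = float(rng.uniform(0.01, 0.19))
        elif which == 3:
            fields["mapping_quality"] = float(rng.uniform(0, 39.9))
        else:
            fields["strand_bias_p"] = float(rng.uniform(1e-6, 0.001))
    return fields


def _make_call(subject_id: str, variant: dict, zygosity: Zygosity,
               rng: np.random.Generator, contaminate: bool) -> VariantCall:
    return VariantCall(subject_id=subject_id, zygosity=zygosity,
                       **variant, **_qc_fields(rng, zygosity, contaminate))


def _gene_chrom(spec: GeneSpec, gene_index: int) -> str:
    if spec.chrom is not None:
        return spec.chrom
    if spec.gene_symbol.startswith("MT-"):
        return "MT"
    return str(1 + gene_index % 22)


def _n_extra_variants(rng: np.random.Generator, mean: float) -> int:
    return int(rng.poisson(mean - 1.0))


# ---------------------------------------------------------------- generator


def generate_cohort_with_ledger(
    config: SimulationConfig,
) -> tuple[Cohort, CarrierLedger]:
    """Generate a cohort plus the generator's true carrier bookkeeping."""
    rng = np.random.default_rng(config.seed)
    subjects = _make_subjects(config, rng)
    factory = _VariantFactory(rng)
    ledger = CarrierLedger()
    calls: list[VariantCall] = []
    contam = config.contaminate_fraction

    fam_members: dict[str, list[int]] = {}
    for i, s in enumerate(subjects):
        fam_members.setdefault(s.family_id, []).append(i)

    for gi, spec in enumerate(config.genes):
        chrom = _gene_chrom(spec, gi)
        targets = _target_probs(spec, subjects)
        carrier_variants: dict[int, list[dict]] = {}

        if config.family_correlation_mode == "independent":
            draws = rng.random(len(subjects)) < targets
            for i in np.nonzero(draws)[0]:
                n_var = 1 + _n_extra_variants(
                    rng, spec.mean_variants_per_carrier)
                carrier_variants[int(i)] = [
                    factory.new_variant(spec.gene_symbol, gi, chrom,
                                        spec.annotation_profile)
                    for _ in range(n_var)
                ]
        else:
            for fam_id in fam_members:
                idx = fam_members[fam_id]
                founders = [i for i in idx
                            if subjects[i].trio_role is not TrioRole.CHILD]
                children = [i for i in idx
                            if subjects[i].trio_role is TrioRole.CHILD]
                for i in founders:
                    if rng.random() < targets[i]:
                        n_var = 1 + _n_extra_variants(
                            rng, spec.mean_variants_per_carrier)
                        carrier_variants[i] = [
                            factory.new_variant(spec.gene_symbol, gi, chrom,
                                                spec.annotation_profile)
                            for _ in range(n_var)
                        ]
                # analytic probability that a child inherits >=1 variant
                # from a carrier parent: P(transmit) = p_parent *
                # (1 - 0.5 * E[0.5^extra]); extra ~ Poisson(mean-1) so
                # E[0.5^extra] = exp(-(mean-1)/2).
                mean_extra = spec.mean_variants_per_carrier - 1.0
                no_transmit_one = 0.5 * math.exp(-mean_extra / 2.0)
                q_parent = [targets[i] * (1.0 - no_transmit_one)
                            for i in founders]
                q_inherit = 1.0 - math.prod(1.0 - q for q in q_parent)
                for i in children:
                    inherited: list[dict] = []
                    for f in founders:
                        for variant in carrier_variants.get(f, []):
                            if rng.random() < 0.5:
                                inherited.append(variant)
                    pt = targets[i]
                    u = rng.random()
                    if pt >= q_inherit:
                        top_up = (0.0 if q_inherit >= 1.0 else
                                  (pt - q_inherit) / (1.0 - q_inherit))
                        if inherited:
                            carrier = True
                        else:
                            carrier = u < top_up
                            inherited = []
                    else:
                        # thin: keep inherited carriage with prob pt/q
                        carrier = bool(inherited) and u < pt / q_inherit
                    if carrier:
                        if not inherited:
                            n_var = 1 + _n_extra_variants(
                                rng, spec.mean_variants_per_carrier)
                            inherited = [
                                factory.new_variant(
                                    spec.gene_symbol, gi, chrom,
                                    spec.annotation_profile)
                                for _ in range(n_var)
                            ]
                        carrier_variants[i] = list(inherited)

        n_case = n_ctrl = 0
        for i, variants in sorted(carrier_variants.items()):
            s = subjects[i]
            if s.group is Group.CASE:
                n_case += 1
            else:
                n_ctrl += 1
            for variant in variants:
                zyg = (Zygosity.HOM
                       if rng.random() < spec.annotation_profile.p_hom
                       else Zygosity.HET)
                contaminate = contam > 0 and rng.random() < contam
                calls.append(_make_call(s.subject_id, variant, zyg, rng,
                                        contaminate))
        ledger.case_carriers[spec.gene_symbol] = n_case
        ledger.control_carriers[spec.gene_symbol] = n_ctrl

    return Cohort(subjects=subjects, calls=calls), ledger


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a synthetic family cohort (deterministic given seed)."""
    cohort, _ = generate_cohort_with_ledger(config)
    return cohort


def generate_null_cohort(config: SimulationConfig) -> Cohort:
    """As :func:`generate_cohort` with every odds ratio forced to 1."""
    null_genes = tuple(
        replace(g, case_odds_ratio=1.0, fracture_odds_ratio=1.0)
        for g in config.genes
    )
    return generate_cohort(replace(config, genes=null_genes))


# ------------------------------------------------------------ trio planting


@dataclass(frozen=True)
class TrioPlant:
    """A complex-inheritance pattern to plant in one synthetic trio.

    ``pattern`` is one of ``compound_het`` (two variants in ``genes[0]``,
    one per parent), ``trans_het_pathway`` (one maternal variant in
    ``genes[0]`` and one paternal in ``genes[1]``, both members of
    ``gene_set``), or ``additive_load`` (moderate-effect variants from both
    parents summing to at least ``target_load``).
    """

    pattern: str
    genes: tuple[str, ...]
    gene_set: Optional[GeneSet] = None
    target_load: float = 15.0

    def __post_init__(self) -> None:
        if self.pattern not in ("compound_het", "trans_het_pathway",
                                "additive_load"):
            raise CohortError(f"unknown trio pattern {self.pattern!r}")
        if self.pattern == "trans_het_pathway":
            if len(self.genes) < 2:
                raise CohortError("trans_het_pathway needs two genes")
            if self.gene_set is None:
                raise CohortError("trans_het_pathway needs its gene set")
        elif not self.genes:
            raise CohortError("plant needs at least one gene")


def _plant_variant(factory: _VariantFactory, gene: str, gene_index: int,
                   consequence: Consequence,
                   rng: np.random.Generator) -> dict:
    profile = AnnotationProfile()
    v = factory.new_variant(gene, gene_index, _gene_chrom(
        GeneSpec(gene, 0.1), gene_index), profile)
    v["consequence"] = consequence
    v["clinvar"] = ClinVar.VUS
    v["gnomad_af"] = 0.05  # present and not rare: no damage add-ons
    return v


def generate_trio_fixtures(
    plants: Sequence[TrioPlant],
    seed: int = 42,
    n_trios: int = 11,
) -> Cohort:
    """Build complete parent-parent-child trios with planted patterns.

    The first ``len(plants)`` trios each receive one planted pattern;
    remaining trios carry only a single maternally inherited synonymous
    variant in a private background gene, which satisfies no detector.
    """
    if len(plants) > n_trios:
        raise CohortError("more plants than trios")
    rng = np.random.default_rng(seed)
    factory = _VariantFactory(rng)
    subjects: list[Subject] = []
    calls: list[VariantCall] = []
    gene_index = 1000  # keep loci clear of study genes

    def add_call(sid: str, variant: dict) -> None:
        calls.append(_make_call(sid, variant, Zygosity.HET, rng, False))

    for t in range(n_trios):
        fam = f"TRIO{t + 1:03d}"
        mother = Subject(subject_id=f"{fam}_M", family_id=fam,
                         group=Group.CASE, sex=Sex.F,
                         trio_role=TrioRole.MOTHER)
        father = Subject(subject_id=f"{fam}_F", family_id=fam,
                         group=Group.CONTROL, sex=Sex.M,
                         trio_role=TrioRole.FATHER)
        child = Subject(subject_id=f"{fam}_C", family_id=fam,
                        group=Group.CASE,
                        fracture=Fracture.PEDIATRIC_FRACTURE,
                        trio_role=TrioRole.CHILD)
        subjects.extend([mother, father, child])

        plant = plants[t] if t < len(plants) else None
        if plant is None:
            gene_index += 1
            v = _plant_variant(factory, f"BG{t:04d}", gene_index,
                               Consequence.SYNONYMOUS, rng)
            add_call(mother.subject_id, v)
            add_call(child.subject_id, v)
        elif plant.pattern == "compound_het":
            gene = plant.genes[0]
            gene_index += 1
            v1 = _plant_variant(factory, gene, gene_index,
                                Consequence.MISSENSE, rng)
            v2 = _plant_variant(factory, gene, gene_index,
                                Consequence.MISSENSE, rng)
            add_call(mother.subject_id, v1)
            add_call(father.subject_id, v2)
            add_call(child.subject_id, v1)
            add_call(child.subject_id, v2)
        elif plant.pattern == "trans_het_pathway":
            gene_a, gene_b = plant.genes[0], plant.genes[1]
            gene_index += 1
            va = _plant_variant(factory, gene_a, gene_index,
                                Consequence.MISSENSE, rng)
            gene_index += 1
            vb = _plant_variant(factory, gene_b, gene_index,
                                Consequence.MISSENSE, rng)
            add_call(mother.subject_id, va)
            add_call(father.subject_id, vb)
            add_call(child.subject_id, va)
            add_call(child.subject_id, vb)
        else:  # additive_load: moderate variants from both parents
            genes = list(plant.genes)
            load = 0.0
            parent_cycle = [mother.subject_id, father.subject_id]
            k = 0
            while load < plant.target_load:
                gene = genes[k % len(genes)]
                gene_index += 1
                v = _plant_variant(factory, gene, gene_index,
                                   Consequence.MISSENSE, rng)
                parent = parent_cycle[k % 2]
                add_call(parent, v)
                add_call(child.subject_id, v)
                load += 5.0
                k += 1

    return Cohort(subjects=subjects, calls=calls)


# -------------------------------------------------------- study-like panel


def study_like_gene_specs() -> tuple[GeneSpec, ...]:
    """Gene panel mirroring the study's printed per-gene carrier rates.

    Control carrier probabilities and case odds ratios are taken from the
    published per-gene 2x2 tables; mitochondrial genes additionally carry
    within-case fracture odds ratios in the printed 4-8 range.  A layer of
    null background genes with odds ratio 1 spans the same prevalence
    range.
    """
    specs: list[GeneSpec] = [
        # genome-wide significant structural genes (control prev, case OR)
        GeneSpec("FLG-AS1", 0.10, 20.8, chrom="1"),
        GeneSpec("PCDHGA1", 0.167, 16.5, chrom="5"),
        GeneSpec("SYNE1", 0.233, 12.4, chrom="6"),
        GeneSpec("RELN", 0.02, 40.0, chrom="7"),
        GeneSpec("OBSCN", 0.033, 30.4, chrom="1"),
        GeneSpec("HSPG2", 0.133, 12.1, chrom="1"),
        GeneSpec("KRT74", 0.133, 12.1, chrom="17"),
        # collagen pathway members
        GeneSpec("COL5A1", 0.167, 8.4, chrom="9"),
        GeneSpec("COL18A1", 0.133, 9.9, chrom="21"),
        GeneSpec("COL17A1", 0.02, 20.0, chrom="10"),
        GeneSpec("PLOD1", 0.10, 3.0, chrom="1"),
        # HLA axis
        GeneSpec("HLA-B", 0.30, 6.8, chrom="6"),
        GeneSpec("HLA-A", 0.30, 4.6, chrom="6"),
        GeneSpec("HLA-C", 0.033, 11.9, chrom="6"),
        GeneSpec("HLA-DQA1", 0.20, 4.0, chrom="6"),
        # mitochondrial genes with fracture modifiers
        GeneSpec("MT-ND5", 0.033, 14.8, fracture_odds_ratio=4.4),
        GeneSpec("MT-ATP6", 0.02, 8.0, fracture_odds_ratio=8.3),
        GeneSpec("MT-CO1", 0.05, 5.0, fracture_odds_ratio=5.3),
        GeneSpec("MT-ND4", 0.02, 6.0, fracture_odds_ratio=5.7),
        GeneSpec("MT-CYB", 0.02, 6.0, fracture_odds_ratio=4.4),
    ]
    # null background layer across the observed prevalence range
    prevalences = np.linspace(0.05, 0.40, 40)
    for i, p in enumerate(prevalences):
        specs.append(GeneSpec(f"NULL{i:03d}", float(round(p, 4)), 1.0))
    return tuple(specs)
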