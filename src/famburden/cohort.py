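"""Domain types for family-based case-control variant cohorts.

The statistical unit throughout the package is the *subject*: one sequenced
individual carrying a family id, a case/control label and optional phenotype
flags.  Variant observations are always attached to a subject and are
aggregated to subject-level carrier indicators before any testing, so that
correlated within-subject observations never masquerade as independent
samples.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

__all__ = [
    "Group",
    "Fracture",
    "Sex",
    "TrioRole",
    "Consequence",
    "Impact",
    "Zygosity",
    "ClinVar",
    "Subject",
    "VariantCall",
    "Cohort",
    "GeneSet",
    "QCThresholds",
    "CohortError",
    "classify_impact",
    "normalize_chrom",
]


class CohortError(ValueError):
    """Raised for structurally invalid cohort data (duplicates, bad enums)."""


class Group(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"


class Fracture(str, enum.Enum):
    NONE = "none"
    FRACTURE = "fracture"
    PEDIATRIC_FRACTURE = "pediatric_fracture"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


class TrioRole(str, enum.Enum):
    CHILD = "child"
    MOTHER = "mother"
    FATHER = "father"
    OTHER = "other"


class Consequence(str, enum.Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    CANONICAL_SPLICE = "canonical_splice"
    SPLICE_REGION = "splice_region"
    MISSENSE = "missense"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


class Impact(str, enum.Enum):
    HIGH = "high"
    MODERATE = "moderate"
    LOW = "low"


class Zygosity(str, enum.Enum):
    HET = "het"
    HOM = "hom"


class ClinVar(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    LB = "LB"
    B = "B"
    ABSENT = "absent"


_IMPACT_MAP = {
    Consequence.STOP_GAIN: Impact.HIGH,
    Consequence.FRAMESHIFT: Impact.HIGH,
    Consequence.CANONICAL_SPLICE: Impact.HIGH,
    Consequence.MISSENSE: Impact.MODERATE,
    Consequence.INFRAME_INDEL: Impact.MODERATE,
    Consequence.SPLICE_REGION: Impact.MODERATE,
    Consequence.SYNONYMOUS: Impact.LOW,
    Consequence.OTHER: Impact.LOW,
}

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}


def classify_impact(consequence: Consequence) -> Impact:
    """Map a functional consequence onto its impact class.

    Truncating consequences (stop gain, frameshift, canonical splice site)
    are high impact; missense, in-frame indels and splice-region variants are
    moderate; synonymous and unclassified consequences are low.
    """
    return _IMPACT_MAP[Consequence(consequence)]


def normalize_chrom(chrom: str) -> str:
    """Normalize a chromosome label to {1..22, X, Y, MT} (VCF convention).

    Accepts "chr" prefixes and the mitochondrial aliases "M", "chrM",
    "chrMT".
    """
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper()
    if c == "M":
        c = "MT"
    if c not in _VALID_CHROMS:
        raise CohortError(f"unrecognized chromosome label: {chrom!r}")
    return c


@dataclass(frozen=True)
class Subject:
    """One sequenced individual."""

    subject_id: str
    family_id: str
    group: Group
    fracture: Fracture = Fracture.NONE
    sex: Sex = Sex.UNKNOWN
    age_years: Optional[float] = None
    trio_role: TrioRole = TrioRole.OTHER

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise CohortError("subject_id must be non-empty")
        if self.age_years is not None and self.age_years < 0:
            raise CohortError(f"negative age for subject {self.subject_id}")
        if (
            self.fracture is Fracture.PEDIATRIC_FRACTURE
            and self.group is not Group.CASE
        ):
            # Fracture analyses compare strata *within* the case group.
            raise CohortError(
                f"subject {self.subject_id}: pediatric_fracture implies case"
            )


@dataclass(frozen=True)
class VariantCall:
    """One subject-by-variant observation with annotation and QC fields.

    ``gnomad_af`` is ``None`` when the variant is absent from the population
    reference (a *novel* variant).  Novelty is a distinct state and is never
    imputed to an allele frequency of zero.
    """

    subject_id: str
    gene_symbol: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    zygosity: Zygosity = Zygosity.HET
    clinvar: ClinVar = ClinVar.ABSENT
    gnomad_af: Optional[float] = None
    qual: float = 100.0
    depth: int = 30
    vaf: float = 0.5
    mapping_quality: float = 60.0
    strand_bias_p: float = 1.0
    impact: Optional[Impact] = None

    def __post_init__(self) -> None:
        if self.chrom not in _VALID_CHROMS:
            object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise CohortError(f"pos must be 1-based positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise CohortError("ref and alt alleles must be non-empty")
        if "," in self.alt:
            raise CohortError(
                f"multi-allelic alt {self.alt!r}: split to one alt per row"
            )
        if self.gnomad_af is not None and not 0.0 <= self.gnomad_af <= 1.0:
            raise CohortError(f"gnomad_af out of [0,1]: {self.gnomad_af}")
        if not 0.0 <= self.vaf <= 1.0:
            raise CohortError(f"vaf out of [0,1]: {self.vaf}")
        if not 0.0 < self.strand_bias_p <= 1.0:
            raise CohortError(
                f"strand_bias_p out of (0,1]: {self.strand_bias_p}"
            )
        if self.qual < 0 or self.depth < 0 or self.mapping_quality < 0:
            raise CohortError("quality fields must be nonnegative")
        expected = classify_impact(self.consequence)
        if self.impact is None:
            object.__setattr__(self, "impact", expected)
        elif self.impact is not expected:
            raise CohortError(
                f"impact {self.impact.value!r} disagrees with consequence "
                f"{self.consequence.value!r} (expected {expected.value!r})"
            )

    @property
    def is_novel(self) -> bool:
        return self.gnomad_af is None

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GeneSet:
    """A named, non-empty collection of unique gene symbols."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise CohortError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise CohortError(f"gene set {self.name!r} has duplicate genes")
        self.genes = genes

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class QCThresholds:
    """Variant retention thresholds.

    A call is retained iff QUAL >= ``qual_min``, depth >= ``depth_min``,
    in-read VAF >= ``vaf_min``, Fisher strand-bias p strictly >
    ``strand_bias_p_min``, mapping quality >= ``mq_min`` and population MAF
    < ``maf_max`` (novel variants pass the MAF criterion).
    """

    qual_min: float = 30.0
    depth_min: int = 10
    vaf_min: float = 0.20
    mq_min: float = 40.0
    strand_bias_p_min: float = 0.001
    maf_max: float = 0.2

    def __post_init__(self) -> None:
        for name in ("qual_min", "depth_min", "vaf_min", "mq_min",
                     "strand_bias_p_min", "maf_max"):
            if getattr(self, name) < 0:
                raise CohortError(f"threshold {name} must be nonnegative")
        if not 0.0 <= self.vaf_min <= 1.0:
            raise CohortError("vaf_min must lie in [0,1]")
        if not 0.0 <= self.maf_max <= 1.0:
            raise CohortError("maf_max must lie in [0,1]")


@dataclass
class Cohort:
    """Subjects plus their variant observations.

    Invariants enforced on construction: subject ids unique, every call's
    subject resolves, and no duplicate (subject, chrom, pos, ref, alt) rows
    (duplicates would distort carrier counting and are a hard error, never a
    silent dedup).
    """

    subjects: list[Subject] = field(default_factory=list)
    calls: list[VariantCall] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        seen: set[str] = set()
        for sid in ids:
            if sid in seen:
                raise CohortError(f"duplicate subject_id: {sid!r}")
            seen.add(sid)
        keys: set[tuple] = set()
        for call in self.calls:
            if call.subject_id not in seen:
                raise CohortError(
                    f"call references unknown subject {call.subject_id!r}"
                )
            if call.key in keys:
                raise CohortError(
                    f"duplicate variant row for subject {call.subject_id!r} "
                    f"at {call.chrom}:{call.pos} {call.ref}>{call.alt}"
                )
            keys.add(call.key)

    @property
    def n_cases(self) -> int:
        return sum(1 for s in self.subjects if s.group is Group.CASE)

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self.subjects if s.group is Group.CONTROL)

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise CohortError(f"unknown subject {subject_id!r}")

    def calls_for(self, subject_id: str) -> list[VariantCall]:
        if subject_id not in {s.subject_id for s in self.subjects}:
            raise CohortError(f"unknown subject {subject_id!r}")
        return [c for c in self.calls if c.subject_id == subject_id]

    def families(self) -> dict[str, list[Subject]]:
        fams: dict[str, list[Subject]] = {}
        for s in self.subjects:
            fams.setdefault(s.family_id, []).append(s)
        return fams

    def subset(self, subject_ids: Iterable[str]) -> "Cohort":
        keep = set(subject_ids)
        return Cohort(
            subjects=[s for s in self.subjects if s.subject_id in keep],
            calls=[c for c in self.calls if c.subject_id in keep],
        )

    def labels(self) -> dict[str, Group]:
        return {s.subject_id: s.group for s in self.subjects}
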