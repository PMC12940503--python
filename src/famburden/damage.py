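"""Additive variant damage scoring.

Each variant scores a base value by functional consequence (stop gain and
frameshift 10, canonical splice 9, missense 5, everything else 0 by
default) plus configurable add-ons: ClinVar pathogenic/likely-pathogenic
classification, homozygosity, novelty (absent from the population
reference) and rarity (population MAF < 0.01).  Novelty and rarity are
mutually exclusive — a novel variant has no frequency to be rare by.  The
add-on magnitudes default to 4/2/2/1, chosen so no single non-ClinVar
add-on can promote a missense variant above a splice variant; they are
fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import ClinVar, Cohort, Consequence, VariantCall, Zygosity

__all__ = ["DamageWeights", "damage_score_variant", "subject_damage_load"]

_DEFAULT_BASE = {
    Consequence.STOP_GAIN: 10.0,
    Consequence.FRAMESHIFT: 10.0,
    Consequence.CANONICAL_SPLICE: 9.0,
    Consequence.MISSENSE: 5.0,
}


@dataclass(frozen=True)
class DamageWeights:
    """Base consequence scores and add-on weights (all nonnegative)."""

    base: dict = field(default_factory=lambda: dict(_DEFAULT_BASE))
    clinvar_plp: float = 4.0
    homozygous: float = 2.0
    novel: float = 2.0
    rare_maf_lt_001: float = 1.0
    rare_maf_threshold: float = 0.01

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.base.values()):
            raise ValueError("base weights must be nonnegative")
        for name in ("clinvar_plp", "homozygous", "novel", "rare_maf_lt_001"):
            if getattr(self, name) < 0:
                raise ValueError(f"add-on weight {name} must be nonnegative")

    def base_score(self, consequence: Consequence) -> float:
        return float(self.base.get(Consequence(consequence), 0.0))


def damage_score_variant(
    v: VariantCall, weights: DamageWeights | None = None
) -> float:
    """Score one variant: consequence base plus qualifying add-ons."""
    w = weights or DamageWeights()
    score = w.base_score(v.consequence)
    if v.clinvar in (ClinVar.P, ClinVar.LP):
        score += w.clinvar_plp
    if v.zygosity is Zygosity.HOM:
        score += w.homozygous
    if v.gnomad_af is None:
        score += w.novel
    elif v.gnomad_af < w.rare_maf_threshold:
        score += w.rare_maf_lt_001
    return score


def subject_damage_load(
    cohort: Cohort,
    subject_id: str,
    weights: DamageWeights | None = None,
) -> float:
    """Total damage score over a subject's retained calls (0 if none)."""
    w = weights or DamageWeights()
    return sum(damage_score_variant(c, w)
               for c in cohort.calls_for(subject_id))
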