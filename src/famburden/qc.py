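"""Variant quality-control filtering.

A call survives QC only if it passes every criterion; removals are audited
against the *first* failing criterion in a fixed order (QUAL, depth, VAF,
strand bias, mapping quality, population MAF), so the audit counts sum to
the number of calls removed.  All thresholds are inclusive except strand
bias, which is a strict ``p > threshold``; novel variants (no population
frequency) pass the MAF criterion by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import Cohort, QCThresholds, VariantCall

CRITERIA = ("qual", "depth", "vaf", "strand_bias", "mapping_quality", "maf")


@dataclass
class QCAudit:
    """Per-criterion removal counts from one filtering pass."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in CRITERIA})

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained


def _first_failure(call: VariantCall, t: QCThresholds) -> str | None:
    if call.qual < t.qual_min:
        return "qual"
    if call.depth < t.depth_min:
        return "depth"
    if call.vaf < t.vaf_min:
        return "vaf"
    if not call.strand_bias_p > t.strand_bias_p_min:
        return "strand_bias"
    if call.mapping_quality < t.mq_min:
        return "mapping_quality"
    if call.gnomad_af is not None and not call.gnomad_af < t.maf_max:
        return "maf"
    return None


def apply_qc_filters(
    calls: list[VariantCall],
    thresholds: QCThresholds | None = None,
) -> tuple[list[VariantCall], QCAudit]:
    """Partition calls into (retained, audit-of-removals).

    Idempotent: filtering the retained list again removes nothing.
    """
    t = thresholds or QCThresholds()
    retained: list[VariantCall] = []
    audit = QCAudit(n_input=len(calls))
    for call in calls:
        failure = _first_failure(call, t)
        if failure is None:
            retained.append(call)
        else:
            audit.removed[failure] += 1
    audit.n_retained = len(retained)
    return retained, audit


def qc_filter_cohort(
    cohort: Cohort, thresholds: QCThresholds | None = None
) -> tuple[Cohort, QCAudit]:
    """QC-filter a cohort's calls, keeping all subjects."""
    retained, audit = apply_qc_filters(cohort.calls, thresholds)
    return Cohort(subjects=list(cohort.subjects), calls=retained), audit
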