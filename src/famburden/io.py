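"""Readers and writers for subject tables, variant tables and gene sets.

Tables are delimited text (comma or tab, auto-detected), UTF-8, with a
required header.  Column names are matched case-insensitively through a
synonym map so exports from different annotation pipelines parse without
renaming.  Gene sets use the GMT convention: one set per line, tab-separated
``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import csv
import math
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

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
    normalize_chrom,
)

PathLike = Union[str, Path]

# Canonical column -> accepted header spellings (lower-cased).
SUBJECT_COLUMNS = {
    "subject_id": {"subject_id", "subject", "sample_id", "sample", "id"},
    "family_id": {"family_id", "family", "fid", "pedigree_id"},
    "group": {"group", "status", "phenotype", "case_control", "label"},
    "fracture": {"fracture", "fracture_status"},
    "sex": {"sex", "gender"},
    "age_years": {"age_years", "age"},
    "trio_role": {"trio_role", "role", "relationship"},
}
SUBJECT_REQUIRED = ("subject_id", "family_id", "group")

VARIANT_COLUMNS = {
    "subject_id": {"subject_id", "subject", "sample_id", "sample"},
    "gene_symbol": {"gene_symbol", "gene", "symbol", "gene_name"},
    "chrom": {"chrom", "chr", "chromosome"},
    "pos": {"pos", "position", "start"},
    "ref": {"ref", "reference", "ref_allele"},
    "alt": {"alt", "alternate", "alt_allele"},
    "consequence": {"consequence", "effect", "variant_effect"},
    "impact": {"impact"},
    "zygosity": {"zygosity", "genotype_class"},
    "clinvar": {"clinvar", "clinvar_significance", "clin_sig"},
    "gnomad_af": {"gnomad_af", "af", "population_af", "maf"},
    "qual": {"qual", "quality"},
    "depth": {"depth", "dp", "read_depth"},
    "vaf": {"vaf", "allele_fraction", "ab"},
    "mapping_quality": {"mapping_quality", "mq", "mapq"},
    "strand_bias_p": {"strand_bias_p", "fs_p", "strand_bias"},
}
VARIANT_REQUIRED = (
    "subject_id", "gene_symbol", "chrom", "pos", "ref", "alt", "consequence",
)

# Annotation-pipeline consequence spellings -> canonical enum values.
CONSEQUENCE_ALIASES = {
    "stop_gain": Consequence.STOP_GAIN,
    "stop_gained": Consequence.STOP_GAIN,
    "stopgain": Consequence.STOP_GAIN,
    "nonsense": Consequence.STOP_GAIN,
    "frameshift": Consequence.FRAMESHIFT,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "canonical_splice": Consequence.CANONICAL_SPLICE,
    "splice_acceptor_variant": Consequence.CANONICAL_SPLICE,
    "splice_donor_variant": Consequence.CANONICAL_SPLICE,
    "splice_acceptor": Consequence.CANONICAL_SPLICE,
    "splice_donor": Consequence.CANONICAL_SPLICE,
    "splice_region": Consequence.SPLICE_REGION,
    "splice_region_variant": Consequence.SPLICE_REGION,
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "inframe_indel": Consequence.INFRAME_INDEL,
    "inframe_insertion": Consequence.INFRAME_INDEL,
    "inframe_deletion": Consequence.INFRAME_INDEL,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
    "other": Consequence.OTHER,
}

CLINVAR_ALIASES = {
    "p": ClinVar.P,
    "pathogenic": ClinVar.P,
    "lp": ClinVar.LP,
    "likely_pathogenic": ClinVar.LP,
    "likely pathogenic": ClinVar.LP,
    "vus": ClinVar.VUS,
    "uncertain_significance": ClinVar.VUS,
    "lb": ClinVar.LB,
    "likely_benign": ClinVar.LB,
    "likely benign": ClinVar.LB,
    "b": ClinVar.B,
    "benign": ClinVar.B,
    "absent": ClinVar.ABSENT,
    "": ClinVar.ABSENT,
    "na": ClinVar.ABSENT,
    ".": ClinVar.ABSENT,
}


class TableFormatError(CohortError):
    """Malformed delimited input (missing columns, bad values)."""


def _sniff_delimiter(path: Path) -> str:
    with open(path, encoding="utf-8", newline="") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def _read_rows(path: PathLike, delimiter: Optional[str]) -> tuple[list[str], list[dict]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise TableFormatError(f"{path}: empty file, header required")
        fields = [f.strip() for f in reader.fieldnames]
        rows = [dict(zip(fields, (v if v is not None else "" for v in row.values())))
                for row in reader]
    return fields, rows


def _resolve_columns(fields: Sequence[str], synonyms: dict, required: Sequence[str],
                     path: PathLike) -> dict[str, str]:
    lower = {f.lower(): f for f in fields}
    mapping: dict[str, str] = {}
    for canonical, names in synonyms.items():
        for name in names:
            if name in lower:
                mapping[canonical] = lower[name]
                break
    missing = [c for c in required if c not in mapping]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    return mapping


def _enum_from(value: str, enum_cls, field_name: str, row_num: int):
    token = value.strip()
    for member in enum_cls:
        if member.value.lower() == token.lower():
            return member
    raise TableFormatError(
        f"row {row_num}: unrecognized {field_name} value {value!r}"
    )


def _float_or_none(value: str, field_name: str, row_num: int) -> Optional[float]:
    token = value.strip()
    if token in ("", "na", "NA", ".", "None"):
        return None
    try:
        x = float(token)
    except ValueError:
        raise TableFormatError(
            f"row {row_num}: malformed numeric {field_name}={value!r}"
        ) from None
    if math.isnan(x):
        return None
    return x


def read_subject_table(path: PathLike, delimiter: Optional[str] = None) -> list[Subject]:
    """Parse a subject/pedigree table into :class:`Subject` records.

    Enum-valued columns are case-insensitive; a duplicated subject id or a
    missing required column is a hard error.
    """
    fields, rows = _read_rows(path, delimiter)
    cols = _resolve_columns(fields, SUBJECT_COLUMNS, SUBJECT_REQUIRED, path)
    subjects: list[Subject] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        sid = row[cols["subject_id"]].strip()
        if sid in seen:
            raise TableFormatError(f"{path}: duplicate subject_id {sid!r}")
        seen.add(sid)
        kwargs = dict(
            subject_id=sid,
            family_id=row[cols["family_id"]].strip(),
            group=_enum_from(row[cols["group"]], Group, "group", i),
        )
        if "fracture" in cols and row[cols["fracture"]].strip():
            kwargs["fracture"] = _enum_from(
                row[cols["fracture"]], Fracture, "fracture", i)
        if "sex" in cols and row[cols["sex"]].strip():
            kwargs["sex"] = _enum_from(row[cols["sex"]], Sex, "sex", i)
        if "age_years" in cols:
            kwargs["age_years"] = _float_or_none(
                row[cols["age_years"]], "age_years", i)
        if "trio_role" in cols and row[cols["trio_role"]].strip():
            kwargs["trio_role"] = _enum_from(
                row[cols["trio_role"]], TrioRole, "trio_role", i)
        subjects.append(Subject(**kwargs))
    return subjects


def read_variant_table(path: PathLike, delimiter: Optional[str] = None) -> list[VariantCall]:
    """Parse an annotated variant table into :class:`VariantCall` records.

    Empty/``NA`` population-frequency cells map to the novel state (``None``),
    never to 0.0.  Unresolvable consequence strings downgrade to ``other``
    with a warning; malformed numerics are hard errors naming the row.
    """
    fields, rows = _read_rows(path, delimiter)
    cols = _resolve_columns(fields, VARIANT_COLUMNS, VARIANT_REQUIRED, path)
    calls: list[VariantCall] = []
    for i, row in enumerate(rows, start=2):
        raw_csq = row[cols["consequence"]].strip().lower()
        csq = CONSEQUENCE_ALIASES.get(raw_csq)
        if csq is None:
            warnings.warn(
                f"{path} row {i}: unknown consequence {raw_csq!r}, "
                "recorded as 'other'",
                stacklevel=2,
            )
            csq = Consequence.OTHER
        pos_raw = row[cols["pos"]].strip()
        try:
            pos = int(pos_raw)
        except ValueError:
            raise TableFormatError(
                f"row {i}: malformed numeric pos={pos_raw!r}") from None
        kwargs = dict(
            subject_id=row[cols["subject_id"]].strip(),
            gene_symbol=row[cols["gene_symbol"]].strip(),
            chrom=normalize_chrom(row[cols["chrom"]]),
            pos=pos,
            ref=row[cols["ref"]].strip(),
            alt=row[cols["alt"]].strip(),
            consequence=csq,
        )
        if "zygosity" in cols and row[cols["zygosity"]].strip():
            kwargs["zygosity"] = _enum_from(
                row[cols["zygosity"]], Zygosity, "zygosity", i)
        if "clinvar" in cols:
            token = row[cols["clinvar"]].strip().lower()
            if token in CLINVAR_ALIASES:
                kwargs["clinvar"] = CLINVAR_ALIASES[token]
            else:
                kwargs["clinvar"] = _enum_from(
                    row[cols["clinvar"]], ClinVar, "clinvar", i)
        if "gnomad_af" in cols:
            kwargs["gnomad_af"] = _float_or_none(
                row[cols["gnomad_af"]], "gnomad_af", i)
        for numeric, cast in (
            ("qual", float), ("depth", int), ("vaf", float),
            ("mapping_quality", float), ("strand_bias_p", float),
        ):
            if numeric in cols and row[cols[numeric]].strip():
                val = _float_or_none(row[cols[numeric]], numeric, i)
                if val is not None:
                    kwargs[numeric] = cast(val)
        calls.append(VariantCall(**kwargs))
    return calls


def write_subject_table(subjects: Iterable[Subject], path: PathLike,
                        delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["subject_id", "family_id", "group", "fracture", "sex",
                    "age_years", "trio_role"])
        for s in subjects:
            w.writerow([
                s.subject_id, s.family_id, s.group.value, s.fracture.value,
                s.sex.value,
                "" if s.age_years is None else f"{s.age_years:g}",
                s.trio_role.value,
            ])


def write_variant_table(calls: Iterable[VariantCall], path: PathLike,
                        delimiter: str = "\t") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter=delimiter)
        w.writerow(["subject_id", "gene_symbol", "chrom", "pos", "ref", "alt",
                    "consequence", "impact", "zygosity", "clinvar",
                    "gnomad_af", "qual", "depth", "vaf", "mapping_quality",
                    "strand_bias_p"])
        for c in calls:
            w.writerow([
                c.subject_id, c.gene_symbol, c.chrom, c.pos, c.ref, c.alt,
                c.consequence.value, c.impact.value, c.zygosity.value,
                c.clinvar.value,
                "" if c.gnomad_af is None else repr(c.gnomad_af),
                repr(c.qual), c.depth, repr(c.vaf),
                repr(c.mapping_quality), repr(c.strand_bias_p),
            ])


def read_gene_sets(path: PathLike) -> list[GeneSet]:
    """Parse a GMT file into :class:`GeneSet` records, in file order.

    Duplicate genes within a line are deduplicated with a warning; a line
    with no genes is a hard error.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                raise TableFormatError(
                    f"{path} line {lineno}: gene set needs "
                    "name, description and >=1 gene"
                )
            name, description = parts[0].strip(), parts[1].strip()
            genes: list[str] = []
            seen: set[str] = set()
            dupes = False
            for g in parts[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    dupes = True
                    continue
                seen.add(g)
                genes.append(g)
            if dupes:
                warnings.warn(
                    f"{path} line {lineno}: duplicate genes in set "
                    f"{name!r} deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, genes=tuple(genes),
                                description=description))
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description or "-", *gs.genes]))
            fh.write("\n")


def read_cohort(subject_path: PathLike, variant_path: PathLike,
                delimiter: Optional[str] = None) -> Cohort:
    """Read a full cohort (subject table + variant table)."""
    return Cohort(
        subjects=read_subject_table(subject_path, delimiter),
        calls=read_variant_table(variant_path, delimiter),
    )


def write_cohort(cohort: Cohort, subject_path: PathLike,
                 variant_path: PathLike, delimiter: str = "\t") -> None:
    write_subject_table(cohort.subjects, subject_path, delimiter)
    write_variant_table(cohort.calls, variant_path, delimiter)
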