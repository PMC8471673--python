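"""Readers and writers for annotated variant tables and gene-cutoff tables.

Two dialects are supported:

* ``tsv`` — a plain tab-separated table whose header matches the field names
  of :class:`~aldoprio.models.AnnotatedVariant`.  This is the canonical
  fixture format.  Absent annotations are empty cells.
* ``vcf`` — VCF 4.2 via :mod:`pysam`, with all annotations carried in INFO
  keys.  The INFO key names are configurable through :class:`VcfFieldMap`.

Both directions are exact inverses of each other: a table written and read
back compares field-for-field equal, and a field absent in the input is
absent in the record (never silently 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from pathlib import Path
from typing import Dict, Optional, Union

import pysam

from .models import AnnotatedVariant, GeneCutoffs, VariantTable

__all__ = [
    "TSV_COLUMNS",
    "VcfFieldMap",
    "VariantParseError",
    "read_annotated_variants",
    "write_variant_table",
    "load_gene_cutoffs",
]


class VariantParseError(ValueError):
    """Raised when an input row cannot be parsed; carries the line number."""


#: Canonical TSV column order (== AnnotatedVariant field order).
TSV_COLUMNS = tuple(f.name for f in dc_fields(AnnotatedVariant))

_BOOL_FIELDS = {"in_evs", "in_tgp", "in_disease_db"}
_INT_FIELDS = {"pos", "gnomad_hits", "exac_hits"}
_FLOAT_FIELDS = {"vaf", "dbsnp_maf", "cadd", "pp2_score", "sift_score"}
_REQUIRED = {"sample_id", "gene", "chrom", "pos", "ref", "alt",
             "protein_change", "consequence", "vaf"}


def _parse_cell(name: str, raw: str, lineno: int):
    raw = raw.strip()
    if raw == "":
        if name in _BOOL_FIELDS:
            return False
        if name in _REQUIRED:
            raise VariantParseError(
                f"line {lineno}: required column {name!r} is empty"
            )
        return None
    try:
        if name in _BOOL_FIELDS:
            low = raw.lower()
            if low in {"true", "1", "yes"}:
                return True
            if low in {"false", "0", "no"}:
                return False
            raise ValueError(raw)
        if name in _INT_FIELDS:
            return int(raw)
        if name in _FLOAT_FIELDS:
            return float(raw)
    except ValueError as exc:
        raise VariantParseError(
            f"line {lineno}: cannot parse column {name!r} value {raw!r}"
        ) from exc
    return raw


def _format_cell(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        # shortest repr round-trips exactly; avoids trailing-zero drift
        return repr(value)
    return str(value)


def _read_tsv(path: Path) -> VariantTable:
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                missing = _REQUIRED - set(header)
                if missing:
                    raise VariantParseError(
                        f"line {lineno}: header lacks required columns "
                        f"{sorted(missing)}"
                    )
                continue
            if len(cells) != len(header):
                raise VariantParseError(
                    f"line {lineno}: expected {len(header)} columns, "
                    f"got {len(cells)}"
                )
            kwargs = {
                name: _parse_cell(name, raw, lineno)
                for name, raw in zip(header, cells)
                if name in {f.name for f in dc_fields(AnnotatedVariant)}
            }
            try:
                records.append(AnnotatedVariant(**kwargs))
            except ValueError as exc:
                raise VariantParseError(f"line {lineno}: {exc}") from exc
    return VariantTable(records=records, provenance=str(path))


def _write_tsv(table: VariantTable, path: Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for rec in table:
            fh.write(
                "\t".join(_format_cell(getattr(rec, c)) for c in TSV_COLUMNS) + "\n"
            )


@dataclass(frozen=True)
class VcfFieldMap:
    """INFO key names used to carry annotations in the VCF dialect."""

    sample_id: str = "SAMPLE"
    gene: str = "GENE"
    protein_change: str = "PCHANGE"
    consequence: str = "CSQ"
    vaf: str = "VAF"
    dbsnp_maf: str = "DBSNP_MAF"
    in_evs: str = "IN_EVS"
    in_tgp: str = "IN_TGP"
    gnomad_hits: str = "GNOMAD_HITS"
    exac_hits: str = "EXAC_HITS"
    cadd: str = "CADD"
    pp2_score: str = "PP2_SCORE"
    pp2_category: str = "PP2_CAT"
    sift_score: str = "SIFT_SCORE"
    sift_category: str = "SIFT_CAT"
    in_disease_db: str = "IN_DISEASE_DB"


_VCF_TYPES = {
    "sample_id": ("String", str),
    "gene": ("String", str),
    "protein_change": ("String", str),
    "consequence": ("String", str),
    "vaf": ("Float", float),
    "dbsnp_maf": ("Float", float),
    "in_evs": ("Flag", bool),
    "in_tgp": ("Flag", bool),
    "gnomad_hits": ("Integer", int),
    "exac_hits": ("Integer", int),
    "cadd": ("Float", float),
    "pp2_score": ("Float", float),
    "pp2_category": ("String", str),
    "sift_score": ("Float", float),
    "sift_category": ("String", str),
    "in_disease_db": ("Flag", bool),
}

_CONTIG_LENGTH = 400_000_000  # generous upper bound; positions are panel-local


def _vcf_header(fmap: VcfFieldMap) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in [str(i) for i in range(1, 23)] + ["X", "Y"]:
        header.contigs.add(chrom, length=_CONTIG_LENGTH)
    for field_name, (vcf_type, _) in _VCF_TYPES.items():
        key = getattr(fmap, field_name)
        number = 0 if vcf_type == "Flag" else 1
        header.add_meta(
            "INFO",
            items=[
                ("ID", key),
                ("Number", number),
                ("Type", vcf_type),
                ("Description", f"aldoprio annotation {field_name}"),
            ],
        )
    return header


def _write_vcf(table: VariantTable, path: Path, fmap: VcfFieldMap) -> None:
    header = _vcf_header(fmap)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in table:
            row = out.header.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, rec.alt),
            )
            for field_name, (vcf_type, caster) in _VCF_TYPES.items():
                value = getattr(rec, field_name)
                key = getattr(fmap, field_name)
                if vcf_type == "Flag":
                    if value:
                        row.info[key] = True
                elif value is not None:
                    row.info[key] = caster(value)
            out.write(row)


def _round_float(x: float) -> float:
    """Undo float32 quantisation from VCF INFO Float fields.

    All scores handled here have at most four decimal places, so rounding to
    four decimals restores the written value exactly.
    """
    return round(float(x), 4)


def _read_vcf(path: Path, fmap: VcfFieldMap) -> VariantTable:
    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for lineno, row in enumerate(vcf, start=1):
            kwargs = {"chrom": row.chrom, "pos": row.pos,
                      "ref": row.ref, "alt": row.alts[0]}
            for field_name, (vcf_type, _) in _VCF_TYPES.items():
                key = getattr(fmap, field_name)
                if vcf_type == "Flag":
                    kwargs[field_name] = key in row.info
                    continue
                value = row.info.get(key)
                if isinstance(value, tuple):
                    value = value[0]
                if value is not None and vcf_type == "Float":
                    if math.isnan(value):
                        value = None
                    else:
                        value = _round_float(value)
                kwargs[field_name] = value
            try:
                records.append(AnnotatedVariant(**kwargs))
            except (TypeError, ValueError) as exc:
                raise VariantParseError(
                    f"record {lineno} ({row.chrom}:{row.pos}): {exc}"
                ) from exc
    return VariantTable(records=records, provenance=str(path))


def read_annotated_variants(
    path: Union[str, Path],
    dialect: str = "tsv",
    field_map: Optional[VcfFieldMap] = None,
) -> VariantTable:
    """Read a variant table from ``path`` in the given dialect.

    Raises :class:`VariantParseError` with the offending line number on
    malformed rows, and a ``ValueError`` listing the allowed panel when a
    gene symbol is unknown.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "vcf":
        return _read_vcf(path, field_map or VcfFieldMap())
    raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'vcf'")


def write_variant_table(
    table: VariantTable,
    path: Union[str, Path],
    dialect: str = "tsv",
    field_map: Optional[VcfFieldMap] = None,
) -> None:
    """Write ``table`` so that :func:`read_annotated_variants` round-trips it."""
    path = Path(path)
    if dialect == "tsv":
        _write_tsv(table, path)
    elif dialect == "vcf":
        _write_vcf(table, path, field_map or VcfFieldMap())
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'tsv' or 'vcf'")


def load_gene_cutoffs(
    path: Union[str, Path], cadd_global: float = 20.0
) -> Dict[str, GeneCutoffs]:
    """Load a per-gene cutoff table (TSV: gene, msc_cadd, msc_pp2).

    One row per gene; a duplicated gene is an error.  ``cadd_global`` is
    attached to every record.
    """
    path = Path(path)
    cutoffs: Dict[str, GeneCutoffs] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                for col in ("gene", "msc_cadd", "msc_pp2"):
                    if col not in header:
                        raise VariantParseError(
                            f"line {lineno}: cutoff header lacks column {col!r}"
                        )
                continue
            row = dict(zip(header, cells))
            gene = row["gene"].strip()
            if gene in cutoffs:
                raise ValueError(f"duplicate gene {gene!r} in cutoff table")
            try:
                cutoffs[gene] = GeneCutoffs(
                    gene=gene,
                    msc_cadd=float(row["msc_cadd"]),
                    msc_pp2=float(row["msc_pp2"]),
                    cadd_global=cadd_global,
                )
            except ValueError as exc:
                raise VariantParseError(f"line {lineno}: {exc}") from exc
    return cutoffs
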