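"""Domain types for annotated somatic variant calls and per-gene score cutoffs.

The package works on *called, annotated* variants from a targeted panel of
seven aldosterone-driver genes (KCNJ5, ATP1A1, ATP2B3, CACNA1D, CACNA1H,
CLCN2, CTNNB1).  Each record carries the population-database evidence and
in-silico deleteriousness scores (CADD, PolyPhen-2, SIFT, plus gene-level
Mutation Significance Cutoffs) that the downstream filter cascade and
consensus rule consume.  Scores are inputs: nothing here computes or fetches
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

__all__ = [
    "PANEL_GENES",
    "CONSEQUENCES",
    "NULL_CONSEQUENCES",
    "PP2_CATEGORIES",
    "SIFT_CATEGORIES",
    "AnnotatedVariant",
    "GeneCutoffs",
    "VariantTable",
    "VariantKey",
]

#: The seven-gene aldosterone-driver panel.
PANEL_GENES = frozenset(
    {"KCNJ5", "ATP1A1", "ATP2B3", "CACNA1D", "CACNA1H", "CLCN2", "CTNNB1"}
)

#: Coding consequences handled by the pipeline.  ``initial_codon`` is kept as
#: a first-class value because start-loss changes count as null variants in
#: the pathogenicity override.
CONSEQUENCES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift",
        "splice_site",
        "synonymous",
        "initial_codon",
        "other",
    }
)

#: Null (presumed loss/alteration-of-product) consequences: these bypass the
#: in-silico consensus because the damage mechanism is structural.
NULL_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_site", "initial_codon"})

PP2_CATEGORIES = frozenset({"probably_damaging", "possibly_damaging", "benign"})
SIFT_CATEGORIES = frozenset({"deleterious", "tolerated"})

_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X", "Y"])

#: Identity of a variant call: (sample_id, chrom, pos, ref, alt).
VariantKey = tuple


@dataclass(frozen=True)
class AnnotatedVariant:
    """One tumor (or blood) variant call with its annotations.

    ``vaf`` and ``dbsnp_maf`` are in percent (0-100), matching how targeted
    panels and population databases report them here.  Any annotation that
    was not observed is ``None`` — never 0, so "absent" and "measured zero"
    stay distinguishable.
    """

    sample_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    protein_change: str
    consequence: str
    vaf: float
    dbsnp_maf: Optional[float] = None
    in_evs: bool = False
    in_tgp: bool = False
    gnomad_hits: Optional[int] = None
    exac_hits: Optional[int] = None
    cadd: Optional[float] = None
    pp2_score: Optional[float] = None
    pp2_category: Optional[str] = None
    sift_score: Optional[float] = None
    sift_category: Optional[str] = None
    in_disease_db: bool = False

    def __post_init__(self) -> None:
        if self.gene not in PANEL_GENES:
            raise ValueError(
                f"unknown gene symbol {self.gene!r}; allowed panel: "
                f"{sorted(PANEL_GENES)}"
            )
        if self.chrom not in _CHROMS:
            raise ValueError(f"invalid chromosome label {self.chrom!r}")
        if self.pos < 1:
            raise ValueError("pos must be a 1-based positive coordinate")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if not 0.0 <= self.vaf <= 100.0:
            raise ValueError(f"vaf must be in [0, 100] percent, got {self.vaf}")
        if (self.consequence == "nonsense") != self.protein_change.endswith("Ter"):
            raise ValueError(
                "consequence 'nonsense' must coincide with a protein change "
                f"ending in 'Ter' (got {self.consequence!r}, "
                f"{self.protein_change!r})"
            )
        if self.dbsnp_maf is not None and not 0.0 <= self.dbsnp_maf <= 100.0:
            raise ValueError("dbsnp_maf must be in [0, 100] percent")
        for name in ("gnomad_hits", "exac_hits"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be a non-negative count")
        if self.cadd is not None and self.cadd < 0:
            raise ValueError("cadd must be >= 0")
        for name in ("pp2_score", "sift_score"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pp2_category is not None and self.pp2_category not in PP2_CATEGORIES:
            raise ValueError(f"unknown pp2_category {self.pp2_category!r}")
        if self.sift_category is not None and self.sift_category not in SIFT_CATEGORIES:
            raise ValueError(f"unknown sift_category {self.sift_category!r}")

    @property
    def key(self) -> VariantKey:
        """Identity tuple ``(sample_id, chrom, pos, ref, alt)``."""
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    def with_fields(self, **changes) -> "AnnotatedVariant":
        return replace(self, **changes)


@dataclass(frozen=True)
class GeneCutoffs:
    """Per-gene Mutation Significance Cutoffs plus the global CADD cutoff.

    MSC values are gene-level thresholds below which a predictor score is
    considered uninformative; a score at or above the cutoff counts as
    damaging evidence.  ``cadd_global`` (default 20) is the panel-wide CADD
    threshold applied on top of the gene-level one.
    """

    gene: str
    msc_cadd: float
    msc_pp2: float
    cadd_global: float = 20.0

    def __post_init__(self) -> None:
        if self.gene not in PANEL_GENES:
            raise ValueError(f"unknown gene symbol {self.gene!r}")
        if self.msc_cadd < 0:
            raise ValueError("msc_cadd must be >= 0")
        if not 0.0 <= self.msc_pp2 <= 1.0:
            raise ValueError("msc_pp2 must be in [0, 1]")
        if self.cadd_global < 0:
            raise ValueError("cadd_global must be >= 0")


@dataclass
class VariantTable:
    """Ordered collection of :class:`AnnotatedVariant` with unique keys."""

    records: list = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(f"duplicate variant key {rec.key}")
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotatedVariant]:
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariantTable):
            return NotImplemented
        return self.records == other.records

    def keys(self) -> set:
        return {rec.key for rec in self.records}

    def subset(self, keep) -> "VariantTable":
        """New table with the records for which ``keep(record)`` is true."""
        return VariantTable(
            records=[r for r in self.records if keep(r)], provenance=self.provenance
        )
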