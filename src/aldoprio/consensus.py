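"""Five-tool in-silico pathogenicity consensus for candidate somatic variants.

A candidate that survived the filter cascade is scored by five predictors:

* **CADD** — damaging iff the CADD score is at or above the panel-wide cutoff
  (default 20);
* **MSC-CADD** — damaging iff the CADD score is at or above the gene-level
  Mutation Significance Cutoff for CADD;
* **PP2** — damaging iff the PolyPhen-2 *category* is probably_damaging;
* **MSC-PP2** — damaging iff the PolyPhen-2 *score* is at or above the
  gene-level MSC for PolyPhen-2;
* **SIFT** — damaging iff the SIFT score is at most 0.05.

A missing input makes that tool ``not_applicable`` — never a dissent.  A
missense candidate is accepted as a novel mutation when at most one tool
votes ``not_damaging`` (the dissent threshold, default 1).  Two overrides
take precedence over the vote: membership in a curated disease database
(HGMD/ClinVar/LOVD, carried as an input boolean), and null variants
(nonsense, frameshift, obligatory splice-site, initial-codon) in genes where
gain/alteration of function is an established disease mechanism.

Boundary comparisons are inclusive on the damaging side (>= for CADD/MSC
cutoffs, <= 0.05 for SIFT).  The PolyPhen-2 category column is trusted as
given even where the numeric score would suggest a different band.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .models import (
    NULL_CONSEQUENCES,
    AnnotatedVariant,
    GeneCutoffs,
    VariantKey,
    VariantTable,
)

__all__ = [
    "TOOLS",
    "SIFT_DAMAGING_MAX",
    "ToolVerdict",
    "PathogenicityCall",
    "tool_verdicts",
    "consensus_call",
    "classify_table",
    "retained_sample_counts",
]

TOOLS = ("CADD", "MSC_CADD", "PP2", "MSC_PP2", "SIFT")

#: SIFT scores at or below this are damaging (conventional SIFT threshold).
SIFT_DAMAGING_MAX = 0.05

DAMAGING = "damaging"
NOT_DAMAGING = "not_damaging"
NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ToolVerdict:
    tool: str
    verdict: str
    basis: str

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")
        if self.verdict not in {DAMAGING, NOT_DAMAGING, NOT_APPLICABLE}:
            raise ValueError(f"unknown verdict {self.verdict!r}")


@dataclass(frozen=True)
class PathogenicityCall:
    """Final per-variant verdict with the route that produced it."""

    key: VariantKey
    gene: str
    verdicts: Tuple[ToolVerdict, ...]
    dissent_count: int
    route: str  # consensus_novel | null_variant | disease_db | rejected
    final: str  # retained | excluded

    def __post_init__(self) -> None:
        if self.route not in {"consensus_novel", "null_variant", "disease_db", "rejected"}:
            raise ValueError(f"unknown route {self.route!r}")
        if not 0 <= self.dissent_count <= len(TOOLS):
            raise ValueError("dissent_count out of range")
        if (self.final == "retained") != (self.route != "rejected"):
            raise ValueError("final must be 'retained' iff route != 'rejected'")

    @property
    def sample_id(self) -> str:
        return self.key[0]


def _verdict(tool: str, damaging: Optional[bool], basis: str) -> ToolVerdict:
    if damaging is None:
        return ToolVerdict(tool, NOT_APPLICABLE, basis)
    return ToolVerdict(tool, DAMAGING if damaging else NOT_DAMAGING, basis)


def tool_verdicts(
    variant: AnnotatedVariant, cutoffs: GeneCutoffs
) -> Tuple[ToolVerdict, ...]:
    """Score ``variant`` with all five tools against its gene's cutoffs."""
    if cutoffs.gene != variant.gene:
        raise ValueError(
            f"cutoffs are for gene {cutoffs.gene!r}, variant is {variant.gene!r}"
        )
    c, p, s = variant.cadd, variant.pp2_score, variant.sift_score
    return (
        _verdict(
            "CADD",
            None if c is None else c >= cutoffs.cadd_global,
            f"cadd={c} vs global cutoff {cutoffs.cadd_global}",
        ),
        _verdict(
            "MSC_CADD",
            None if c is None else c >= cutoffs.msc_cadd,
            f"cadd={c} vs MSC {cutoffs.msc_cadd}",
        ),
        _verdict(
            "PP2",
            None
            if variant.pp2_category is None
            else variant.pp2_category == "probably_damaging",
            f"category={variant.pp2_category}",
        ),
        _verdict(
            "MSC_PP2",
            None if p is None else p >= cutoffs.msc_pp2,
            f"pp2_score={p} vs MSC {cutoffs.msc_pp2}",
        ),
        _verdict(
            "SIFT",
            None if s is None else s <= SIFT_DAMAGING_MAX,
            f"sift_score={s} vs {SIFT_DAMAGING_MAX}",
        ),
    )


def consensus_call(
    variant: AnnotatedVariant,
    verdicts: Tuple[ToolVerdict, ...],
    dissent_threshold: int = 1,
) -> PathogenicityCall:
    """Combine tool verdicts and overrides into a final pathogenicity call.

    Route precedence: disease-database membership, then null-variant
    consequence, then the at-most-``dissent_threshold``-dissents consensus;
    anything else is rejected.
    """
    if len(verdicts) != len(TOOLS):
        raise ValueError(f"expected {len(TOOLS)} verdicts, got {len(verdicts)}")
    dissent_count = sum(v.verdict == NOT_DAMAGING for v in verdicts)

    if variant.in_disease_db:
        route = "disease_db"
    elif variant.consequence in NULL_CONSEQUENCES:
        route = "null_variant"
    elif dissent_count <= dissent_threshold:
        route = "consensus_novel"
    else:
        route = "rejected"

    return PathogenicityCall(
        key=variant.key,
        gene=variant.gene,
        verdicts=tuple(verdicts),
        dissent_count=dissent_count,
        route=route,
        final="retained" if route != "rejected" else "excluded",
    )


def classify_table(
    table: VariantTable,
    cutoffs: Dict[str, GeneCutoffs],
    dissent_threshold: int = 1,
) -> List[PathogenicityCall]:
    """One :class:`PathogenicityCall` per record, in table order."""
    calls = []
    for rec in table:
        if rec.gene not in cutoffs:
            raise KeyError(
                f"no cutoffs for gene {rec.gene!r}; cutoff table covers "
                f"{sorted(cutoffs)}"
            )
        verdicts = tool_verdicts(rec, cutoffs[rec.gene])
        calls.append(consensus_call(rec, verdicts, dissent_threshold))
    return calls


def retained_sample_counts(calls: Iterable[PathogenicityCall]) -> Dict[str, int]:
    """Distinct retained samples per gene (a sample counts once per gene)."""
    per_gene: Dict[str, set] = {}
    for call in calls:
        if call.final == "retained":
            per_gene.setdefault(call.gene, set()).add(call.sample_id)
    return {gene: len(samples) for gene, samples in sorted(per_gene.items())}
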