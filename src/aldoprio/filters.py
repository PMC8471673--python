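"""Sequential filtering of raw tumor variant calls down to somatic candidates.

The cascade mirrors a tumor-only targeted-panel workflow:

1. **VAF floor** — drop calls whose variant allele frequency is below a
   configurable floor (default 5%, the lowest VAF retained in the published
   call set).  An optional high-VAF "rescue" threshold (disabled by default)
   lets calls above it bypass the population filters, preserving an
   alternative reading of the published criteria in which >30% VAF calls are
   kept outright.
2. **Consequence** — keep protein-altering calls (missense, nonsense,
   frameshift, splice-site by default); synonymous and other changes drop.
3. **Population databases** — drop anything common in the population:
   dbSNP MAF > 1%, any EVS or 1000 Genomes record, > 5 gnomAD hits, or
   > 1 ExAC hit.  Absent annotations mean "not observed" and never exclude.
4. **Somatic confirmation** — drop tumor calls also present in matched
   blood (germline); skipped when no blood table is supplied.

Every step returns an audit entry (input/excluded/retained counts plus the
excluded keys with reason codes) and the counts are conserved at each step.
Exclusion reasons use first-match-wins in the fixed order documented on
:func:`apply_population_filters` so audits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, List, Optional, Tuple

from .models import AnnotatedVariant, VariantKey, VariantTable

__all__ = [
    "FilterConfig",
    "FilterStep",
    "FilterAudit",
    "apply_vaf_filter",
    "apply_consequence_filter",
    "apply_population_filters",
    "confirm_somatic",
    "run_cascade",
]

DEFAULT_KEPT_CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site"}
)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the filter cascade.

    ``vaf_floor`` and ``dbsnp_maf_max`` are percentages; the hit counts are
    strict "more than" thresholds.  ``vaf_keep_threshold`` is ``None``
    (disabled) by default; when set, calls with VAF strictly above it are
    flagged ``vaf_rescued`` and bypass the population filters.
    """

    vaf_floor: float = 5.0
    vaf_keep_threshold: Optional[float] = None
    dbsnp_maf_max: float = 1.0
    gnomad_hits_max: int = 5
    exac_hits_max: int = 1
    kept_consequences: FrozenSet[str] = DEFAULT_KEPT_CONSEQUENCES

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_floor <= 100.0:
            raise ValueError("vaf_floor must be in [0, 100] percent")
        if self.vaf_keep_threshold is not None and self.vaf_keep_threshold < 0:
            raise ValueError("vaf_keep_threshold must be non-negative")
        if self.dbsnp_maf_max < 0:
            raise ValueError("dbsnp_maf_max must be non-negative")
        if self.gnomad_hits_max < 0 or self.exac_hits_max < 0:
            raise ValueError("hit thresholds must be non-negative")


@dataclass
class FilterStep:
    """Audit entry for one cascade step."""

    name: str
    n_input: int
    n_excluded: int
    n_retained: int
    exclusions: List[Tuple[VariantKey, str]] = field(default_factory=list)
    rescued: FrozenSet[VariantKey] = frozenset()
    skipped: bool = False

    def __post_init__(self) -> None:
        if self.n_input != self.n_excluded + self.n_retained:
            raise ValueError(
                f"step {self.name!r}: input ({self.n_input}) != excluded "
                f"({self.n_excluded}) + retained ({self.n_retained})"
            )


@dataclass
class FilterAudit:
    """Chained audit over all cascade steps."""

    steps: List[FilterStep] = field(default_factory=list)

    def add(self, step: FilterStep) -> None:
        if self.steps and not step.skipped and step.n_input != self.steps[-1].n_retained:
            raise ValueError(
                f"step {step.name!r} input count {step.n_input} does not chain "
                f"from previous retained count {self.steps[-1].n_retained}"
            )
        self.steps.append(step)

    @property
    def n_input(self) -> int:
        return self.steps[0].n_input if self.steps else 0

    @property
    def n_retained(self) -> int:
        return self.steps[-1].n_retained if self.steps else 0

    @property
    def n_excluded_total(self) -> int:
        return sum(s.n_excluded for s in self.steps)

    def all_exclusions(self) -> List[Tuple[VariantKey, str]]:
        return [item for s in self.steps for item in s.exclusions]


def _split(
    table: VariantTable, name: str, reason_of, rescued: FrozenSet[VariantKey] = frozenset()
) -> Tuple[VariantTable, FilterStep]:
    """Partition ``table`` by ``reason_of(record) -> Optional[str]``."""
    kept, exclusions = [], []
    for rec in table:
        reason = None if rec.key in rescued else reason_of(rec)
        if reason is None:
            kept.append(rec)
        else:
            exclusions.append((rec.key, reason))
    step = FilterStep(
        name=name,
        n_input=len(table),
        n_excluded=len(exclusions),
        n_retained=len(kept),
        exclusions=exclusions,
        rescued=rescued,
    )
    return VariantTable(records=kept, provenance=table.provenance), step


def apply_vaf_filter(
    table: VariantTable, config: FilterConfig
) -> Tuple[VariantTable, FilterStep]:
    """Drop calls with VAF below the floor (inclusive at the floor).

    When the optional keep threshold is enabled, calls strictly above it are
    recorded in the step's ``rescued`` set so later population filters can
    wave them through.
    """

    def reason_of(rec: AnnotatedVariant) -> Optional[str]:
        return "low_vaf" if rec.vaf < config.vaf_floor else None

    out, step = _split(table, "vaf", reason_of)
    if config.vaf_keep_threshold is not None:
        step.rescued = frozenset(
            rec.key for rec in out if rec.vaf > config.vaf_keep_threshold
        )
    return out, step


def apply_consequence_filter(
    table: VariantTable, config: FilterConfig
) -> Tuple[VariantTable, FilterStep]:
    """Keep protein-altering consequences only."""

    def reason_of(rec: AnnotatedVariant) -> Optional[str]:
        if rec.consequence not in config.kept_consequences:
            return "not_protein_altering"
        return None

    return _split(table, "consequence", reason_of)


def apply_population_filters(
    table: VariantTable,
    config: FilterConfig,
    rescued: FrozenSet[VariantKey] = frozenset(),
) -> Tuple[VariantTable, FilterStep]:
    """Drop population-common calls.

    A record is excluded iff dbSNP MAF > 1% OR it appears in EVS OR in the
    1000 Genomes Project OR has more than 5 gnomAD hits OR more than 1 ExAC
    hit (thresholds from config; comparisons strict).  The exclusion reason
    is the first matching rule in that order.  Absent annotations count as
    "not observed".  Keys in ``rescued`` bypass this step entirely.
    """

    def reason_of(rec: AnnotatedVariant) -> Optional[str]:
        if rec.dbsnp_maf is not None and rec.dbsnp_maf > config.dbsnp_maf_max:
            return "dbsnp_common"
        if rec.in_evs:
            return "in_evs"
        if rec.in_tgp:
            return "in_tgp"
        if rec.gnomad_hits is not None and rec.gnomad_hits > config.gnomad_hits_max:
            return "gnomad_common"
        if rec.exac_hits is not None and rec.exac_hits > config.exac_hits_max:
            return "exac_common"
        return None

    return _split(table, "population", reason_of, rescued=rescued)


def confirm_somatic(
    tumor: VariantTable, blood: Optional[VariantTable]
) -> Tuple[VariantTable, FilterStep]:
    """Drop tumor calls that also appear in matched blood (germline).

    Matching is on ``(sample_id, chrom, pos, ref, alt)``.  With no blood
    table the step is a pass-through marked ``skipped``.
    """
    if blood is None:
        step = FilterStep(
            name="somatic",
            n_input=len(tumor),
            n_excluded=0,
            n_retained=len(tumor),
            skipped=True,
        )
        return tumor, step

    blood_keys = blood.keys()

    def reason_of(rec: AnnotatedVariant) -> Optional[str]:
        return "germline" if rec.key in blood_keys else None

    return _split(tumor, "somatic", reason_of)


def run_cascade(
    tumor: VariantTable,
    blood: Optional[VariantTable] = None,
    config: Optional[FilterConfig] = None,
) -> Tuple[VariantTable, FilterAudit]:
    """Run the full cascade: VAF -> consequence -> population -> somatic.

    The retained set is a pure per-record predicate intersection, so it is
    invariant to input row order and the cascade is idempotent.
    """
    config = config or FilterConfig()
    audit = FilterAudit()

    table, step = apply_vaf_filter(tumor, config)
    audit.add(step)
    rescued = step.rescued

    table, step = apply_consequence_filter(table, config)
    audit.add(step)

    table, step = apply_population_filters(table, config, rescued=rescued)
    audit.add(step)

    table, step = confirm_somatic(table, blood)
    audit.add(step)

    return table, audit
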