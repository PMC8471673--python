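"""End-to-end orchestration: filter -> consensus -> prevalence -> association.

:func:`run_full_pipeline` chains the stages over in-memory inputs, collects a
stage-granular log mirroring the filter audit, and (optionally) writes all
tabular outputs to a directory.  Outputs are deterministic: re-running with
identical inputs and configuration reproduces every table byte for byte;
timestamps are confined to the run log.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .cohort import (
    AssociationResult,
    OutcomeCall,
    PatientRecord,
    PrevalenceSummary,
    assign_carrier_status,
    classify_biochemical_outcome,
    classify_clinical_outcome,
    cohort_to_frame,
    outcome_crosstab,
    prevalence_summary,
)
from .consensus import TOOLS, PathogenicityCall, classify_table
from .filters import FilterAudit, FilterConfig, run_cascade
from .io import write_variant_table
from .models import GeneCutoffs, VariantTable

__all__ = ["PipelineConfig", "PipelineStageError", "ReportBundle", "run_full_pipeline"]


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    dissent_threshold: int = 1
    bp_threshold: Tuple[float, float] = (140.0, 90.0)
    arr_threshold: float = 38.0
    k_threshold: float = 3.5
    test: str = "pearson_chi2"
    out_dir: Optional[Path] = None
    seed: Optional[int] = None

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["filter_config"]["kept_consequences"] = sorted(
            payload["filter_config"]["kept_consequences"]
        )
        payload["out_dir"] = None  # location does not affect results
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ReportBundle:
    filtered: VariantTable
    audit: FilterAudit
    calls: List[PathogenicityCall]
    prevalence: PrevalenceSummary
    outcomes: Dict[str, OutcomeCall]
    clinical_association: Optional[AssociationResult]
    biochemical_association: Optional[AssociationResult]
    cohort: List[PatientRecord]
    log: List[str]
    config_hash: str


def _stage(log: List[str], name: str, func):
    try:
        result = func()
    except Exception as exc:
        raise PipelineStageError(name, exc) from exc
    return result


def calls_to_frame(calls: Iterable[PathogenicityCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        row = {
            "sample_id": call.key[0],
            "gene": call.gene,
            "chrom": call.key[1],
            "pos": call.key[2],
            "ref": call.key[3],
            "alt": call.key[4],
            "dissent_count": call.dissent_count,
            "route": call.route,
            "final": call.final,
        }
        for verdict in call.verdicts:
            row[f"verdict_{verdict.tool}"] = verdict.verdict
        rows.append(row)
    columns = ["sample_id", "gene", "chrom", "pos", "ref", "alt"] + [
        f"verdict_{t}" for t in TOOLS
    ] + ["dissent_count", "route", "final"]
    return pd.DataFrame(rows, columns=columns)


def audit_to_frame(audit: FilterAudit) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "step": s.name,
                "n_input": s.n_input,
                "n_excluded": s.n_excluded,
                "n_retained": s.n_retained,
                "skipped": s.skipped,
            }
            for s in audit.steps
        ]
    )


def run_full_pipeline(
    config: PipelineConfig,
    tumor: VariantTable,
    blood: Optional[VariantTable],
    cutoffs: Dict[str, GeneCutoffs],
    sanger: Dict[str, str],
    cohort: Optional[List[PatientRecord]] = None,
    sanger_counts: Optional[Dict[str, int]] = None,
    n_total: Optional[int] = None,
) -> ReportBundle:
    """Run all stages and return the report bundle.

    ``sanger`` maps hotspot-carrier samples in the *cohort* to their gene;
    ``sanger_counts`` (defaulting to per-gene tallies of ``sanger``) and
    ``n_total`` (defaulting to cohort size + Sanger carriers) drive the
    prevalence summary.  Association tests are skipped when no cohort is
    given.
    """
    if not cutoffs:
        raise PipelineStageError("setup", ValueError("empty gene-cutoff mapping"))
    missing = {rec.gene for rec in tumor} - set(cutoffs)
    if missing:
        raise PipelineStageError(
            "setup", ValueError(f"no cutoffs for genes {sorted(missing)}")
        )

    log: List[str] = [
        f"start {datetime.now(timezone.utc).isoformat()}",
        f"config_hash {config.config_hash()} seed {config.seed}",
    ]

    filtered, audit = _stage(
        log, "filter", lambda: run_cascade(tumor, blood, config.filter_config)
    )
    for step in audit.steps:
        log.append(
            f"filter:{step.name} input={step.n_input} excluded={step.n_excluded} "
            f"retained={step.n_retained}{' (skipped)' if step.skipped else ''}"
        )

    calls = _stage(
        log, "classify",
        lambda: classify_table(filtered, cutoffs, config.dissent_threshold),
    )
    n_retained = sum(c.final == "retained" for c in calls)
    log.append(f"classify retained={n_retained} rejected={len(calls) - n_retained}")

    counts = sanger_counts
    if counts is None:
        counts = {}
        for gene in sanger.values():
            counts[gene] = counts.get(gene, 0) + 1
    total = n_total
    if total is None:
        total = (len(cohort) if cohort else 0) + sum(counts.values())
    prevalence = _stage(
        log, "prevalence", lambda: prevalence_summary(counts, calls, total)
    )
    log.append(
        f"prevalence carriers={prevalence.n_carriers}/{prevalence.n_total} "
        f"({prevalence.overall_percent:.1f}%)"
    )

    outcomes: Dict[str, OutcomeCall] = {}
    clinical_assoc = biochem_assoc = None
    assigned: List[PatientRecord] = []
    if cohort is not None:
        assigned = _stage(
            log, "carrier_assignment",
            lambda: assign_carrier_status(cohort, calls, sanger),
        )
        followed = [
            r for r in assigned
            if r.sbp_post is not None and r.potassium_post is not None
        ]

        def _outcomes():
            return {
                r.sample_id: OutcomeCall(
                    clinical=classify_clinical_outcome(r, config.bp_threshold),
                    biochemical=classify_biochemical_outcome(
                        r, config.arr_threshold, config.k_threshold
                    ),
                )
                for r in followed
            }

        outcomes = _stage(log, "outcomes", _outcomes)
        log.append(f"outcomes classified={len(outcomes)} of {len(assigned)}")

        grouping = lambda r: "carrier" if r.is_carrier else "non_carrier"
        clinical_assoc = _stage(
            log, "associate_clinical",
            lambda: outcome_crosstab(
                followed, grouping, outcome="clinical", test=config.test,
                bp_threshold=config.bp_threshold,
            ),
        )
        biochem_assoc = _stage(
            log, "associate_biochemical",
            lambda: outcome_crosstab(
                followed, grouping, outcome="biochemical", test=config.test,
                arr_threshold=config.arr_threshold, k_threshold=config.k_threshold,
            ),
        )
        log.append(
            f"associate clinical_p={clinical_assoc.p_value:.4g} "
            f"biochemical_p={biochem_assoc.p_value:.4g}"
        )

    bundle = ReportBundle(
        filtered=filtered,
        audit=audit,
        calls=calls,
        prevalence=prevalence,
        outcomes=outcomes,
        clinical_association=clinical_assoc,
        biochemical_association=biochem_assoc,
        cohort=assigned,
        log=log,
        config_hash=config.config_hash(),
    )
    if config.out_dir is not None:
        _write_bundle(bundle, Path(config.out_dir))
    return bundle


def _write_bundle(bundle: ReportBundle, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_variant_table(bundle.filtered, out_dir / "filtered_variants.tsv")
    audit_to_frame(bundle.audit).to_csv(out_dir / "filter_audit.tsv", sep="\t", index=False)
    calls_to_frame(bundle.calls).to_csv(out_dir / "pathogenicity_calls.tsv", sep="\t", index=False)
    bundle.prevalence.to_frame().to_csv(out_dir / "prevalence.tsv", sep="\t", index=False)
    if bundle.cohort:
        cohort_to_frame(bundle.cohort).to_csv(out_dir / "cohort_assigned.csv", index=False)
    if bundle.outcomes:
        pd.DataFrame(
            [
                {"sample_id": s, "clinical": oc.clinical, "biochemical": oc.biochemical}
                for s, oc in sorted(bundle.outcomes.items())
            ]
        ).to_csv(out_dir / "outcome_calls.tsv", sep="\t", index=False)
    assoc_rows = []
    for name, assoc in (
        ("clinical", bundle.clinical_association),
        ("biochemical", bundle.biochemical_association),
    ):
        if assoc is not None:
            assoc_rows.append(
                {
                    "outcome": name,
                    "test": assoc.test,
                    "statistic": assoc.statistic,
                    "df": assoc.df,
                    "p_value": assoc.p_value,
                }
            )
    if assoc_rows:
        pd.DataFrame(assoc_rows).to_csv(out_dir / "associations.tsv", sep="\t", index=False)
    (out_dir / "run_log.txt").write_text("\n".join(bundle.log) + "\n")
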