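"""Synthetic variant tables and cohorts with planted, recoverable truth.

The generator emulates the inputs of the real study so every pipeline stage
is testable without access to the (unreleased) patient-level data:

* **Variant tables** — each carrier sample gets one driver whose score
  profile is resampled (with clipped jitter) from the published 21-variant
  call set, so drivers are guaranteed to survive the filter cascade and the
  five-tool consensus.  Decoys are constructed to violate exactly one named
  filter each: population-common calls, synonymous changes, low-VAF
  artifacts, and germline calls that also appear in the matched blood table.
* **Cohorts** — genotype groups are drawn at the study's carrier fraction
  (21/75 by default); clinical and biochemical outcomes come from
  group-specific trinomials matching the published outcome frequencies;
  baseline covariates follow the published mean/SD summaries truncated at
  physical bounds.  Post-surgery fields are constructed so the PASO
  classifiers reproduce the sampled outcome labels exactly.

All randomness flows through ``numpy.random.default_rng`` (PCG64) seeded
from ``SimulationConfig.seed``, so identical configs give identical outputs
across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .consensus import consensus_call, tool_verdicts
from .datasets import published_gene_cutoffs, published_variant_table
from .filters import FilterConfig
from .models import AnnotatedVariant, GeneCutoffs, VariantKey, VariantTable
from .cohort import PatientRecord

__all__ = [
    "SimulationConfig",
    "PlantedTruth",
    "simulate_variant_tables",
    "simulate_cohort",
]

DECOY_CLASSES = ("common_snp", "synonymous", "low_vaf", "germline")

#: (complete, partial, absent) clinical-success probabilities per group,
#: matching the published carrier (15/3/3 of 21) and non-carrier
#: (18/23/13 of 54) outcome frequencies.
DEFAULT_CLINICAL_PROBS = {
    "carrier": (0.714, 0.143, 0.143),
    "non_carrier": (0.333, 0.426, 0.241),
}

#: (complete, partial, absent) biochemical-success probabilities per group
#: (carriers 18/0/3 of 21; non-carriers 43/4/7 of 54).
DEFAULT_BIOCHEMICAL_PROBS = {
    "carrier": (0.857, 0.0, 0.143),
    "non_carrier": (0.796, 0.074, 0.130),
}

#: Baseline covariate (mean, sd, lower bound) mirroring the published cohort
#: summaries for the 75 hotspot-negative patients.
DEFAULT_COVARIATES = {
    "age": (54.5, 10.6, 18.0),
    "bmi": (26.2, 4.0, 12.0),
    "sbp": (152.0, 20.8, 90.0),
    "dbp": (90.8, 14.5, 40.0),
    "pra": (0.83, 2.32, 0.01),
    "aldosterone": (49.8, 35.2, 1.0),
    "log_arr": (2.28, 0.83, None),
    "potassium": (3.6, 0.6, 2.0),
    "creatinine": (0.93, 0.36, 0.2),
    "cystatin_c": (0.84, 0.23, 0.2),
    "microalbuminuria": (0.06, 0.12, 0.0),
    "tumor_size": (2.09, 2.57, 0.3),
    "bapwv": (1722.0, 329.2, 800.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.  ``seed`` is mandatory."""

    seed: int
    n_samples: int = 75
    driver_fraction: float = 21.0 / 75.0
    vaf_range: Tuple[float, float] = (5.0, 50.0)
    low_vaf_range: Tuple[float, float] = (0.5, 4.9)
    n_decoys: int = 120
    decoy_mix: Mapping[str, float] = field(
        default_factory=lambda: {c: 0.25 for c in DECOY_CLASSES}
    )
    clinical_probs: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL_PROBS)
    )
    biochemical_probs: Mapping[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BIOCHEMICAL_PROBS)
    )
    covariate_params: Mapping[str, tuple] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    female_fraction: float = 0.573

    def __post_init__(self) -> None:
        if not 0.0 <= self.driver_fraction <= 1.0:
            raise ValueError("driver_fraction must be in [0, 1]")
        if set(self.decoy_mix) != set(DECOY_CLASSES):
            raise ValueError(f"decoy_mix must cover exactly {DECOY_CLASSES}")
        if any(p < 0 for p in self.decoy_mix.values()) or not np.isclose(
            sum(self.decoy_mix.values()), 1.0
        ):
            raise ValueError("decoy_mix proportions must be non-negative and sum to 1")
        for name, probs in [*self.clinical_probs.items(), *self.biochemical_probs.items()]:
            if any(p < 0 for p in probs) or not np.isclose(sum(probs), 1.0, atol=1e-6):
                raise ValueError(f"outcome probabilities for {name!r} must sum to 1")
        if self.vaf_range[0] >= self.vaf_range[1] or self.low_vaf_range[0] >= self.low_vaf_range[1]:
            raise ValueError("VAF ranges must be increasing pairs")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside simulated data."""

    genotype: Dict[str, str] = field(default_factory=dict)  # sample -> carrier/non_carrier
    driver_keys: Dict[str, VariantKey] = field(default_factory=dict)
    variant_classes: Dict[VariantKey, str] = field(default_factory=dict)
    clinical_outcomes: Dict[str, str] = field(default_factory=dict)
    biochemical_outcomes: Dict[str, str] = field(default_factory=dict)

    def carriers(self) -> set:
        return {s for s, g in self.genotype.items() if g == "carrier"}


def _largest_remainder(total: int, proportions: Mapping[str, float]) -> Dict[str, int]:
    raw = {k: total * p for k, p in proportions.items()}
    counts = {k: int(v) for k, v in raw.items()}
    leftover = total - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:leftover]:
        counts[k] += 1
    return counts


def _clip_keep_side(value: float, cutoff: float, damaging: bool,
                    lo: float, hi: float) -> float:
    """Clip a jittered score so it stays on the same side of ``cutoff``."""
    if damaging:
        return float(min(max(value, cutoff), hi))
    return float(min(max(value, lo), np.nextafter(cutoff, lo)))


def _jitter_driver(
    template: AnnotatedVariant,
    cutoffs: GeneCutoffs,
    rng: np.random.Generator,
    sample_id: str,
    vaf_range: Tuple[float, float],
    used: set,
) -> AnnotatedVariant:
    cadd = None
    if template.cadd is not None:
        floor = max(cutoffs.cadd_global, cutoffs.msc_cadd)
        cadd = float(max(template.cadd + rng.normal(0, 0.8), floor))
    pp2_score = None
    if template.pp2_score is not None:
        pp2_score = _clip_keep_side(
            template.pp2_score + rng.normal(0, 0.02),
            cutoffs.msc_pp2,
            template.pp2_score >= cutoffs.msc_pp2,
            0.0, 1.0,
        )
    sift_score = None
    if template.sift_score is not None:
        if template.sift_score <= 0.05:
            sift_score = float(np.clip(template.sift_score + rng.normal(0, 0.01), 0.0, 0.05))
        else:
            sift_score = float(np.clip(template.sift_score + rng.normal(0, 0.02), 0.06, 1.0))

    pos = None
    while pos is None or (sample_id, template.chrom, pos) in used:
        pos = int(template.pos + 3 * rng.integers(-300, 301))
    used.add((sample_id, template.chrom, pos))

    variant = template.with_fields(
        sample_id=sample_id,
        pos=pos,
        vaf=float(np.round(rng.uniform(*vaf_range), 2)),
        cadd=None if cadd is None else round(cadd, 3),
        pp2_score=None if pp2_score is None else round(pp2_score, 3),
        sift_score=None if sift_score is None else round(sift_score, 3),
    )
    # construction guarantee: a planted driver must pass the consensus rule
    call = consensus_call(variant, tool_verdicts(variant, cutoffs))
    assert call.final == "retained", "driver jitter violated the consensus rule"
    return variant


def _make_decoy(
    decoy_class: str,
    template: AnnotatedVariant,
    rng: np.random.Generator,
    sample_id: str,
    config: SimulationConfig,
    used: set,
) -> AnnotatedVariant:
    pos = None
    while pos is None or (sample_id, template.chrom, pos) in used:
        pos = int(template.pos + 3 * rng.integers(-5000, 5001) + 1)
    used.add((sample_id, template.chrom, pos))

    fields = dict(
        sample_id=sample_id,
        pos=pos,
        vaf=float(np.round(rng.uniform(*config.vaf_range), 2)),
    )
    if decoy_class == "common_snp":
        violation = rng.integers(0, 5)
        if violation == 0:
            fields["dbsnp_maf"] = float(np.round(rng.uniform(1.5, 30.0), 2))
        elif violation == 1:
            fields["in_evs"] = True
        elif violation == 2:
            fields["in_tgp"] = True
        elif violation == 3:
            fields["gnomad_hits"] = int(rng.integers(6, 200))
        else:
            fields["exac_hits"] = int(rng.integers(2, 50))
    elif decoy_class == "synonymous":
        res = int(rng.integers(10, 900))
        fields["consequence"] = "synonymous"
        fields["protein_change"] = f"Ala{res}Ala"
    elif decoy_class == "low_vaf":
        fields["vaf"] = float(np.round(rng.uniform(*config.low_vaf_range), 2))
    elif decoy_class == "germline":
        fields["vaf"] = float(np.round(np.clip(rng.normal(50.0, 3.0), 35.0, 65.0), 2))
    else:
        raise ValueError(f"unknown decoy class {decoy_class!r}")
    # nonsense templates carry a Ter protein change; keep the pairing valid
    if decoy_class == "synonymous" and template.consequence == "nonsense":
        fields["consequence"] = "synonymous"
    return template.with_fields(**fields)


def simulate_variant_tables(
    config: SimulationConfig,
    cutoffs: Optional[Dict[str, GeneCutoffs]] = None,
    filter_config: Optional[FilterConfig] = None,
) -> Tuple[VariantTable, VariantTable, PlantedTruth]:
    """Simulate tumor and matched-blood variant tables with planted truth.

    Every planted driver survives the full cascade plus consensus; every
    decoy is excluded at its designated step.  Germline decoys appear in
    both tables under the same key.
    """
    cutoffs = cutoffs or published_gene_cutoffs()
    rng = np.random.default_rng([config.seed, 11])
    templates = [t for t in published_variant_table() if t.gene in cutoffs]

    samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
    is_carrier = rng.random(config.n_samples) < config.driver_fraction

    truth = PlantedTruth()
    used: set = set()
    tumor_records: List[AnnotatedVariant] = []
    blood_records: List[AnnotatedVariant] = []

    for sample_id, carrier in zip(samples, is_carrier):
        truth.genotype[sample_id] = "carrier" if carrier else "non_carrier"
        if carrier:
            template = templates[rng.integers(0, len(templates))]
            driver = _jitter_driver(
                template, cutoffs[template.gene], rng, sample_id,
                config.vaf_range, used,
            )
            tumor_records.append(driver)
            truth.driver_keys[sample_id] = driver.key
            truth.variant_classes[driver.key] = "driver"

    class_counts = _largest_remainder(config.n_decoys, config.decoy_mix)
    for decoy_class in DECOY_CLASSES:
        for _ in range(class_counts[decoy_class]):
            sample_id = samples[rng.integers(0, len(samples))]
            template = templates[rng.integers(0, len(templates))]
            decoy = _make_decoy(decoy_class, template, rng, sample_id, config, used)
            tumor_records.append(decoy)
            truth.variant_classes[decoy.key] = decoy_class
            if decoy_class == "germline":
                blood_records.append(
                    decoy.with_fields(
                        vaf=float(np.round(np.clip(rng.normal(50.0, 3.0), 35.0, 65.0), 2))
                    )
                )

    tumor = VariantTable(records=tumor_records, provenance=f"simulated(seed={config.seed})")
    blood = VariantTable(records=blood_records, provenance=f"simulated(seed={config.seed})")
    return tumor, blood, truth


_PANEL_SIM_GENES = ("ATP1A1", "ATP2B3", "CACNA1D", "CACNA1H", "CLCN2", "CTNNB1")


def _truncated_normal(rng, mean, sd, lower, size):
    values = rng.normal(mean, sd, size=size)
    if lower is not None:
        for _ in range(100):
            bad = values < lower
            if not bad.any():
                break
            values[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        values = np.maximum(values, lower if lower is not None else values)
    return values


def simulate_cohort(
    config: SimulationConfig,
    genotype: Optional[Mapping[str, str]] = None,
) -> Tuple[List[PatientRecord], PlantedTruth]:
    """Simulate a cohort of patients with planted outcome labels.

    ``genotype`` may carry a sample -> {carrier, non_carrier} mapping (for
    instance from :func:`simulate_variant_tables`); otherwise groups are
    drawn at ``driver_fraction``.  Post-surgery fields are built so the PASO
    classifiers reproduce the planted labels exactly.
    """
    rng = np.random.default_rng([config.seed, 23])
    if genotype is None:
        samples = [f"S{i:04d}" for i in range(1, config.n_samples + 1)]
        carrier_flags = rng.random(len(samples)) < config.driver_fraction
        genotype = {
            s: ("carrier" if c else "non_carrier")
            for s, c in zip(samples, carrier_flags)
        }
    samples = list(genotype)
    n = len(samples)

    cov = {
        name: _truncated_normal(rng, *params, size=n)
        for name, params in config.covariate_params.items()
    }
    female = rng.random(n) < config.female_fraction

    truth = PlantedTruth(genotype=dict(genotype))
    records: List[PatientRecord] = []
    labels = ("complete", "partial", "absent")

    for i, sample_id in enumerate(samples):
        group = genotype[sample_id]
        clin = labels[rng.choice(3, p=config.clinical_probs[group])]
        bio = labels[rng.choice(3, p=config.biochemical_probs[group])]
        truth.clinical_outcomes[sample_id] = clin
        truth.biochemical_outcomes[sample_id] = bio

        sbp, dbp = float(cov["sbp"][i]), float(cov["dbp"][i])
        aldosterone = float(cov["aldosterone"][i])
        meds_pre = int(rng.integers(1, 4))

        if clin == "complete":
            sbp_post = float(rng.uniform(105.0, 135.0))
            dbp_post = float(rng.uniform(60.0, 85.0))
            meds_post = 0
        elif clin == "partial":
            sbp_post = sbp - float(rng.uniform(5.0, 20.0))
            dbp_post = dbp - float(rng.uniform(2.0, 10.0))
            meds_post = meds_pre
        else:
            sbp_post = sbp + float(rng.uniform(2.0, 15.0))
            dbp_post = dbp + float(rng.uniform(1.0, 10.0))
            meds_post = meds_pre

        if bio == "complete":
            k_post = float(rng.uniform(3.6, 4.8))
            arr_post = float(rng.uniform(5.0, 30.0))
            aldo_post = float(rng.uniform(3.0, 15.0))
        elif bio == "partial":
            k_post = float(rng.uniform(3.6, 4.8))
            arr_post = float(rng.uniform(45.0, 120.0))
            aldo_post = aldosterone * float(rng.uniform(0.2, 0.45))
        else:
            k_post = float(rng.uniform(2.5, 3.3))
            arr_post = float(rng.uniform(45.0, 120.0))
            aldo_post = aldosterone * float(rng.uniform(0.8, 1.1))

        bapwv_mean = float(cov["bapwv"][i])
        right_mean = bapwv_mean + float(rng.normal(0, 30))
        left_mean = bapwv_mean + float(rng.normal(0, 30))

        carrier = group == "carrier"
        records.append(
            PatientRecord(
                sample_id=sample_id,
                genotype_group="ngs_carrier" if carrier else "non_carrier",
                carrier_gene=(
                    _PANEL_SIM_GENES[rng.integers(0, len(_PANEL_SIM_GENES))]
                    if carrier else None
                ),
                sex="female" if female[i] else "male",
                age=float(cov["age"][i]),
                bmi=float(cov["bmi"][i]),
                sbp=sbp,
                dbp=dbp,
                pra=float(cov["pra"][i]),
                aldosterone=aldosterone,
                log_arr=float(cov["log_arr"][i]),
                potassium=float(cov["potassium"][i]),
                creatinine=float(cov["creatinine"][i]),
                cystatin_c=float(cov["cystatin_c"][i]),
                microalbuminuria=float(cov["microalbuminuria"][i]),
                tumor_size=float(cov["tumor_size"][i]),
                bapwv_right=(right_mean + float(rng.normal(0, 20)),
                             right_mean + float(rng.normal(0, 20))),
                bapwv_left=(left_mean + float(rng.normal(0, 20)),
                            left_mean + float(rng.normal(0, 20))),
                n_antihypertensives_pre=meds_pre,
                sbp_post=sbp_post,
                dbp_post=dbp_post,
                n_antihypertensives_post=meds_post,
                potassium_post=k_post,
                arr_post=arr_post,
                aldosterone_post=aldo_post,
                confirmatory_test_improved=False,
            )
        )
    return records, truth
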