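"""Cohort analysis: surgical-outcome classification and genotype association.

Covers the clinical side of the study:

* PASO (Primary Aldosteronism Surgery Outcome) classification of clinical and
  biochemical success at 12 months after unilateral adrenalectomy;
* arterial-stiffness aggregation (final baPWV = max of per-side means of two
  measurements);
* carrier-status assignment combining hotspot (Sanger) screening with the
  NGS pathogenicity calls;
* per-gene mutation prevalence arithmetic;
* contingency statistics (Pearson chi-square without continuity correction,
  Fisher's exact test), crude odds ratios with Woolf confidence intervals,
  and multinomial-logistic likelihood-ratio tests for outcome determinants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PatientRecord",
    "OutcomeCall",
    "AssociationResult",
    "LRTestResult",
    "MultinomialLRReport",
    "PrevalenceSummary",
    "classify_clinical_outcome",
    "classify_biochemical_outcome",
    "final_bapwv",
    "assign_carrier_status",
    "prevalence_summary",
    "contingency_test",
    "outcome_crosstab",
    "crude_odds_ratio",
    "multinomial_lr_tests",
]

GENOTYPE_GROUPS = ("sanger_carrier", "ngs_carrier", "non_carrier")
OUTCOME_LABELS = ("complete", "partial", "absent")


@dataclass
class PatientRecord:
    """One patient: genotype group, baseline covariates, post-surgery data.

    Pressures in mmHg, potassium in mmol/L, aldosterone in ng/dL, PRA in
    ng/mL/min, baPWV in cm/s, tumor size in cm.  Post-surgery fields are at
    12 months and may be absent (``None``) for patients without follow-up.
    """

    sample_id: str
    genotype_group: str = "non_carrier"
    carrier_gene: Optional[str] = None
    sex: Optional[str] = None  # "female" / "male"
    age: Optional[float] = None
    bmi: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    pra: Optional[float] = None
    aldosterone: Optional[float] = None
    log_arr: Optional[float] = None
    potassium: Optional[float] = None
    creatinine: Optional[float] = None
    cystatin_c: Optional[float] = None
    microalbuminuria: Optional[float] = None
    tumor_size: Optional[float] = None
    bapwv_right: Optional[Tuple[float, float]] = None
    bapwv_left: Optional[Tuple[float, float]] = None
    n_antihypertensives_pre: Optional[int] = None
    sbp_post: Optional[float] = None
    dbp_post: Optional[float] = None
    n_antihypertensives_post: Optional[int] = None
    potassium_post: Optional[float] = None
    arr_post: Optional[float] = None
    aldosterone_post: Optional[float] = None
    confirmatory_test_improved: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.genotype_group not in GENOTYPE_GROUPS:
            raise ValueError(f"unknown genotype group {self.genotype_group!r}")
        if self.genotype_group == "non_carrier" and self.carrier_gene is not None:
            raise ValueError("non-carriers cannot carry a gene label")
        for name in ("age", "bmi", "sbp", "dbp", "aldosterone", "potassium",
                     "creatinine", "cystatin_c", "microalbuminuria",
                     "tumor_size"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def is_carrier(self) -> bool:
        return self.genotype_group != "non_carrier"


@dataclass(frozen=True)
class OutcomeCall:
    clinical: str
    biochemical: str

    def __post_init__(self) -> None:
        for value in (self.clinical, self.biochemical):
            if value not in OUTCOME_LABELS:
                raise ValueError(f"unknown outcome label {value!r}")


@dataclass
class AssociationResult:
    table: np.ndarray
    test: str
    statistic: float
    df: Optional[int]
    p_value: float
    odds_ratio: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table)
        if (self.table < 0).any():
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")


def _require(record: PatientRecord, names: Sequence[str]) -> None:
    missing = [n for n in names if getattr(record, n) is None]
    if missing:
        raise ValueError(
            f"patient {record.sample_id}: missing post-surgery fields {missing}"
        )


def classify_clinical_outcome(
    record: PatientRecord, bp_threshold: Tuple[float, float] = (140.0, 90.0)
) -> str:
    """PASO clinical success at 12 months.

    *Complete*: blood pressure normalized (strictly below ``bp_threshold`` on
    both systolic and diastolic) with no antihypertensive medication.
    *Partial*: same blood pressure as before surgery on fewer drugs, or
    reduced blood pressure on the same number of drugs or fewer.  Otherwise
    *absent*.  "Reduced" means neither component higher and at least one
    strictly lower.
    """
    _require(record, ["sbp", "dbp", "sbp_post", "dbp_post",
                      "n_antihypertensives_pre", "n_antihypertensives_post"])
    sbp_t, dbp_t = bp_threshold
    normalized = record.sbp_post < sbp_t and record.dbp_post < dbp_t
    if normalized and record.n_antihypertensives_post == 0:
        return "complete"

    same_bp = record.sbp_post == record.sbp and record.dbp_post == record.dbp
    reduced_bp = (
        record.sbp_post <= record.sbp
        and record.dbp_post <= record.dbp
        and (record.sbp_post < record.sbp or record.dbp_post < record.dbp)
    )
    fewer_meds = record.n_antihypertensives_post < record.n_antihypertensives_pre
    same_or_fewer = record.n_antihypertensives_post <= record.n_antihypertensives_pre
    if (same_bp and fewer_meds) or (reduced_bp and same_or_fewer):
        return "partial"
    return "absent"


def classify_biochemical_outcome(
    record: PatientRecord,
    arr_threshold: float = 38.0,
    k_threshold: float = 3.5,
) -> str:
    """PASO biochemical success at 12 months.

    *Complete*: serum potassium normalized (>= ``k_threshold`` mmol/L) and
    aldosterone-to-renin ratio below ``arr_threshold``.  *Partial*:
    hypokalemia corrected but ARR still raised, with an improved confirmatory
    test or a >= 50% fall in plasma aldosterone from baseline.  Otherwise
    *absent*.
    """
    _require(record, ["potassium_post", "arr_post"])
    k_ok = record.potassium_post >= k_threshold
    arr_ok = record.arr_post < arr_threshold
    if k_ok and arr_ok:
        return "complete"
    if k_ok and not arr_ok:
        improved = bool(record.confirmatory_test_improved)
        fell = False
        if record.aldosterone_post is not None and record.aldosterone:
            fell = record.aldosterone_post <= 0.5 * record.aldosterone
        if improved or fell:
            return "partial"
    return "absent"


def final_bapwv(record: PatientRecord) -> float:
    """Final brachial-ankle pulse wave velocity in cm/s.

    Each side is measured twice; the final value is the maximum of the two
    per-side means.
    """
    if record.bapwv_right is None or record.bapwv_left is None:
        raise ValueError(
            f"patient {record.sample_id}: both baPWV sides are required"
        )
    right = sum(record.bapwv_right) / 2.0
    left = sum(record.bapwv_left) / 2.0
    return max(right, left)


def assign_carrier_status(
    cohort: Iterable[PatientRecord],
    calls: Iterable,
    sanger: Dict[str, str],
) -> List[PatientRecord]:
    """Set each patient's genotype group from screening results.

    ``sanger`` maps sample_id -> mutated gene for hotspot-screening carriers;
    ``calls`` are pathogenicity calls whose retained entries define NGS
    carriers.  A sample is a carrier once, however many retained variants it
    has.  A sample in both sources violates the pipeline contract (NGS runs
    only on Sanger-negatives) and raises.
    """
    ngs_gene: Dict[str, str] = {}
    for call in calls:
        if call.final == "retained":
            ngs_gene.setdefault(call.sample_id, call.gene)

    overlap = set(sanger) & set(ngs_gene)
    if overlap:
        raise ValueError(
            f"samples present in both Sanger mapping and NGS calls: "
            f"{sorted(overlap)} (NGS runs only on Sanger-negative samples)"
        )

    out = []
    for rec in cohort:
        if rec.sample_id in sanger:
            out.append(replace(rec, genotype_group="sanger_carrier",
                               carrier_gene=sanger[rec.sample_id]))
        elif rec.sample_id in ngs_gene:
            out.append(replace(rec, genotype_group="ngs_carrier",
                               carrier_gene=ngs_gene[rec.sample_id]))
        else:
            out.append(replace(rec, genotype_group="non_carrier",
                               carrier_gene=None))
    return out


@dataclass
class PrevalenceSummary:
    per_gene: Dict[str, Tuple[int, float]]  # gene -> (count, percent of total)
    n_total: int
    n_carriers: int
    overall_percent: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "count": c, "percent": p}
            for g, (c, p) in sorted(
                self.per_gene.items(), key=lambda kv: (-kv[1][0], kv[0])
            )
        ]
        return pd.DataFrame(rows)


def prevalence_summary(
    sanger_counts: Dict[str, int],
    calls: Iterable,
    n_total: int,
) -> PrevalenceSummary:
    """Combine hotspot-screening counts with NGS retained-sample counts.

    Per-gene count = Sanger carriers + distinct NGS samples with a retained
    call in that gene; overall prevalence = total carrier samples / n_total.
    """
    per_gene_samples: Dict[str, set] = {}
    ngs_samples = set()
    for call in calls:
        if call.final == "retained":
            per_gene_samples.setdefault(call.gene, set()).add(call.sample_id)
            ngs_samples.add(call.sample_id)

    genes = set(sanger_counts) | set(per_gene_samples)
    per_gene = {}
    for gene in genes:
        count = sanger_counts.get(gene, 0) + len(per_gene_samples.get(gene, set()))
        per_gene[gene] = (count, 100.0 * count / n_total if n_total else 0.0)

    n_carriers = sum(sanger_counts.values()) + len(ngs_samples)
    if n_total < n_carriers:
        raise ValueError("n_total cannot be smaller than the carrier count")
    overall = 100.0 * n_carriers / n_total if n_total else 0.0
    return PrevalenceSummary(per_gene, n_total, n_carriers, overall)


def contingency_test(table, test: str = "pearson_chi2") -> AssociationResult:
    """Association test on an r x c count table.

    ``pearson_chi2`` is Pearson's chi-square without continuity correction
    (df = (r-1)(c-1)); ``fisher_exact`` is the exact test for 2x2 tables.  A
    zero row/column margin is an error naming the margin.
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("need an r x c table with r, c >= 2")
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be non-negative integers")
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    if (row_sums == 0).any():
        raise ValueError(f"zero row margin at row {int(np.argmin(row_sums))}")
    if (col_sums == 0).any():
        raise ValueError(f"zero column margin at column {int(np.argmin(col_sums))}")

    if test == "pearson_chi2":
        chi2, p, df, _ = stats.chi2_contingency(counts, correction=False)
        return AssociationResult(counts.astype(int), test, float(chi2), int(df), float(p))
    if test == "fisher_exact":
        if counts.shape != (2, 2):
            raise ValueError("fisher_exact supports 2x2 tables only")
        oddsr, p = stats.fisher_exact(counts)
        return AssociationResult(
            counts.astype(int), test, float(oddsr), None, float(p),
            odds_ratio=float(oddsr),
        )
    raise ValueError(f"unknown test {test!r}")


def outcome_crosstab(
    cohort: Iterable[PatientRecord],
    grouping: Callable[[PatientRecord], str],
    outcome: str = "clinical",
    test: str = "pearson_chi2",
    outcome_levels: Sequence[str] = ("complete", "absent", "partial"),
    **thresholds,
) -> AssociationResult:
    """Cross-tabulate an outcome against a genotype partition and test it.

    ``grouping`` maps a patient to a group label; rows follow first
    appearance order, columns follow ``outcome_levels``.
    """
    if outcome == "clinical":
        classify = lambda r: classify_clinical_outcome(r, **thresholds)
    elif outcome == "biochemical":
        classify = lambda r: classify_biochemical_outcome(r, **thresholds)
    else:
        raise ValueError(f"unknown outcome {outcome!r}")

    groups: List[str] = []
    counts: Dict[str, Dict[str, int]] = {}
    for rec in cohort:
        g = grouping(rec)
        if g not in counts:
            groups.append(g)
            counts[g] = {lvl: 0 for lvl in outcome_levels}
        counts[g][classify(rec)] += 1
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    table = np.array([[counts[g][lvl] for lvl in outcome_levels] for g in groups])
    # drop all-zero outcome columns (levels unobserved in this cohort)
    table = table[:, table.sum(axis=0) > 0]
    return contingency_test(table, test=test)


def crude_odds_ratio(table) -> AssociationResult:
    """Crude odds ratio for a 2x2 table with a Woolf (log-normal) 95% CI.

    OR = (a*d)/(b*c).  If any cell is zero, the Haldane-Anscombe correction
    (add 0.5 to every cell) is applied to both the estimate and the CI.
    """
    counts = np.asarray(table, dtype=float)
    if counts.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    work = counts + 0.5 if (counts == 0).any() else counts
    a, b = work[0]
    c, d = work[1]
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.975)
    lo, hi = math.exp(math.log(or_) - z * se), math.exp(math.log(or_) + z * se)
    fisher = contingency_test(counts.astype(int), test="fisher_exact")
    return AssociationResult(
        counts.astype(int), "crude_odds_ratio", float(or_), None,
        fisher.p_value, odds_ratio=float(or_), ci_low=float(lo), ci_high=float(hi),
    )


@dataclass(frozen=True)
class LRTestResult:
    covariate: str
    chi2: float
    df: int
    p_value: float
    converged: bool


@dataclass
class MultinomialLRReport:
    per_covariate: Dict[str, LRTestResult]
    overall_chi2: float
    overall_df: int
    overall_p: float
    accuracy: float
    n_used: int
    n_dropped: int
    converged: bool


def _fit_mnlogit(y_codes: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    model = sm.MNLogit(y_codes, sm.add_constant(X, has_constant="add"))
    with np.errstate(all="ignore"):
        try:
            res = model.fit(method="newton", maxiter=200, disp=0)
        except Exception:
            # singular Hessian (degenerate covariate, separation): gradient
            # methods still reach the maximum-likelihood region
            res = model.fit(method="bfgs", maxiter=500, disp=0)
    converged = bool(res.mle_retvals.get("converged", True))
    return res, converged


def multinomial_lr_tests(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    reference: str = "absent",
) -> MultinomialLRReport:
    """Likelihood-ratio tests for each covariate in a multinomial logit.

    The outcome must have three levels; ``reference`` is the base category so
    both remaining contrasts are estimated.  For each covariate the statistic
    is twice the log-likelihood difference between the full model and the
    model omitting that covariate (df = 2 per scalar covariate).  Also
    reported: the full-vs-null improvement chi-square and the in-sample
    classification accuracy of the full model.  Rows with any missing value
    are dropped (listwise deletion) and counted in ``n_dropped``.
    """
    cols = [outcome, *covariates]
    frame = data[cols]
    n_before = len(frame)
    frame = frame.dropna()
    n_used, n_dropped = len(frame), n_before - len(frame)

    levels = sorted(frame[outcome].unique())
    if len(levels) != 3:
        raise ValueError(f"outcome must have 3 observed levels, got {levels}")
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not observed")
    ordered = [reference] + [lvl for lvl in levels if lvl != reference]
    y = pd.Categorical(frame[outcome], categories=ordered).codes.astype(int)
    X = frame[list(covariates)].astype(float)
    n_params = (len(covariates) + 1) * (len(levels) - 1)
    if n_used <= n_params:
        raise ValueError("not enough observations for the parameter count")

    full, full_conv = _fit_mnlogit(y, X)

    per_cov: Dict[str, LRTestResult] = {}
    for cov in covariates:
        reduced_X = X.drop(columns=[cov])
        try:
            reduced, red_conv = _fit_mnlogit(y, reduced_X)
            lr = max(0.0, 2.0 * (full.llf - reduced.llf))
            df = 2
            p = float(stats.chi2.sf(lr, df))
            per_cov[cov] = LRTestResult(cov, float(lr), df, p,
                                        full_conv and red_conv)
        except Exception:  # separation / singular fit: flagged, not silent
            per_cov[cov] = LRTestResult(cov, float("nan"), 2, float("nan"), False)

    null_ll = _null_loglik(y)
    overall_chi2 = max(0.0, 2.0 * (full.llf - null_ll))
    overall_df = 2 * len(covariates)
    overall_p = float(stats.chi2.sf(overall_chi2, overall_df))
    predicted = np.asarray(full.predict()).argmax(axis=1)
    accuracy = float((predicted == y).mean())

    return MultinomialLRReport(
        per_covariate=per_cov,
        overall_chi2=float(overall_chi2),
        overall_df=overall_df,
        overall_p=overall_p,
        accuracy=accuracy,
        n_used=n_used,
        n_dropped=n_dropped,
        converged=full_conv,
    )


def _null_loglik(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only multinomial model."""
    n = len(y)
    ll = 0.0
    for lvl in np.unique(y):
        k = int((y == lvl).sum())
        ll += k * math.log(k / n)
    return ll


# --- cohort CSV I/O ---------------------------------------------------------
#
# Column dictionary: scalar fields use their PatientRecord names; the paired
# baPWV measurements are flattened to bapwv_right_1/_2 and bapwv_left_1/_2.
# Missing values are empty cells.

_SCALAR_COLUMNS = [
    "sample_id", "genotype_group", "carrier_gene", "sex", "age", "bmi",
    "sbp", "dbp", "pra", "aldosterone", "log_arr", "potassium", "creatinine",
    "cystatin_c", "microalbuminuria", "tumor_size",
    "n_antihypertensives_pre", "sbp_post", "dbp_post",
    "n_antihypertensives_post", "potassium_post", "arr_post",
    "aldosterone_post", "confirmatory_test_improved",
]
COHORT_CSV_COLUMNS = (
    _SCALAR_COLUMNS[:16]
    + ["bapwv_right_1", "bapwv_right_2", "bapwv_left_1", "bapwv_left_2"]
    + _SCALAR_COLUMNS[16:]
)


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for rec in cohort:
        row = {c: getattr(rec, c) for c in _SCALAR_COLUMNS}
        for side in ("right", "left"):
            pair = getattr(rec, f"bapwv_{side}")
            row[f"bapwv_{side}_1"] = None if pair is None else pair[0]
            row[f"bapwv_{side}_2"] = None if pair is None else pair[1]
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_CSV_COLUMNS)


def frame_to_cohort(frame: pd.DataFrame) -> List[PatientRecord]:
    records = []
    for _, row in frame.iterrows():
        kwargs = {}
        for col in _SCALAR_COLUMNS:
            value = row.get(col)
            if pd.isna(value):
                value = None
            kwargs[col] = value
        for name in ("n_antihypertensives_pre", "n_antihypertensives_post"):
            if kwargs[name] is not None:
                kwargs[name] = int(kwargs[name])
        if kwargs["confirmatory_test_improved"] is not None:
            kwargs["confirmatory_test_improved"] = bool(kwargs["confirmatory_test_improved"])
        for side in ("right", "left"):
            a, b = row.get(f"bapwv_{side}_1"), row.get(f"bapwv_{side}_2")
            kwargs[f"bapwv_{side}"] = (
                None if pd.isna(a) or pd.isna(b) else (float(a), float(b))
            )
        records.append(PatientRecord(**kwargs))
    return records


def write_cohort_csv(cohort: Iterable[PatientRecord], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> List[PatientRecord]:
    return frame_to_cohort(pd.read_csv(path))
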