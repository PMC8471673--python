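# Methods

## Scope and data model

The pipeline starts at *called, annotated* variants: each record carries
coordinates (1-based, VCF convention, forward-strand alleles), the gene
symbol from the seven-gene aldosterone-driver panel, the protein change, a
coding consequence, the variant allele frequency (VAF, percent), population
evidence (dbSNP minor-allele frequency in percent, EVS/1000-Genomes
membership flags, gnomAD and ExAC hit counts) and precomputed in-silico
scores (CADD; PolyPhen-2 score and category; SIFT score and category).
Nothing recomputes or fetches annotations. An annotation that was not
observed is absent (`None`), never zero: "measured zero" and "not looked up"
behave differently in the population filters, and serialization (TSV or VCF
with configurable INFO keys) preserves the distinction exactly.

The packaged fixture encodes the published 21-variant NGS call set, one row
per sample event (the *ATP2B3* Gly1189Ser change appears in two samples).
Positions are synthetic placeholders (gene anchor + 3 × residue number)
because the source table reports chromosome labels only; they are flagged as
such in the fixture header. Two encoding notes: the SIFT entries printed as
score 0 with prediction "n/a" are stored with SIFT absent, following the
prediction column (retention is unaffected either way); and the *CLCN2*
Gly466Ala PolyPhen-2 score of 0.489 keeps its printed *probably damaging*
category even though conventional score bands would call it *possibly
damaging* — the category column is trusted as given.

## Filter cascade

Steps run in a fixed order — VAF, consequence, population, somatic — and
each emits an audit entry whose counts conserve (input = excluded +
retained). Because every step is a pure per-record predicate, the retained
set is order-independent and the cascade is idempotent; the test suite
checks both, plus agreement with an independent per-predicate oracle on
1,500 random records.

Parameters (defaults): `vaf_floor` 5.0% (inclusive), `dbsnp_maf_max` 1.0%,
`gnomad_hits_max` 5 and `exac_hits_max` 1 (both strict "more than"),
`kept_consequences` = {missense, nonsense, frameshift, splice_site}.
"Non-synonymous" is read as missense ∪ nonsense; start-loss/stop-loss map to
`other` unless configured. The published filtering criteria state both a 10%
exclusion floor and a 30% keep rule, yet the published call set retains VAFs
from 5.07% to 48.37%; the two readings cannot be reconciled, so the floor is
a parameter defaulting to 5.0% (the value consistent with the published
calls) and the 30% criterion is available as an optional `vaf_keep_threshold`
rescue — calls strictly above it bypass the population filters — disabled by
default. Exclusion reasons are first-match-wins in the documented order
(dbSNP, EVS, TGP, gnomAD, ExAC) so audits are deterministic. Somatic
confirmation removes tumor calls whose `(sample, chrom, pos, ref, alt)` key
appears in matched blood; with no blood table the step is recorded as
skipped rather than silently passing.

## Pathogenicity consensus

Five verdicts per candidate, each `damaging`, `not_damaging` or
`not_applicable` (input missing):

| tool | damaging when | default cutoff |
| --- | --- | --- |
| CADD | score ≥ global cutoff | 20 |
| MSC-CADD | score ≥ gene-level MSC | per-gene table |
| PP2 | category = probably_damaging | — |
| MSC-PP2 | score ≥ gene-level MSC | per-gene table |
| SIFT | score ≤ 0.05 | 0.05 |

A candidate passes the consensus when its `not_damaging` count is at most
the dissent threshold (default 1); `not_applicable` votes are neutral, so
removing a dissenting score can never reject a previously retained call
(tested exhaustively). Route precedence is disease-database membership,
then null-variant consequence (nonsense, frameshift, obligatory splice
site, initial codon — structural damage needs no score consensus in genes
where gain/alteration of function is an established mechanism), then the
consensus vote. Cutoff comparisons are inclusive on the damaging side; the
published data contain no observations exactly at a cutoff that would
discriminate between conventions, so the inclusive reading was fixed once
and documented here. The rule is verified against a brute-force enumeration
of all 3⁵ verdict combinations crossed with both override flags.

The gene-cutoff table covers the six genes with published MSC values;
*KCNJ5* is deliberately absent (hotspot screening handles it before NGS),
and looking up a gene without cutoffs is a defined error rather than a
silent default.

## Outcome classification and association statistics

PASO calls at 12 months post-adrenalectomy:

* **Clinical complete** — both pressures strictly below the normal-BP
  threshold (default 140/90 mmHg; the source criteria do not pin the number,
  so it is configurable) with zero antihypertensives. **Partial** — same BP
  on fewer drugs, or reduced BP (neither component higher, at least one
  strictly lower) on the same number of drugs or fewer. Else **absent**.
* **Biochemical complete** — potassium ≥ 3.5 mmol/L and ARR < 38 (the
  operationalized footnote definition, preferred over the vaguer prose).
  **Partial** — hypokalemia corrected with ARR still raised, plus an improved
  confirmatory test or a ≥ 50% fall in plasma aldosterone. Else **absent**.

Final baPWV is the maximum of the two per-side means of duplicate
measurements. Carrier assignment is Sanger mapping first, then ≥ 1 retained
NGS call (a sample counts once); a sample in both sources violates the
screening contract (NGS runs only on Sanger-negatives) and raises.

Group comparisons use Pearson χ² without continuity correction as the
default r×c test — it reproduces the published p = 0.010 (clinical 3×2) and
p = 0.440 (biochemical 3×2) — with Fisher's exact test opt-in for 2×2 tables
(cross-checked against full hypergeometric enumeration). Crude odds ratios
use the cross-product with a Woolf log-normal 95% CI and the
Haldane–Anscombe +0.5 correction when a cell is zero. Multinomial logistic
models (reference category *absent*, so both the *complete* and *partial*
contrasts are estimated; covariates untransformed; listwise deletion with a
logged count) are fit by Newton's method with a BFGS fallback for singular
Hessians; each covariate's likelihood-ratio χ² is twice the log-likelihood
difference against the model omitting it (df = 2 per scalar covariate), and
the report includes the full-vs-null improvement and in-sample
classification accuracy. Non-convergence is flagged per covariate, never
silent.

## Synthetic data

The generator defines the conditions everything stochastic is tested under.
Variant tables: carriers are drawn per sample at fraction 21/75; each
carrier gets exactly one driver (the published set shows one mutation per
sample) whose score profile is resampled from the published rows with small
jitter clipped to preserve every tool verdict, and whose VAF is uniform on
[5, 50]% (spanning the published 5.07–48.37%). Decoys (120 by default, equal
mix) each violate exactly one named rule: population-common (one of the five
population rules at random), synonymous, low-VAF (uniform on [0.5, 4.9]%),
or germline (VAF ≈ 50%, mirrored into the blood table). X-linked *ATP2B3*
VAFs are simulated like autosomes; ploidy-aware VAF modelling is out of
scope.

Cohorts: clinical outcome probabilities are carriers (0.714, 0.143, 0.143)
and non-carriers (0.333, 0.426, 0.241) for complete/partial/absent, and
biochemical (0.857, 0, 0.143) vs (0.796, 0.074, 0.130), matching the
published outcome frequencies; covariates are normals truncated at physical
bounds with the published means and SDs (age 54.5 ± 10.6 y, BMI 26.2 ± 4.0,
sBP 152.0 ± 20.8 mmHg, tumor size 2.09 ± 2.57 cm, baPWV 1722 ± 329 cm/s,
female fraction 0.573, …). Post-surgery fields are constructed so the PASO
classifiers reproduce the sampled labels exactly — this makes truth recovery
a sharp zero-error check of the classifiers' wiring, not a statement about
classifier robustness on noisy real follow-up data. All randomness flows
through `numpy.random.default_rng` (PCG64) from a mandatory seed.

What passing synthetic tests shows — and does not. The planted cases are
deliberately unambiguous (drivers comfortably inside every cutoff, decoys
violating exactly one rule), so zero-error recovery validates the logic of
the cascade/consensus/assignment chain, not its behaviour on borderline real
variants. Likewise, the regression study (power ≥ 0.8 for the planted
carrier effect at n = 300 over 200 replicates; null covariates near the
nominal 5%; uniform permutation-null p-values) validates the test machinery
under the generating model, not the published adjusted estimates: the
adjusted OR 10.9 (CI 1.7–69.2), the per-covariate likelihood-ratio table and
the CYP11B2-positive subgroup OR 481.9 depend on unreleased patient-level
covariates and are not reproducible from printed summaries. The published
carrier-vs-carrier comparison p = 0.271 (NGS vs Sanger carriers) is also not
reproduced: no standard test on the printed counts yields it, and the
originating test is not identifiable.

## Numerical and problem-size choices

Pipeline outputs are deterministic and byte-identical across reruns
(timestamps live only in the run log; configurations are content-hashed).
VCF INFO floats are stored single-precision by the format, so readers round
to four decimals — exact for every score in scope, which carries at most
four decimals. Property-based checks use 1,200–1,500 random variants per
table; convergence checks use cohorts of 10,000 (tolerance 0.02 on outcome
frequencies, ±0.01 on the 0.714 carrier complete-success rate); the
regression study uses 200 replicates of n = 300 cohorts. These sizes give
stable Monte-Carlo estimates while keeping the full suite fast to iterate
on.
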