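"""Packaged study inputs: the published variant fixture and summary counts.

The cohort's raw sequencing and patient-level clinical data are not publicly
deposited, so the shipped inputs are (a) the published per-variant annotation
table for the 21 NGS-retained somatic calls, (b) the per-gene score cutoffs,
and (c) the printed cohort summary counts (hotspot-screening carrier counts
and the 3x2 / 2x2 surgical-outcome tables) used by the association analyses.
"""

from __future__ import annotations

from importlib import resources
from typing import Dict

import numpy as np

from .io import load_gene_cutoffs, read_annotated_variants
from .models import GeneCutoffs, VariantTable

__all__ = [
    "published_variant_table",
    "published_gene_cutoffs",
    "SANGER_POSITIVE_COUNTS",
    "N_COHORT_TOTAL",
    "N_NGS_SCREENED",
    "OUTCOME_LEVELS",
    "CLINICAL_OUTCOME_COUNTS",
    "BIOCHEMICAL_OUTCOME_COUNTS",
    "COMBINED_CARRIER_2X2",
    "CRUDE_OR_2X2",
]

#: Carrier counts from first-pass Sanger hotspot screening of all 240 samples.
SANGER_POSITIVE_COUNTS: Dict[str, int] = {"KCNJ5": 151, "CTNNB1": 10, "ATP1A1": 4}

#: Total adrenal tumor DNA samples in the cohort.
N_COHORT_TOTAL = 240

#: Hotspot-negative samples that went on to the targeted NGS panel.
N_NGS_SCREENED = 75

#: Row/column conventions for the outcome count tables below: rows are
#: (NGS-mutation carriers, non-carriers); columns follow the published order
#: (complete, absent, partial) success at 12 months post-adrenalectomy.
OUTCOME_LEVELS = ("complete", "absent", "partial")

CLINICAL_OUTCOME_COUNTS = np.array([[15, 3, 3], [18, 13, 23]])
BIOCHEMICAL_OUTCOME_COUNTS = np.array([[18, 3, 0], [43, 7, 4]])

#: Complete clinical success vs not, for combined (Sanger + NGS) carriers
#: against non-carriers: rows (carrier, non-carrier), columns (complete, not).
COMBINED_CARRIER_2X2 = np.array([[130, 56], [18, 36]])

#: Complete clinical success vs not, NGS carriers against non-carriers,
#: for the crude odds-ratio illustration.
CRUDE_OR_2X2 = np.array([[15, 6], [18, 36]])


def _data_path(name: str):
    return resources.files("aldoprio").joinpath("data", name)


def published_variant_table() -> VariantTable:
    """The 21-variant NGS fixture (one row per sample event)."""
    with resources.as_file(_data_path("published_variants.tsv")) as path:
        return read_annotated_variants(path, dialect="tsv")


def published_gene_cutoffs(cadd_global: float = 20.0) -> Dict[str, GeneCutoffs]:
    """Per-gene MSC cutoffs for the six NGS-hit genes."""
    with resources.as_file(_data_path("gene_cutoffs.tsv")) as path:
        return load_gene_cutoffs(path, cadd_global=cadd_global)
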