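#!/usr/bin/env python
"""Combined mutation prevalence across hotspot (Sanger) and NGS screening.

Adds the NGS-retained sample counts to the hotspot-screening carrier counts
(KCNJ5 151, CTNNB1 10, ATP1A1 4) over the full 240-sample cohort.  Expected
outcome: 186/240 carriers (77.5%), with KCNJ5 151, CTNNB1 11, CACNA1D 9,
ATP1A1 5, CACNA1H 5, ATP2B3 3 and CLCN2 2.
"""

from pathlib import Path

from aldoprio.consensus import classify_table
from aldoprio.datasets import (
    N_COHORT_TOTAL,
    SANGER_POSITIVE_COUNTS,
    published_gene_cutoffs,
    published_variant_table,
)
from aldoprio.cohort import prevalence_summary

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    calls = classify_table(published_variant_table(), published_gene_cutoffs())
    prev = prevalence_summary(SANGER_POSITIVE_COUNTS, calls, n_total=N_COHORT_TOTAL)
    print(
        f"overall: {prev.n_carriers}/{prev.n_total} samples carry a driver "
        f"mutation ({prev.overall_percent:.1f}%)"
    )
    frame = prev.to_frame()
    print(frame.to_string(index=False, float_format=lambda x: f"{x:.1f}"))

    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "prevalence.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'prevalence.tsv'}")


if __name__ == "__main__":
    main()
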