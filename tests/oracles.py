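"""Independent brute-force oracles used to cross-check the implementation.

Everything here re-derives expected results from first principles (per-record
predicate evaluation, exhaustive enumeration, closed-form counting) without
touching the code paths under test.
"""

from __future__ import annotations

import math
from typing import Set

import numpy as np

from aldoprio.models import AnnotatedVariant, VariantTable

PANEL = ("KCNJ5", "ATP1A1", "ATP2B3", "CACNA1D", "CACNA1H", "CLCN2", "CTNNB1")
CHROM_OF = {
    "KCNJ5": "11", "ATP1A1": "1", "ATP2B3": "X", "CACNA1D": "3",
    "CACNA1H": "16", "CLCN2": "3", "CTNNB1": "3",
}
CONSEQ = ("missense", "nonsense", "frameshift", "splice_site", "synonymous", "other")


def random_variant(rng: np.random.Generator, sample_id: str, pos: int) -> AnnotatedVariant:
    """A random annotated variant with a realistic mix of absent fields."""
    gene = PANEL[rng.integers(0, len(PANEL))]
    consequence = CONSEQ[rng.integers(0, len(CONSEQ))]
    protein_change = (
        f"Gln{int(rng.integers(1, 999))}Ter"
        if consequence == "nonsense"
        else f"Leu{int(rng.integers(1, 999))}Ile"
    )
    maybe = lambda value, p=0.5: value if rng.random() < p else None
    ref, alt = ("C", "T") if rng.random() < 0.5 else ("G", "A")
    return AnnotatedVariant(
        sample_id=sample_id,
        gene=gene,
        chrom=CHROM_OF[gene],
        pos=pos,
        ref=ref,
        alt=alt,
        protein_change=protein_change,
        consequence=consequence,
        vaf=float(np.round(rng.uniform(0, 100), 2)),
        dbsnp_maf=maybe(float(np.round(rng.uniform(0, 5), 3))),
        in_evs=bool(rng.random() < 0.15),
        in_tgp=bool(rng.random() < 0.15),
        gnomad_hits=maybe(int(rng.integers(0, 12))),
        exac_hits=maybe(int(rng.integers(0, 4))),
        cadd=maybe(float(np.round(rng.uniform(0, 40), 1))),
        pp2_score=maybe(float(np.round(rng.uniform(0, 1), 3))),
        pp2_category=maybe(
            ("probably_damaging", "possibly_damaging", "benign")[rng.integers(0, 3)]
        ),
        sift_score=maybe(float(np.round(rng.uniform(0, 1), 3))),
        sift_category=maybe(("deleterious", "tolerated")[rng.integers(0, 2)]),
        in_disease_db=bool(rng.random() < 0.1),
    )


def random_table(rng: np.random.Generator, n: int, prefix: str = "R") -> VariantTable:
    return VariantTable(
        records=[
            random_variant(rng, f"{prefix}{i % 40:03d}", 1_000_000 + 7 * i)
            for i in range(n)
        ]
    )


def cascade_oracle(
    record: AnnotatedVariant,
    blood_keys: Set,
    vaf_floor: float = 5.0,
    kept_consequences=frozenset({"missense", "nonsense", "frameshift", "splice_site"}),
) -> bool:
    """Independent evaluation of every filtering predicate on one record."""
    if record.vaf < vaf_floor:
        return False
    if record.consequence not in kept_consequences:
        return False
    if record.dbsnp_maf is not None and record.dbsnp_maf > 1.0:
        return False
    if record.in_evs or record.in_tgp:
        return False
    if record.gnomad_hits is not None and record.gnomad_hits > 5:
        return False
    if record.exac_hits is not None and record.exac_hits > 1:
        return False
    if record.key in blood_keys:
        return False
    return True


def consensus_route_oracle(
    in_disease_db: bool, is_null: bool, n_not_damaging: int, threshold: int = 1
) -> str:
    """Enumerated precedence: disease db, then null variant, then consensus."""
    if in_disease_db:
        return "disease_db"
    if is_null:
        return "null_variant"
    if n_not_damaging <= threshold:
        return "consensus_novel"
    return "rejected"


def fisher_2x2_enumeration(table) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins."""
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x: int) -> float:
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))
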