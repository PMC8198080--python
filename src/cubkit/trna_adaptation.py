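"""Codon–anticodon adaptation: does each amino acid's preferred codon pair
with the most abundant tRNA isoacceptor of the species?

Matching is strict Watson–Crick reverse complement (DNA alphabet, 5'→3' as
in GtRNAdb); wobble decoding (G:U, inosine) is deliberately not modeled,
though :func:`adaptation_report` accepts a custom cognate function as an
extension hook. Met and Trp have single-codon families: they are reported
descriptively but excluded from optimality statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .genetic_code import AA_1TO3, SYN_FAMILIES, reverse_complement
from .rscu import RSCUTable
from .sequence_io import TRNAGeneTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdaptationRecord:
    amino_acid: str  # 3-letter
    preferred_codon: str
    preferred_rscu: float | None
    cognate_anticodon: str
    cognate_count: int
    max_isotypes: tuple[str, ...]  # all anticodons tied at the family max
    family_total: int
    is_optimal: bool
    single_codon_family: bool


def anticodon_for(codon: str) -> str:
    """Watson–Crick cognate anticodon of a codon (reverse complement)."""
    if len(codon) != 3:
        raise ValueError(f"codon must be length 3: {codon!r}")
    return reverse_complement(codon.upper())


def isotype_totals(trna: TRNAGeneTable) -> dict[str, int]:
    """Total tRNA gene count per amino acid."""
    out: dict[str, int] = {}
    for aa, fam in trna.isotypes.items():
        total = sum(fam.values())
        if total == 0:
            log.warning("amino acid %s has an empty isotype family", aa)
        out[aa] = total
    return out


def adaptation_report(
    rscu_table: RSCUTable,
    trna: TRNAGeneTable,
    cognate_fn: Callable[[str], str] = anticodon_for,
) -> list[AdaptationRecord]:
    """Per-amino-acid adaptation records for one species.

    The preferred codon is the family's RSCU maximum (ties resolved to the
    lexicographically first codon, logged); it is optimal when its cognate
    anticodon's gene count equals the family maximum and is positive.
    """
    records: list[AdaptationRecord] = []
    for aa1, family in sorted(SYN_FAMILIES.items()):
        aa3 = AA_1TO3[aa1]
        if aa3 not in trna.isotypes:
            raise KeyError(f"amino acid {aa3} missing from tRNA table {trna.species}")
        isotypes = dict(trna.isotypes[aa3])
        single = len(family) == 1
        if single:
            preferred, pref_rscu = family[0], None
        else:
            vals = {c: rscu_table.values[c] for c in family}
            if all(v is None for v in vals.values()):
                continue
            best = max(v for v in vals.values() if v is not None)
            tied = sorted(c for c, v in vals.items() if v == best)
            if len(tied) > 1:
                log.info("%s: RSCU tie among %s; using %s", aa3, tied, tied[0])
            preferred, pref_rscu = tied[0], best
        cognate = cognate_fn(preferred)
        cognate_count = isotypes.get(cognate, 0)
        fam_max = max(isotypes.values()) if isotypes else 0
        max_isos = tuple(sorted(a for a, n in isotypes.items() if n == fam_max and fam_max > 0))
        records.append(
            AdaptationRecord(
                amino_acid=aa3,
                preferred_codon=preferred,
                preferred_rscu=pref_rscu,
                cognate_anticodon=cognate,
                cognate_count=cognate_count,
                max_isotypes=max_isos,
                family_total=sum(isotypes.values()),
                is_optimal=cognate_count > 0 and cognate_count == fam_max,
                single_codon_family=single,
            )
        )
    return records


def report_frame(records: list[AdaptationRecord]) -> pd.DataFrame:
    rows = [
        {
            "amino_acid": r.amino_acid,
            "preferred_codon": r.preferred_codon,
            "preferred_rscu": r.preferred_rscu,
            "cognate_anticodon": r.cognate_anticodon,
            "cognate_count": r.cognate_count,
            "max_isotypes": ",".join(r.max_isotypes),
            "family_total": r.family_total,
            "is_optimal": r.is_optimal,
            "single_codon_family": r.single_codon_family,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("amino_acid")


def optimal_amino_acids(records: list[AdaptationRecord]) -> list[str]:
    """Amino acids whose preferred codon matches the top isoacceptor,
    excluding the single-codon families (Met, Trp)."""
    return [r.amino_acid for r in records if r.is_optimal and not r.single_codon_family]
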