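"""Standard nuclear genetic code: codon universe, synonymous families, degeneracy.

All five study species are mammals, so translation table 1 is fixed; alternative
codes are deliberately out of scope. The canonical internal alphabet is DNA
(T, not U); report layers may render U to match codon-usage conventions.
"""

from __future__ import annotations

from Bio.Data import CodonTable

BASES = "ACGT"
CODONS: tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

_standard = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
START_CODON = "ATG"

#: codon -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)

#: one-letter amino acid -> tuple of synonymous codons (alphabetical)
SYN_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYN_FAMILIES.setdefault(_aa, ())
    SYN_FAMILIES[_aa] += (_codon,)

#: degeneracy (family size) per amino acid
DEGENERACY: dict[str, int] = {aa: len(c) for aa, c in SYN_FAMILIES.items()}

#: the 18 amino acids with ≥2 synonymous codons (Met and Trp excluded)
DEGENERATE_AAS: tuple[str, ...] = tuple(
    aa for aa, k in sorted(DEGENERACY.items()) if k >= 2
)

#: the 59 sense codons belonging to degenerate families (the RSCU universe)
RSCU_CODONS: tuple[str, ...] = tuple(
    c for aa in DEGENERATE_AAS for c in SYN_FAMILIES[aa]
)

#: degeneracy class -> amino acids, as used by Wright's ENc
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa in DEGENERATE_AAS:
    DEGENERACY_CLASSES.setdefault(DEGENERACY[_aa], ())
    DEGENERACY_CLASSES[DEGENERACY[_aa]] += (_aa,)

AA_1TO3: dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
AA_3TO1: dict[str, str] = {v: k for k, v in AA_1TO3.items()}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase A/C/G/T)."""
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGT characters: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(codon: str) -> str:
    """Render a DNA codon in the RNA alphabet (T→U) for report tables."""
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    """Normalize an RNA or DNA codon to the canonical DNA alphabet."""
    return codon.upper().replace("U", "T")
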