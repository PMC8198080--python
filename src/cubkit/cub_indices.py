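"""Codon-usage-bias indices: Wright's effective number of codons (ENc), the
expected ENc–GC3 curve, the codon adaptation index (CAI), and the P2
translational-selection index.

ENc summarizes how many codons a gene effectively uses, from 20 (one codon
per amino acid, absolute bias) to 61 (uniform synonymous usage, no bias).
Per family, the homozygosity estimator is

    F̂ = (n · Σ p_j² − 1) / (n − 1),   p_j = x_j / n,

and ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ over the degeneracy-class means.

CAI is the geometric mean of relative adaptiveness w = f / f_max of each
codon against a reference usage table; 1 means fully optimal codon choice.

P2 = (WWC + SSU) / (WWY + SSY) contrasts pyrimidine choice at the third
position within weak-weak (A/T at positions 1–2) and strong-strong (G/C)
codon classes; values above 0.5 are read as translational selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY_CLASSES,
    DEGENERATE_AAS,
    SYN_FAMILIES,
    to_dna,
)
from .rscu import RSCUTable
from .sequence_io import CodingSequence, CodonCountTable, ReferenceUsageTable, count_codons

ENC_MIN = 20.0
ENC_MAX = 61.0

RSCU_CLASS_MEAN = "RSCU_CLASS_MEAN"
COUNT_CLASSIC = "COUNT_CLASSIC"

# third-position pyrimidine classes over weak-weak and strong-strong codons
WWC_CODONS = ("AAC", "ATC", "TAC", "TTC")
WWU_CODONS = ("AAT", "ATT", "TAT", "TTT")
SSC_CODONS = ("CCC", "CGC", "GCC", "GGC")
SSU_CODONS = ("CCT", "CGT", "GCT", "GGT")


class EncUndefinedError(ValueError):
    """Gene too short or degenerate to score with Wright's estimator."""


@dataclass(frozen=True)
class EncResult:
    enc: float
    class_means: Mapping[int, float]
    per_family_F: Mapping[str, float]
    missing_classes: tuple[int, ...]
    raw_enc: float  # before clamping to [20, 61]


@dataclass(frozen=True)
class CaiResult:
    cai: float
    per_codon_w: Mapping[str, float]
    codons_used: int


@dataclass(frozen=True)
class P2Result:
    sSU: float
    wWU: float
    sSC: float
    wWC: float
    p2: float
    mode: str

    @property
    def translational_selection(self) -> bool:
        return self.p2 > 0.5


def family_homozygosity(counts: Mapping[str, int], family: tuple[str, ...]) -> float | None:
    """F̂ for one synonymous family; None when undefined (n < 2 or F̂ ≤ 0)."""
    n = sum(counts[c] for c in family)
    if n < 2:
        return None
    sum_p2 = sum((counts[c] / n) ** 2 for c in family)
    f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
    return f_hat if f_hat > 0 else None


def enc(counts: CodonCountTable) -> EncResult:
    """Wright's effective number of codons from pooled sense-codon counts.

    Families with n < 2 (or F̂ ≤ 0) are excluded from their class mean. An
    empty 3-fold class (Ile unobserved) is imputed as (F̄₂ + F̄₄)/2; any other
    empty class raises. The result is clamped to the definitional [20, 61].
    """
    per_family: dict[str, float] = {}
    class_means: dict[int, float] = {}
    missing: list[int] = []
    for k, aas in sorted(DEGENERACY_CLASSES.items()):
        f_vals = []
        for aa in aas:
            f = family_homozygosity(counts.counts, SYN_FAMILIES[aa])
            if f is not None:
                per_family[aa] = f
                f_vals.append(f)
        if f_vals:
            class_means[k] = sum(f_vals) / len(f_vals)
        else:
            missing.append(k)
    if 3 in missing and 2 in class_means and 4 in class_means:
        class_means[3] = (class_means[2] + class_means[4]) / 2.0
    if any(k not in class_means for k in (2, 3, 4, 6)):
        raise EncUndefinedError(
            f"degeneracy classes without usable families: "
            f"{[k for k in (2, 3, 4, 6) if k not in class_means]}"
        )
    raw = (
        2.0
        + 9.0 / class_means[2]
        + 1.0 / class_means[3]
        + 5.0 / class_means[4]
        + 3.0 / class_means[6]
    )
    return EncResult(
        enc=min(max(raw, ENC_MIN), ENC_MAX),
        class_means=class_means,
        per_family_F=per_family,
        missing_classes=tuple(missing),
        raw_enc=raw,
    )


def enc_for_sequence(seq: CodingSequence) -> EncResult:
    """ENc of a single CDS (stops excluded automatically)."""
    return enc(count_codons([seq], include_stops=False))


def enc_expected(s: float) -> float:
    """Expected ENc when composition (GC3 fraction ``s``) alone drives usage:
    ENc* = 2 + s + 29 / (s² + (1−s)²)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3 fraction {s} outside [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def relative_adaptiveness(reference: ReferenceUsageTable) -> dict[str, float]:
    """w = f / f_max within each family, from reference per-thousand
    frequencies; a zero reference frequency is replaced by the frequency a
    0.5 count would have had in the reference corpus before dividing."""
    total_count = sum(reference.raw_counts.values())
    if total_count <= 0:
        raise ValueError("reference table has no counts")
    pseudo = 0.5 / total_count * 1000.0
    w: dict[str, float] = {}
    for aa in DEGENERATE_AAS + ("M", "W"):
        fam = SYN_FAMILIES[aa]
        freqs = {
            c: (reference.frequencies[c] if reference.frequencies[c] > 0 else pseudo)
            for c in fam
        }
        fmax = max(freqs.values())
        if fmax <= 0:
            raise ValueError(f"reference family {aa} is all zero")
        for c in fam:
            w[c] = freqs[c] / fmax
    return w


def cai(counts: CodonCountTable, reference: ReferenceUsageTable) -> CaiResult:
    """CAI = exp of the count-weighted mean of ln w over all sense codons,
    excluding Met, Trp and stops (single-codon families carry no signal)."""
    w = relative_adaptiveness(reference)
    log_sum = 0.0
    n_used = 0
    for aa in DEGENERATE_AAS:
        for c in SYN_FAMILIES[aa]:
            x = counts.counts[c]
            if x:
                log_sum += x * math.log(w[c])
                n_used += x
    if n_used == 0:
        raise ValueError("no scorable codons in query")
    return CaiResult(cai=math.exp(log_sum / n_used), per_codon_w=w, codons_used=n_used)


def _class_mean_rscu(table: RSCUTable, codons: tuple[str, ...]) -> float:
    vals = [table.values[c] for c in codons]
    if any(v is None for v in vals):
        raise ValueError(f"RSCU undefined for {[c for c, v in zip(codons, vals) if v is None]}")
    return sum(vals) / len(vals)


def p2(source: RSCUTable | CodonCountTable, mode: str = RSCU_CLASS_MEAN) -> P2Result:
    """P2 index from an RSCU table (class means of RSCU; the reading that
    reproduces published per-species P2 tables) or from raw codon counts
    (the classic count-based variant).

    In RSCU_CLASS_MEAN mode the WWY/SSY denominators are the 8-codon union means,
    so P2 = 2·(WWC + SSU) / (WWU + WWC + SSU + SSC).
    """
    if mode == RSCU_CLASS_MEAN:
        if not isinstance(source, RSCUTable):
            raise TypeError("RSCU_CLASS_MEAN mode needs an RSCUTable")
        wwc = _class_mean_rscu(source, WWC_CODONS)
        wwu = _class_mean_rscu(source, WWU_CODONS)
        ssc = _class_mean_rscu(source, SSC_CODONS)
        ssu = _class_mean_rscu(source, SSU_CODONS)
        denom = wwu + wwc + ssu + ssc
        if denom == 0:
            raise ZeroDivisionError("all P2 class means are zero")
        value = 2.0 * (wwc + ssu) / denom
    elif mode == COUNT_CLASSIC:
        if not isinstance(source, CodonCountTable):
            raise TypeError("COUNT_CLASSIC mode needs a CodonCountTable")
        c = source.counts
        wwc = sum(c[x] for x in WWC_CODONS)
        wwu = sum(c[x] for x in WWU_CODONS)
        ssc = sum(c[x] for x in SSC_CODONS)
        ssu = sum(c[x] for x in SSU_CODONS)
        denom = wwu + wwc + ssu + ssc
        if denom == 0:
            raise ZeroDivisionError("no codons in the P2 classes")
        # classic form: (WWC + SSU) / (WWY + SSY) with count sums,
        # WWY = WWU + WWC and SSY = SSU + SSC
        value = (wwc + ssu) / denom
    else:
        raise ValueError(f"unknown P2 mode {mode!r}")
    return P2Result(sSU=float(ssu), wWU=float(wwu), sSC=float(ssc), wWC=float(wwc),
                    p2=float(value), mode=mode)
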