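"""Dinucleotide relative abundance: observed frequencies from overlapping
windows, odds ratios against an expectation, and representation classes.

Two expectation conventions are exposed. UNIFORM divides every observed
frequency by 1/16 = 0.0625; MONO_PRODUCT uses the product of pooled
mononucleotide frequencies, the conventional relative-abundance measure.
Neither is silently "corrected" into the other. An odds ratio below 0.78
marks underrepresentation; above 1.23, overrepresentation (strict
inequalities; the boundary values are NORMAL).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .genetic_code import BASES, to_rna
from .sequence_io import CodingSequence

DINUCLEOTIDES: tuple[str, ...] = tuple(a + b for a in BASES for b in BASES)

UNDER_THRESHOLD = 0.78
OVER_THRESHOLD = 1.23

UNIFORM = "UNIFORM"
MONO_PRODUCT = "MONO_PRODUCT"


@dataclass(frozen=True)
class DinucleotideProfile:
    observed: Mapping[str, float]
    expected: Mapping[str, float]
    odds_ratio: Mapping[str, float | None]
    classification: Mapping[str, str]
    expected_mode: str

    def to_frame(self, rna: bool = True) -> pd.DataFrame:
        """Table-style output: one row per dinucleotide (XpY naming)."""
        rows = []
        for d in DINUCLEOTIDES:
            name = "p".join(to_rna(ch) for ch in d) if rna else d
            rows.append(
                {
                    "dinucleotide": name,
                    "observed": self.observed[d],
                    "expected": self.expected[d],
                    "odds_ratio": self.odds_ratio[d],
                    "class": self.classification[d],
                }
            )
        return pd.DataFrame(rows).set_index("dinucleotide")


def dinucleotide_frequencies(seqs: Iterable[CodingSequence]) -> dict[str, float]:
    """Observed dinucleotide frequencies from overlapping width-2 windows.

    Windows step by 1 within each sequence and never span record boundaries;
    counts are pooled over all sequences and normalized by the pooled window
    count.
    """
    counts = {d: 0 for d in DINUCLEOTIDES}
    total = 0
    n_seqs = 0
    for s in seqs:
        n_seqs += 1
        b = s.bases
        if len(b) < 2:
            raise ValueError(f"{s.id}: sequence shorter than 2 bases")
        for i in range(len(b) - 1):
            counts[b[i : i + 2]] += 1
            total += 1
    if n_seqs == 0:
        raise ValueError("no sequences")
    return {d: c / total for d, c in counts.items()}


def mononucleotide_frequencies(seqs: Iterable[CodingSequence]) -> dict[str, float]:
    counts = {b: 0 for b in BASES}
    for s in seqs:
        for ch in s.bases:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no bases")
    return {b: c / total for b, c in counts.items()}


def classify_ratio(ratio: float | None) -> str:
    if ratio is None:
        return "UNDEFINED"
    if ratio < UNDER_THRESHOLD:
        return "UNDER"
    if ratio > OVER_THRESHOLD:
        return "OVER"
    return "NORMAL"


def odds_ratios(
    observed: Mapping[str, float],
    expected_mode: str = UNIFORM,
    mono_freqs: Mapping[str, float] | None = None,
) -> DinucleotideProfile:
    """Odds ratios observed/expected for all 16 dinucleotides.

    MONO_PRODUCT requires pooled mononucleotide frequencies; an absent base
    leaves the affected ratios undefined (flagged, not raised).
    """
    obs = {d: float(observed[d]) for d in DINUCLEOTIDES}
    s = sum(obs.values())
    if abs(s - 1.0) > 1e-6:
        raise ValueError(f"observed frequencies sum to {s}, expected 1")
    if expected_mode == UNIFORM:
        expected = {d: 1.0 / 16.0 for d in DINUCLEOTIDES}
    elif expected_mode == MONO_PRODUCT:
        if mono_freqs is None:
            raise ValueError("MONO_PRODUCT mode needs mononucleotide frequencies")
        expected = {d: mono_freqs[d[0]] * mono_freqs[d[1]] for d in DINUCLEOTIDES}
    else:
        raise ValueError(f"unknown expected_mode {expected_mode!r}")
    ratio: dict[str, float | None] = {
        d: (obs[d] / e if e > 0 else None) for d, e in expected.items()
    }
    classification = {d: classify_ratio(r) for d, r in ratio.items()}
    return DinucleotideProfile(
        observed=obs,
        expected=expected,
        odds_ratio=ratio,
        classification=classification,
        expected_mode=expected_mode,
    )


def dinucleotide_profile(
    seqs: list[CodingSequence], expected_mode: str = UNIFORM
) -> DinucleotideProfile:
    """Convenience: frequencies plus odds ratios in one call."""
    obs = dinucleotide_frequencies(seqs)
    mono = mononucleotide_frequencies(seqs) if expected_mode == MONO_PRODUCT else None
    return odds_ratios(obs, expected_mode=expected_mode, mono_freqs=mono)
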