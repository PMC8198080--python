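"""Nucleotide composition: overall and third-codon-position percentages,
GC1/GC2/GC3/GC12, and dataset summaries.

GC3 computed here is the single source of truth consumed by the neutrality
plot and the expected ENc–GC3 curve. All percentages are carried at full
precision; rounding belongs to the report layer.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import CodingSequence


@dataclass(frozen=True)
class CompositionProfile:
    """Per-sequence base composition, percentages in [0, 100]."""

    id: str
    species: str
    pct_A: float
    pct_T: float
    pct_G: float
    pct_C: float
    pct_A3: float
    pct_T3: float
    pct_G3: float
    pct_C3: float
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc_overall: float
    au_overall: float


_NUMERIC_FIELDS = [f.name for f in fields(CompositionProfile) if f.name not in ("id", "species")]


def composition_profile(seq: CodingSequence, include_stop: bool = True) -> CompositionProfile:
    """Compute a composition profile over the whole CDS.

    The terminal stop codon is part of the transcript and is included by
    default; ``include_stop=False`` drops the final codon before counting.
    Third-position metrics use one base per codon.
    """
    codons = seq.codons()
    if not include_stop:
        codons = codons[:-1]
    if not codons:
        raise ValueError(f"{seq.id}: no codons to profile")
    bases = "".join(codons)
    n = len(bases)

    def pct(chars: str, pool: str) -> float:
        return 100.0 * sum(pool.count(ch) for ch in chars) / len(pool)

    pos = ["".join(c[i] for c in codons) for i in range(3)]
    gc1, gc2, gc3 = (pct("GC", p) for p in pos)
    gc_overall = pct("GC", bases)
    return CompositionProfile(
        id=seq.id,
        species=seq.species,
        pct_A=pct("A", bases),
        pct_T=pct("T", bases),
        pct_G=pct("G", bases),
        pct_C=pct("C", bases),
        pct_A3=pct("A", pos[2]),
        pct_T3=pct("T", pos[2]),
        pct_G3=pct("G", pos[2]),
        pct_C3=pct("C", pos[2]),
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=(gc1 + gc2) / 2.0,
        gc_overall=gc_overall,
        au_overall=100.0 - gc_overall,
    )


def profiles_frame(profiles: Iterable[CompositionProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame, one row per sequence."""
    rows = [{f.name: getattr(p, f.name) for f in fields(CompositionProfile)} for p in profiles]
    if not rows:
        raise ValueError("no profiles")
    return pd.DataFrame(rows).set_index("id")


def summarize_profiles(profiles: Sequence[CompositionProfile]) -> pd.DataFrame:
    """Mean, sample SD (n−1), min, max per composition field.

    A single profile yields mean=min=max with SD flagged as NaN.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    df = profiles_frame(profiles)[_NUMERIC_FIELDS]
    out = pd.DataFrame(
        {
            "mean": df.mean(),
            "sd": df.std(ddof=1) if len(df) > 1 else np.nan,
            "min": df.min(),
            "max": df.max(),
        }
    )
    out.index.name = "field"
    return out
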