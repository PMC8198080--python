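"""Relative synonymous codon usage: per-codon RSCU, classification, species
averages, shared preferred codons, and hierarchical clustering for heatmaps.

RSCU for codon j of amino acid i is x_ij · k_i / Σ_j x_ij, where k_i is the
family degeneracy: 1 means the codon is used exactly as often as expected
under uniform synonymous usage, and the values in a family always sum to k_i.
The universe is the 59 sense codons of the 18 degenerate families (Met, Trp
and stops excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import pdist

from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    RSCU_CODONS,
    SYN_FAMILIES,
    to_dna,
    to_rna,
)
from .sequence_io import CodonCountTable

log = logging.getLogger(__name__)

OVERREPRESENTED = "OVERREPRESENTED"
PREFERRED = "PREFERRED"
UNBIASED = "UNBIASED"
UNDERREPRESENTED = "UNDERREPRESENTED"
ABSENT = "ABSENT"

OVER_THRESHOLD = 1.6
UNDER_THRESHOLD = 0.6


@dataclass
class RSCUTable:
    """RSCU values for one species or dataset.

    ``values[codon]`` is None (flagged ABSENT) when the whole family is
    unobserved. ``family_counts`` carries the underlying family totals when
    the table came from counts (empty when built from published values).
    """

    label: str
    values: dict[str, float | None]
    family_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = {to_dna(c): v for c, v in self.values.items()}
        missing = set(RSCU_CODONS) - set(self.values)
        if missing:
            raise ValueError(f"RSCU table {self.label}: missing codons {sorted(missing)}")

    @property
    def flags(self) -> dict[str, str]:
        return {c: classify_value(v) for c, v in self.values.items()}

    def to_frame(self, rna: bool = True) -> pd.DataFrame:
        rows = []
        for c in RSCU_CODONS:
            rows.append(
                {
                    "amino_acid": CODON_TO_AA[c],
                    "codon": to_rna(c) if rna else c,
                    "rscu": self.values[c],
                    "flag": classify_value(self.values[c]),
                }
            )
        return pd.DataFrame(rows)


def rscu(counts: CodonCountTable) -> RSCUTable:
    """RSCU from a codon count table (stops never enter the computation)."""
    values: dict[str, float | None] = {}
    fam_counts: dict[str, int] = {}
    for aa in DEGENERATE_AAS:
        fam = SYN_FAMILIES[aa]
        total = sum(counts.counts[c] for c in fam)
        fam_counts[aa] = total
        for c in fam:
            values[c] = None if total == 0 else counts.counts[c] * len(fam) / total
    return RSCUTable(label="dataset", values=values, family_counts=fam_counts)


def classify_value(value: float | None) -> str:
    """Representation class of one RSCU value (strict inequalities;
    boundary values fall to the non-extreme class)."""
    if value is None:
        return ABSENT
    if value > OVER_THRESHOLD:
        return OVERREPRESENTED
    if value > 1.0:
        return PREFERRED
    if value < UNDER_THRESHOLD:
        return UNDERREPRESENTED
    return UNBIASED


def classify_rscu(table: RSCUTable) -> dict[str, str]:
    return table.flags


def average_rscu(tables: Sequence[RSCUTable], label: str = "average") -> RSCUTable:
    """Unweighted arithmetic mean per codon across species tables.

    ABSENT codons are excluded from their mean with a logged note. For a
    pooled (count-weighted) average, sum the CodonCountTables and call
    :func:`rscu` on the sum instead.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to average")
    values: dict[str, float | None] = {}
    for c in RSCU_CODONS:
        vals = [t.values[c] for t in tables if t.values[c] is not None]
        if not vals:
            values[c] = None
        else:
            if len(vals) < len(tables):
                log.info("codon %s absent in %d table(s); averaged over the rest",
                         c, len(tables) - len(vals))
            values[c] = float(np.mean(vals))
    return RSCUTable(label=label, values=values)


def shared_preferred(tables: Sequence[RSCUTable], inclusive: bool = False) -> set[str]:
    """Codons preferred (RSCU above 1) in every table.

    ``inclusive`` admits values equal to 1 as well — needed when the inputs
    are published tables rounded to two decimals, where a true value just
    above 1 can print as 1.00.
    """
    if not tables:
        raise ValueError("no tables")
    shared: set[str] = set()
    for c in RSCU_CODONS:
        vals = [t.values[c] for t in tables]
        if any(v is None for v in vals):
            continue
        if all(v >= 1.0 if inclusive else v > 1.0 for v in vals):
            shared.add(c)
    return shared


@dataclass(frozen=True)
class ClusterResult:
    row_order: tuple[str, ...]  # codons, leaf order
    col_order: tuple[str, ...]  # species labels, leaf order
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    matrix: pd.DataFrame  # codons x species RSCU matrix fed to clustering


def rscu_matrix(tables: Sequence[RSCUTable]) -> pd.DataFrame:
    """Codon-by-species RSCU matrix; ABSENT values become 0 for clustering."""
    data = {
        t.label: [t.values[c] if t.values[c] is not None else 0.0 for c in RSCU_CODONS]
        for t in tables
    }
    return pd.DataFrame(data, index=list(RSCU_CODONS))


def rscu_cluster(tables: Sequence[RSCUTable]) -> ClusterResult:
    """Average-linkage Euclidean clustering of codon rows and species columns.

    Deterministic given input order; scipy's linkage breaks distance ties by
    the lowest cluster index.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables to cluster")
    m = rscu_matrix(tables)
    row_link = linkage(pdist(m.values, metric="euclidean"), method="average")
    col_link = linkage(pdist(m.values.T, metric="euclidean"), method="average")
    row_leaves = dendrogram(row_link, no_plot=True)["leaves"]
    col_leaves = dendrogram(col_link, no_plot=True)["leaves"]
    return ClusterResult(
        row_order=tuple(m.index[i] for i in row_leaves),
        col_order=tuple(m.columns[i] for i in col_leaves),
        row_linkage=row_link,
        col_linkage=col_link,
        matrix=m,
    )


def tables_to_frame(
    tables: Sequence[RSCUTable], average: RSCUTable | None = None, rna: bool = True
) -> pd.DataFrame:
    """Species columns side by side (plus optional average), Table-style."""
    out = pd.DataFrame(
        {
            "amino_acid": [CODON_TO_AA[c] for c in RSCU_CODONS],
            "codon": [to_rna(c) if rna else c for c in RSCU_CODONS],
        }
    )
    for t in tables:
        out[t.label] = [t.values[c] for c in RSCU_CODONS]
    if average is not None:
        out[average.label] = [average.values[c] for c in RSCU_CODONS]
    return out
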