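"""Bundled published reference tables for the EPB41L3 codon-usage study.

The package ships the printed per-species RSCU table, the pooled observed
dinucleotide frequencies (with the published odds ratios for comparison),
and the five species' tRNA isoacceptor gene-count panels as plain TSV.
These are analysis inputs: downstream quantities (odds ratios, P2, shared
preferred codons, adaptation reports) are always recomputed from them.
"""

from __future__ import annotations

from importlib import resources as _ilr
from pathlib import Path

import pandas as pd

from .rscu import RSCUTable
from .sequence_io import TRNAGeneTable, read_trna_counts

SPECIES = (
    "homo_sapiens",
    "rattus_norvegicus",
    "bos_taurus",
    "mus_musculus",
    "pongo_abelii",
)


def _data_path(name: str) -> Path:
    return Path(str(_ilr.files("cubkit").joinpath("data", name)))


def load_published_rscu() -> dict[str, RSCUTable]:
    """Per-species RSCU tables (plus the published cross-species average)
    for the EPB41L3 coding sequences."""
    df = pd.read_csv(_data_path("epb41l3_rscu.tsv"), sep="\t")
    out: dict[str, RSCUTable] = {}
    for col in list(SPECIES) + ["average"]:
        out[col] = RSCUTable(
            label=col, values=dict(zip(df["codon"], df[col].astype(float)))
        )
    return out


def load_published_dinucleotides() -> pd.DataFrame:
    """Observed dinucleotide frequencies (and published odds ratios) of the
    pooled EPB41L3 transcripts, indexed by DNA dinucleotide."""
    return pd.read_csv(
        _data_path("epb41l3_dinucleotides.tsv"), sep="\t", index_col="dinucleotide"
    )


def load_trna_table(species: str, on_total_mismatch: str = "error") -> TRNAGeneTable:
    """One species' tRNA isoacceptor gene-count panel."""
    if species not in SPECIES:
        raise KeyError(f"unknown species {species!r}; choose from {SPECIES}")
    return read_trna_counts(
        _data_path(f"trna_{species}.tsv"),
        species=species,
        on_total_mismatch=on_total_mismatch,
    )


def load_trna_preferred_codons(species: str) -> dict[str, list[str]]:
    """The preferred-codon column of a tRNA panel (slash-separated ties)."""
    df = pd.read_csv(_data_path(f"trna_{species}.tsv"), sep="\t")
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        aa = str(row["amino_acid"]).split()[0]
        out[aa] = str(row["preferred_codon"]).split("/")
    return out
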