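"""Reading and validating coding sequences; parsers for reference codon-usage
tables (Kazusa ``countcodon`` text layout) and tRNA gene-count tables.

Validation mirrors the usual curation rules for complete CDSs: a start codon,
a terminal stop, no internal stop, no ambiguous base, length a multiple of 3.
Validation is advisory — records that fail are reported and can be excluded —
with a strict mode that aborts instead.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .genetic_code import (
    BASES,
    CODONS,
    CODON_TO_AA,
    START_CODON,
    STOP_CODONS,
    SYN_FAMILIES,
    to_dna,
)

log = logging.getLogger(__name__)

# validation failure reason codes
NO_START = "NO_START"
NO_TERMINAL_STOP = "NO_TERMINAL_STOP"
INTERNAL_STOP = "INTERNAL_STOP"
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
BAD_LENGTH = "BAD_LENGTH"


@dataclass(frozen=True)
class CodingSequence:
    """One coding sequence with its species label.

    ``bases`` is uppercase DNA (U already normalized to T).
    """

    id: str
    species: str
    bases: str

    @property
    def codon_count(self) -> int:
        return len(self.bases) // 3

    def codons(self) -> list[str]:
        """The sequence split into consecutive codons (requires length % 3 == 0)."""
        if len(self.bases) % 3:
            raise ValueError(f"{self.id}: length {len(self.bases)} not a multiple of 3")
        return [self.bases[i : i + 3] for i in range(0, len(self.bases), 3)]


@dataclass(frozen=True)
class ValidationReport:
    id: str
    passed: bool
    failures: tuple[str, ...]


@dataclass
class CodonCountTable:
    """Counts of the 64 codons pooled over a set of sequences.

    ``counts[j]`` is x_ij, the count of codon j; ``family_totals[aa]`` is the
    family total n for amino acid aa (sense codons only).
    """

    counts: dict[str, int]
    include_stops: bool = False

    def __post_init__(self) -> None:
        full = {c: 0 for c in CODONS}
        full.update({to_dna(c): int(n) for c, n in self.counts.items()})
        self.counts = full

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def family_totals(self) -> dict[str, int]:
        return {
            aa: sum(self.counts[c] for c in fam) for aa, fam in SYN_FAMILIES.items()
        }

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if self.include_stops != other.include_stops:
            raise ValueError("cannot add tables with different include_stops flags")
        merged = {c: self.counts[c] + other.counts[c] for c in CODONS}
        return CodonCountTable(merged, include_stops=self.include_stops)


@dataclass(frozen=True)
class ReferenceUsageTable:
    """Species codon-usage reference: per-thousand frequency and raw count per codon."""

    species: str
    frequencies: Mapping[str, float]  # codon -> per-thousand frequency
    raw_counts: Mapping[str, float]  # codon -> count in the reference corpus

    def __post_init__(self) -> None:
        missing = set(CODONS) - set(self.frequencies)
        if missing:
            raise ValueError(f"MISSING_CODON: {sorted(missing)}")
        if any(v < 0 for v in self.frequencies.values()):
            raise ValueError("negative reference frequency")


@dataclass(frozen=True)
class TRNAGeneTable:
    """tRNA isoacceptor gene counts: amino acid (3-letter) -> anticodon -> count.

    Anticodons are DNA alphabet, written 5'→3' as in GtRNAdb. Rows whose
    source printed a split count "a/b" keep the pair in ``split_counts``;
    ``isotypes`` stores the summed value.
    """

    species: str
    isotypes: Mapping[str, Mapping[str, int]]
    split_counts: Mapping[str, Mapping[str, tuple[int, ...]]] = field(
        default_factory=dict
    )


def read_cds_fasta(path: str | Path, species_label: str = "unknown") -> list[CodingSequence]:
    """Read a multi-FASTA of coding sequences.

    U is normalized to T and case folded to upper; the FASTA header (id) is
    preserved. An empty file is an error, not an empty list.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return [
        CodingSequence(id=r.id, species=species_label, bases=to_dna(str(r.seq)))
        for r in records
    ]


def validate_cds(seq: CodingSequence) -> ValidationReport:
    """Check one CDS against the curation rules; reports, never raises."""
    failures: list[str] = []
    b = seq.bases
    if set(b) - set(BASES):
        failures.append(AMBIGUOUS_BASE)
    if len(b) % 3 or len(b) == 0:
        failures.append(BAD_LENGTH)
        return ValidationReport(seq.id, False, tuple(failures))
    codons = [b[i : i + 3] for i in range(0, len(b), 3)]
    if codons[0] != START_CODON:
        failures.append(NO_START)
    if codons[-1] not in STOP_CODONS:
        failures.append(NO_TERMINAL_STOP)
    if any(c in STOP_CODONS for c in codons[:-1]):
        failures.append(INTERNAL_STOP)
    return ValidationReport(seq.id, not failures, tuple(failures))


def filter_valid(
    seqs: Iterable[CodingSequence], strict: bool = False
) -> tuple[list[CodingSequence], list[ValidationReport]]:
    """Split sequences into the valid subset plus all reports.

    With ``strict`` any failing record raises instead of being excluded.
    """
    kept: list[CodingSequence] = []
    reports: list[ValidationReport] = []
    for s in seqs:
        rep = validate_cds(s)
        reports.append(rep)
        if rep.passed:
            kept.append(s)
        elif strict:
            raise ValueError(f"{s.id}: validation failed: {','.join(rep.failures)}")
        else:
            log.warning("excluding %s: %s", s.id, ",".join(rep.failures))
    return kept, reports


def write_validation_reports(reports: Iterable[ValidationReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tpassed\tfailures\n")
        for r in reports:
            fh.write(f"{r.id}\t{str(r.passed).lower()}\t{','.join(r.failures)}\n")


def count_codons(
    seqs: Iterable[CodingSequence], include_stops: bool = False
) -> CodonCountTable:
    """Pool codon counts across sequences.

    Stop codons are counted only when ``include_stops`` is set; codon-bias
    indices (RSCU, ENc, CAI) are defined over sense codons and expect False.
    """
    counts = {c: 0 for c in CODONS}
    for s in seqs:
        for c in s.codons():  # raises on non-multiple-of-3
            if c in STOP_CODONS and not include_stops:
                continue
            counts[c] += 1
    return CodonCountTable(counts, include_stops=include_stops)


_COUNTCODON_TOKEN = re.compile(
    r"([ACGTUacgtu]{3})\s+([0-9.]+)\s*\(\s*([0-9.]+)\s*\)"
)


def read_reference_usage(path: str | Path, species: str | None = None) -> ReferenceUsageTable:
    """Parse a Kazusa countcodon-style table: ``CODON freq-per-thousand (count)``.

    Accepts U or T alphabet; keys are stored in DNA. All 64 codons must be
    present exactly once.
    """
    path = Path(path)
    text = path.read_text()
    freqs: dict[str, float] = {}
    counts: dict[str, float] = {}
    for m in _COUNTCODON_TOKEN.finditer(text):
        codon = to_dna(m.group(1))
        if codon in freqs:
            raise ValueError(f"{path}: duplicate codon {codon}")
        freqs[codon] = float(m.group(2))
        counts[codon] = float(m.group(3))
    missing = set(CODONS) - set(freqs)
    if missing:
        raise ValueError(f"{path}: MISSING_CODON {sorted(missing)}")
    return ReferenceUsageTable(
        species=species or path.stem, frequencies=freqs, raw_counts=counts
    )


_ISOTYPE_ITEM = re.compile(r"([ACGTacgt]{3})\s*\(\s*(\d+(?:/\d+)*)\s*\)")
_AA_LABEL = re.compile(r"^([A-Za-z]{3})\b")


def read_trna_counts(
    path: str | Path,
    species: str | None = None,
    on_total_mismatch: str = "error",
) -> TRNAGeneTable:
    """Parse a delimited tRNA gene-count table.

    Expected row layout (tab-separated): an amino-acid label like ``Ala (A)``,
    optionally a preferred-codon column, an isotype list like
    ``AGC (22), GGC (0), CGC (4), TGC (8)``, and a total count. Split counts
    ``a/b`` (as printed for Met) are summed, the pair retained. The stated
    total must equal the sum of item counts; ``on_total_mismatch="keep"``
    downgrades that to a warning so a typo row in a published table can still
    be loaded for inspection.
    """
    if on_total_mismatch not in {"error", "keep"}:
        raise ValueError("on_total_mismatch must be 'error' or 'keep'")
    path = Path(path)
    isotypes: dict[str, dict[str, int]] = {}
    splits: dict[str, dict[str, tuple[int, ...]]] = {}
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line or line.lower().startswith(("amino", "#")):
            continue
        cells = [c.strip() for c in re.split(r"\t|\|", line) if c.strip()]
        m = _AA_LABEL.match(cells[0])
        if m is None:
            raise ValueError(f"{path}: unparseable amino-acid label in row: {raw!r}")
        aa = m.group(1).capitalize()
        items = _ISOTYPE_ITEM.findall(line)
        if not items:
            raise ValueError(f"{path}: row {aa} has no isotype entries")
        fam: dict[str, int] = {}
        for anticodon, countstr in items:
            parts = tuple(int(p) for p in countstr.split("/"))
            ac = anticodon.upper()
            fam[ac] = sum(parts)
            if len(parts) > 1:
                splits.setdefault(aa, {})[ac] = parts
        stated = int(cells[-1]) if cells[-1].isdigit() else None
        if stated is not None and stated != sum(fam.values()):
            msg = (
                f"{path}: row {aa}: stated total {stated} != item sum "
                f"{sum(fam.values())}"
            )
            if on_total_mismatch == "error":
                raise ValueError(msg)
            log.warning(msg)
        isotypes[aa] = fam
    if not isotypes:
        raise ValueError(f"{path}: no rows parsed")
    return TRNAGeneTable(
        species=species or path.stem, isotypes=isotypes, split_counts=splits
    )
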