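"""Synthetic CDS generators with known codon-usage structure.

These emulate the shape of a curated mammalian transcript set — valid CDSs
(ATG start, terminal stop, no internal stop, no ambiguous base), lengths in
the hundreds-to-~1100-codon range, grouped into a handful of species-like
families — with controllable per-family codon probabilities and
controllable coupling between GC12 and GC3. Stop codons carry zero sampling
weight inside bodies, so every generated sequence validates by
construction. A single integer seed drives one named random stream per
generator call; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .genetic_code import (
    CODONS,
    CODON_TO_AA,
    DEGENERATE_AAS,
    STOP_CODONS,
    SYN_FAMILIES,
)
from .sequence_io import CodingSequence, ReferenceUsageTable, TRNAGeneTable
from .genetic_code import AA_1TO3

STOPS = tuple(sorted(STOP_CODONS))
_SENSE = tuple(c for c in CODONS if c not in STOP_CODONS)


def _default_aa_probs() -> dict[str, float]:
    # uniform over the 18 degenerate families, Met/Trp at low weight so all
    # RSCU families are exercised without single-codon families dominating
    probs = {aa: 1.0 for aa in DEGENERATE_AAS}
    probs["M"] = probs["W"] = 0.2
    z = sum(probs.values())
    return {aa: p / z for aa, p in probs.items()}


def _uniform_family_probs() -> dict[str, np.ndarray]:
    return {
        aa: np.full(len(fam), 1.0 / len(fam)) for aa, fam in SYN_FAMILIES.items()
    }


@dataclass
class SyntheticSpec:
    """Recipe for one species-like CDS set."""

    n_sequences: int = 10
    codons_per_sequence: int = 900  # body length, excluding start/stop
    amino_acid_probs: dict[str, float] = field(default_factory=_default_aa_probs)
    family_codon_probs: dict[str, np.ndarray] = field(
        default_factory=_uniform_family_probs
    )
    seed: int = 0
    label: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_sequences <= 0 or self.codons_per_sequence <= 0:
            raise ValueError("sizes must be positive")
        if abs(sum(self.amino_acid_probs.values()) - 1.0) > 1e-9:
            raise ValueError("amino_acid_probs must sum to 1")
        for aa, vec in self.family_codon_probs.items():
            vec = np.asarray(vec, dtype=float)
            if len(vec) != len(SYN_FAMILIES[aa]) or abs(vec.sum() - 1.0) > 1e-9:
                raise ValueError(f"bad codon probability vector for {aa}")
            self.family_codon_probs[aa] = vec


@dataclass
class GradientSpec:
    """Recipe for a GC12~GC3 gradient set (neutrality-plot geometry).

    ``mutation_fraction`` m is the designed slope of expected GC12 on the
    latent GC3 target; ``noise_sd`` is Gaussian noise on the GC12 target in
    percent points.
    """

    mutation_fraction: float = 0.5
    gc3_range: tuple[float, float] = (0.3, 0.7)
    noise_sd: float = 1.5
    n_sequences: int = 200
    codons_per_sequence: int = 500
    gc12_baseline: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gc3_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("gc3_range must satisfy 0 <= low <= high <= 1")
        if not 0.0 <= self.mutation_fraction <= 1.0:
            raise ValueError("mutation_fraction must be in [0, 1]")


def _assemble(rng: np.random.Generator, body_codons: Sequence[str], label: str,
              index: int, species: str) -> CodingSequence:
    stop = STOPS[rng.integers(len(STOPS))]
    return CodingSequence(
        id=f"{label}_{index:03d}",
        species=species,
        bases="ATG" + "".join(body_codons) + stop,
    )


def generate_cds(spec: SyntheticSpec) -> list[CodingSequence]:
    """Sample CDSs codon by codon from the spec's probabilities."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    aas = sorted(spec.amino_acid_probs)
    aa_p = np.array([spec.amino_acid_probs[a] for a in aas])
    out = []
    for i in range(spec.n_sequences):
        chosen = rng.choice(len(aas), size=spec.codons_per_sequence, p=aa_p)
        body = []
        for ai in chosen:
            aa = aas[ai]
            fam = SYN_FAMILIES[aa]
            body.append(fam[rng.choice(len(fam), p=spec.family_codon_probs[aa])])
        out.append(_assemble(rng, body, spec.label, i, spec.label))
    return out


#: designated "preferred" codon per family for the bias gradient: the
#: GC3-ending codon first in alphabetical order (matches the G/C-ending
#: preference typical of mammalian genes)
PREFERRED_CODON: dict[str, str] = {
    aa: sorted(fam, key=lambda c: (c[2] not in "GC", c))[0]
    for aa, fam in SYN_FAMILIES.items()
}


def generate_biased_set(
    theta: float, n: int = 10, length: int = 400, seed: int = 0
) -> list[CodingSequence]:
    """CDS set whose codon bias strength is dialed by theta in [0, 1].

    Per-family codon probabilities interpolate linearly between uniform
    (theta=0) and one-hot on the designated preferred codon (theta=1), so
    ENc decreases monotonically from the 61 cap toward 20 as theta rises.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must be in [0, 1]")
    fam_probs = {}
    for aa, fam in SYN_FAMILIES.items():
        uniform = np.full(len(fam), 1.0 / len(fam))
        onehot = np.array([1.0 if c == PREFERRED_CODON[aa] else 0.0 for c in fam])
        fam_probs[aa] = (1.0 - theta) * uniform + theta * onehot
    spec = SyntheticSpec(
        n_sequences=n,
        codons_per_sequence=length,
        family_codon_probs=fam_probs,
        seed=seed,
        label=f"biased{theta:g}",
    )
    return generate_cds(spec)


def _gc12_weight(codon: str) -> float:
    return (codon[0] in "GC") * 0.5 + (codon[1] in "GC") * 0.5


def _codon_weights(t3: float, eta: float, aa_probs: dict[str, float]) -> np.ndarray:
    """Sampling weights over sense codons: amino-acid probability, split
    within each family so that GC-ending codons get total mass t3, tilted by
    exp(eta * gc12)."""
    w = np.zeros(len(_SENSE))
    for idx, c in enumerate(_SENSE):
        aa = CODON_TO_AA[c]
        fam = SYN_FAMILIES[aa]
        gc_end = [x for x in fam if x[2] in "GC"]
        at_end = [x for x in fam if x[2] not in "GC"]
        if not gc_end or not at_end:
            third = 1.0 / len(fam)  # Met/Trp: no third-position choice
        elif c[2] in "GC":
            third = t3 / len(gc_end)
        else:
            third = (1.0 - t3) / len(at_end)
        w[idx] = aa_probs[aa] * third * np.exp(eta * _gc12_weight(c))
    return w


def _solve_eta(t3: float, target12: float, aa_probs: dict[str, float]) -> float:
    g12 = np.array([_gc12_weight(c) for c in _SENSE])

    def mean_gc12(eta: float) -> float:
        w = _codon_weights(t3, eta, aa_probs)
        return float(w @ g12 / w.sum()) - target12

    lo, hi = -30.0, 30.0
    if mean_gc12(lo) > 0 or mean_gc12(hi) < 0:
        raise ValueError(f"GC12 target {target12} infeasible")
    return float(brentq(mean_gc12, lo, hi, xtol=1e-10))


def generate_neutrality_set(g: GradientSpec) -> list[CodingSequence]:
    """CDS set with a designed GC12-on-GC3 slope.

    For sequence i a latent GC3 target t_i is drawn uniformly in
    ``gc3_range``; third-position G/C propensity is set to t_i, and the
    positions-1/2 G/C propensity to baseline + m·(t_i − midpoint) + noise,
    realized by tilting codon sampling weights independently at positions
    1–2 (exponential tilt, solved per sequence) and position 3. OLS of the
    realized GC12 on realized GC3 then recovers m up to sampling noise.
    """
    lo, hi = g.gc3_range
    if lo == hi:
        import warnings

        warnings.warn("gc3_range is degenerate; downstream regressions will fail")
    rng = np.random.default_rng(np.random.SeedSequence(g.seed).spawn(1)[0])
    mid = (lo + hi) / 2.0
    aa_probs = _default_aa_probs()
    out = []
    for i in range(g.n_sequences):
        t3 = rng.uniform(lo, hi) if hi > lo else lo
        target12 = (
            g.gc12_baseline
            + g.mutation_fraction * (t3 - mid)
            + rng.normal(0.0, g.noise_sd / 100.0)
        )
        target12 = float(np.clip(target12, 0.05, 0.95))
        t3_eff = float(np.clip(t3, 0.02, 0.98))
        eta = _solve_eta(t3_eff, target12, aa_probs)
        w = _codon_weights(t3_eff, eta, aa_probs)
        w /= w.sum()
        idxs = rng.choice(len(_SENSE), size=g.codons_per_sequence, p=w)
        body = [_SENSE[k] for k in idxs]
        out.append(_assemble(rng, body, "grad", i, "gradient"))
    return out


def generate_reference_table(seed: int = 0, species: str = "synthetic") -> ReferenceUsageTable:
    """Random but realistic reference usage: positive counts for all 64
    codons drawn from a dispersed gamma, converted to per-thousand."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    counts = {c: float(np.round(rng.gamma(shape=2.0, scale=400.0) + 1.0)) for c in CODONS}
    total = sum(counts.values())
    freqs = {c: v / total * 1000.0 for c, v in counts.items()}
    return ReferenceUsageTable(species=species, frequencies=freqs, raw_counts=counts)


def generate_trna_table(seed: int = 0, species: str = "synthetic") -> TRNAGeneTable:
    """Random tRNA gene-count table: every codon's cognate anticodon slot is
    present with a small non-negative count."""
    from .trna_adaptation import anticodon_for

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    isotypes: dict[str, dict[str, int]] = {}
    for aa, fam in sorted(SYN_FAMILIES.items()):
        isotypes[AA_1TO3[aa]] = {
            anticodon_for(c): int(rng.integers(0, 25)) for c in fam
        }
    return TRNAGeneTable(species=species, isotypes=isotypes)


def write_fasta(seqs: Sequence[CodingSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), 70):
                fh.write(s.bases[i : i + 70] + "\n")


def write_reference_usage(table: ReferenceUsageTable, path: str | Path) -> None:
    """Emit Kazusa countcodon-style text (4 codons per line)."""
    items = [
        f"{c} {table.frequencies[c]:5.1f} ({int(table.raw_counts[c]):6d})"
        for c in CODONS
    ]
    with open(path, "w") as fh:
        for i in range(0, len(items), 4):
            fh.write("  ".join(items[i : i + 4]) + "\n")


def write_trna_counts(table: TRNAGeneTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("amino_acid\tisotypes\ttotal\n")
        for aa, fam in table.isotypes.items():
            items = ", ".join(f"{ac} ({n})" for ac, n in sorted(fam.items()))
            fh.write(f"{aa}\t{items}\t{sum(fam.values())}\n")


def mutate_codons(
    seq: CodingSequence,
    rng: np.random.Generator,
    rate_synonymous: float = 0.0,
    rate_any: float = 0.0,
) -> CodingSequence:
    """Codon-level substitution that preserves CDS validity.

    With probability ``rate_synonymous`` a body codon is swapped within its
    synonymous family (third-position drift); with ``rate_any`` it is
    replaced by a random sense codon (amino-acid change). Start and stop
    codons are never touched.
    """
    codons = seq.codons()
    body = codons[1:-1]
    out = []
    for c in body:
        u = rng.random()
        if u < rate_any:
            out.append(_SENSE[rng.integers(len(_SENSE))])
        elif u < rate_any + rate_synonymous and c in CODON_TO_AA:
            fam = SYN_FAMILIES[CODON_TO_AA[c]]
            out.append(fam[rng.integers(len(fam))])
        else:
            out.append(c)
    return CodingSequence(seq.id, seq.species,
                          codons[0] + "".join(out) + codons[-1])


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Materialize a full synthetic test corpus: five species-like FASTA
    files (ortholog-like, derived from a shared ancestor so pairwise
    divergences stay in the K2P-correctable range), a reference usage table
    and a tRNA table per species."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    rng = np.random.default_rng(seed)
    gene_ancestor = generate_biased_set(theta=0.3, n=1, length=600, seed=seed)[0]
    for i, species in enumerate(["alpha", "beta", "gamma", "delta", "epsilon"]):
        divergence = 0.02 + 0.03 * i  # codon replacement rate from the ancestor
        sp_ancestor = mutate_codons(
            gene_ancestor, rng, rate_synonymous=0.05, rate_any=divergence
        )
        n_seqs = 7 if i == 0 else 4
        seqs = [
            mutate_codons(
                CodingSequence(f"{species}_{j:03d}", species, sp_ancestor.bases),
                rng,
                rate_synonymous=0.02,
                rate_any=0.01,
            )
            for j in range(n_seqs)
        ]
        fasta = outdir / f"{species}.fasta"
        write_fasta(seqs, fasta)
        manifest[f"fasta:{species}"] = fasta
        ref = generate_reference_table(seed=seed * 1000 + i, species=species)
        ref_path = outdir / f"{species}_reference.txt"
        write_reference_usage(ref, ref_path)
        manifest[f"reference:{species}"] = ref_path
        trna = generate_trna_table(seed=seed * 1000 + i, species=species)
        trna_path = outdir / f"{species}_trna.tsv"
        write_trna_counts(trna, trna_path)
        manifest[f"trna:{species}"] = trna_path
    return manifest
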