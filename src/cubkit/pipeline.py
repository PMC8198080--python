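"""End-to-end orchestration: run every analysis stage over a multi-species
CDS set and emit the full table suite plus a machine-readable summary.

Stages run in dependency order; a stage whose inputs are missing (no tRNA
table, no alignment) is skipped with a logged notice rather than failing
the run. Output is deterministic given the same inputs and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import composition, cub_indices, dinucleotides, forces, phylogeny, rscu
from .sequence_io import (
    count_codons,
    filter_valid,
    read_cds_fasta,
    read_reference_usage,
    read_trna_counts,
    write_validation_reports,
)
from .trna_adaptation import adaptation_report, report_frame

log = logging.getLogger(__name__)


@dataclass
class SpeciesInput:
    label: str
    fasta: str
    reference: str | None = None  # Kazusa countcodon table for CAI
    trna: str | None = None  # tRNA gene-count TSV


@dataclass
class AnalysisConfig:
    species: list[SpeciesInput]
    output_dir: str
    include_stops_in_composition: bool = True
    expected_mode: str = dinucleotides.UNIFORM
    p2_mode: str = cub_indices.RSCU_CLASS_MEAN
    strict_validation: bool = False
    alignment: str | None = None  # pre-aligned multi-FASTA for the tree
    trim_to_common: bool = False  # fallback when no alignment is given
    rounding: int = 4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        species = [SpeciesInput(**s) for s in raw.pop("species")]
        return cls(species=species, **raw)


@dataclass
class AnalysisBundle:
    manifest: dict[str, Path] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _emit(bundle: AnalysisBundle, outdir: Path, name: str, df: pd.DataFrame,
          rounding: int) -> None:
    path = outdir / name
    df.round(rounding).to_csv(path, sep="\t")
    bundle.manifest[name] = path


def run_pipeline(config: AnalysisConfig) -> AnalysisBundle:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = AnalysisBundle()
    t0 = time.time()

    # ingest + validate
    per_species = {}
    reports = []
    for sp in config.species:
        seqs = read_cds_fasta(sp.fasta, species_label=sp.label)
        kept, reps = filter_valid(seqs, strict=config.strict_validation)
        reports.extend(reps)
        if not kept:
            raise ValueError(f"{sp.label}: no valid sequences")
        per_species[sp.label] = kept
    all_seqs = [s for seqs in per_species.values() for s in seqs]
    write_validation_reports(reports, outdir / "validation.tsv")
    bundle.manifest["validation.tsv"] = outdir / "validation.tsv"

    # composition
    profiles = [
        composition.composition_profile(s, include_stop=config.include_stops_in_composition)
        for s in all_seqs
    ]
    _emit(bundle, outdir, "composition.tsv", composition.profiles_frame(profiles),
          config.rounding)
    _emit(bundle, outdir, "composition_summary.tsv",
          composition.summarize_profiles(profiles), config.rounding)

    # dinucleotides
    dinuc = dinucleotides.dinucleotide_profile(all_seqs, expected_mode=config.expected_mode)
    _emit(bundle, outdir, "dinucleotides.tsv", dinuc.to_frame(), config.rounding)

    # RSCU per species + average
    tables = []
    for label, seqs in per_species.items():
        t = rscu.rscu(count_codons(seqs, include_stops=False))
        t.label = label
        tables.append(t)
    avg = rscu.average_rscu(tables) if len(tables) >= 2 else None
    rscu_frame = rscu.tables_to_frame(tables, average=avg)
    _emit(bundle, outdir, "rscu.tsv", rscu_frame.set_index("codon"), config.rounding)
    shared = sorted(rscu.shared_preferred(tables)) if len(tables) >= 2 else []

    # per-sequence indices
    references = {
        sp.label: read_reference_usage(sp.reference, species=sp.label)
        for sp in config.species
        if sp.reference
    }
    rows = []
    for s in all_seqs:
        counts = count_codons([s], include_stops=False)
        prof = next(p for p in profiles if p.id == s.id)
        row = {"id": s.id, "species": s.species, "gc3": prof.gc3,
               "enc": cub_indices.enc(counts).enc}
        if s.species in references:
            row["cai"] = cub_indices.cai(counts, references[s.species]).cai
        rows.append(row)
    indices = pd.DataFrame(rows).set_index("id")
    _emit(bundle, outdir, "indices.tsv", indices, config.rounding)
    if not references:
        bundle.skipped.append("cai: SKIPPED (no reference usage tables)")
        log.info("cai: SKIPPED (no reference usage tables)")

    # P2 per species
    p2_rows = []
    for t in tables:
        if config.p2_mode == cub_indices.RSCU_CLASS_MEAN:
            res = cub_indices.p2(t, mode=config.p2_mode)
        else:
            res = cub_indices.p2(
                count_codons(per_species[t.label], include_stops=False),
                mode=config.p2_mode,
            )
        p2_rows.append({"species": t.label, "SSU": res.sSU, "WWU": res.wWU,
                        "SSC": res.sSC, "WWC": res.wWC, "P2": res.p2})
    p2_df = pd.DataFrame(p2_rows).set_index("species")
    _emit(bundle, outdir, "p2.tsv", p2_df, config.rounding)

    # forces
    neut = forces.neutrality([(p.gc12, p.gc3) for p in profiles])
    neut_df = pd.DataFrame(
        [{"slope": neut.slope, "intercept": neut.intercept, "r": neut.pearson_r,
          "p": neut.p_value, "n": neut.n, "mutation_pct": neut.mutation_pct,
          "selection_pct": neut.selection_pct}]
    ).set_index("n")
    _emit(bundle, outdir, "neutrality.tsv", neut_df, config.rounding)

    pts, overall = forces.pr2(profiles)
    pr2_df = pd.DataFrame(
        [{"id": p.label, "gc_bias": p.gc_bias, "at_bias": p.at_bias}
         for p in pts + [overall]]
    ).set_index("id")
    _emit(bundle, outdir, "pr2.tsv", pr2_df, config.rounding)

    egc, frac_below = forces.enc_gc3_points(
        indices["enc"].tolist(), (indices["gc3"] / 100.0).tolist(),
        labels=indices.index.tolist(),
    )
    egc_df = pd.DataFrame(
        [{"id": p.label, "gc3": p.gc3, "enc_observed": p.enc_observed,
          "enc_expected": p.enc_expected, "deviation": p.deviation} for p in egc]
    ).set_index("id")
    _emit(bundle, outdir, "enc_gc3.tsv", egc_df, config.rounding)

    feat_cols = ["pct_A", "pct_T", "pct_G", "pct_C", "pct_A3", "pct_T3",
                 "pct_G3", "pct_C3", "gc3"]
    feats = composition.profiles_frame(profiles)[feat_cols].copy()
    feats["enc"] = indices["enc"]
    if "cai" in indices.columns:
        feats["cai"] = indices["cai"]
    r_df, p_df, s_df = forces.correlation_table(feats)
    _emit(bundle, outdir, "correlations_r.tsv", r_df, config.rounding)
    _emit(bundle, outdir, "correlations_stars.tsv", s_df, config.rounding)
    _emit(bundle, outdir, "regressions.tsv", forces.enc_regressions(feats),
          config.rounding)

    # tRNA adaptation
    any_trna = False
    for sp in config.species:
        if not sp.trna:
            continue
        any_trna = True
        trna = read_trna_counts(sp.trna, species=sp.label)
        table = next(t for t in tables if t.label == sp.label)
        recs = adaptation_report(table, trna)
        _emit(bundle, outdir, f"adaptation_{sp.label}.tsv", report_frame(recs),
              config.rounding)
    if not any_trna:
        bundle.skipped.append("trna_adaptation: SKIPPED (no tRNA tables)")
        log.info("trna_adaptation: SKIPPED (no tRNA tables)")

    # phylogeny
    tree_input = None
    if config.alignment:
        tree_input = read_cds_fasta(config.alignment, species_label="aligned")
    elif config.trim_to_common and len(all_seqs) >= 3:
        tree_input = phylogeny.trim_to_common_length(all_seqs)
    if tree_input and len(tree_input) >= 3:
        dm = phylogeny.k2p_matrix(tree_input)
        (outdir / "distances.tsv").write_text(dm.as_tsv())
        bundle.manifest["distances.tsv"] = outdir / "distances.tsv"
        tree = phylogeny.neighbor_joining(dm)
        (outdir / "tree.nwk").write_text(phylogeny.write_newick(tree) + "\n")
        bundle.manifest["tree.nwk"] = outdir / "tree.nwk"
    else:
        bundle.skipped.append("phylogeny: SKIPPED (no alignment provided)")
        log.info("phylogeny: SKIPPED (no alignment provided)")

    bundle.summary = {
        "n_sequences": len(all_seqs),
        "n_species": len(per_species),
        "total_codons": int(count_codons(all_seqs, include_stops=True).total_codons),
        "mean_gc": float(composition.profiles_frame(profiles)["gc_overall"].mean()),
        "mean_gc3": float(composition.profiles_frame(profiles)["gc3"].mean()),
        "mean_enc": float(indices["enc"].mean()),
        "neutrality_slope": neut.slope,
        "neutrality_r": neut.pearson_r,
        "mutation_pct": neut.mutation_pct,
        "selection_pct": neut.selection_pct,
        "pr2_overall": {"gc_bias": overall.gc_bias, "at_bias": overall.at_bias},
        "fraction_below_expected_enc": frac_below,
        "shared_preferred_codons": shared,
        "p2": {row["species"]: row["P2"] for row in p2_rows},
        "skipped": bundle.skipped,
    }
    if "cai" in indices.columns:
        bundle.summary["mean_cai"] = float(indices["cai"].mean())
    with open(outdir / "summary.json", "w") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
    bundle.manifest["summary.json"] = outdir / "summary.json"
    log.info("pipeline finished in %.1fs; %d artifacts", time.time() - t0,
             len(bundle.manifest))
    return bundle
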