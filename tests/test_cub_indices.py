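"""Wright's ENc, the expected ENc-GC3 curve, CAI, and the P2 index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit import cub_indices as ci
from cubkit.genetic_code import DEGENERATE_AAS, RSCU_CODONS, SYN_FAMILIES
from cubkit.rscu import RSCUTable, rscu
from cubkit.sequence_io import CodonCountTable, ReferenceUsageTable, count_codons
from cubkit.synthetic_data import generate_biased_set, generate_reference_table


def _uniform_counts(per_codon: int = 100) -> CodonCountTable:
    counts = {c: per_codon for aa in DEGENERATE_AAS for c in SYN_FAMILIES[aa]}
    return CodonCountTable(counts)


def _one_per_family_counts(n: int = 10) -> CodonCountTable:
    counts = {SYN_FAMILIES[aa][0]: n for aa in DEGENERATE_AAS}
    return CodonCountTable(counts)


class TestEnc:
    def test_absolute_bias_scores_twenty(self):
        assert ci.enc(_one_per_family_counts()).enc == pytest.approx(20.0)

    def test_uniform_usage_clamps_to_sixty_one(self):
        res = ci.enc(_uniform_counts())
        assert res.enc == 61.0
        assert res.raw_enc > 61.0

    def test_homozygosity_hand_case(self):
        # two-fold family with counts (3,1): F = (4*(9/16+1/16) - 1)/3 = 0.5
        f = ci.family_homozygosity({"TTT": 3, "TTC": 1}, ("TTT", "TTC"))
        assert f == pytest.approx(0.5)

    def test_small_families_excluded(self):
        counts = _one_per_family_counts()
        counts.counts["ATT"] = 0
        counts.counts["ATC"] = 0
        counts.counts["ATA"] = 1  # Ile n=1: excluded, class 3 imputed
        res = ci.enc(counts)
        assert 3 in res.missing_classes
        assert res.class_means[3] == pytest.approx(
            (res.class_means[2] + res.class_means[4]) / 2
        )

    def test_empty_class_errors(self):
        counts = CodonCountTable({"TTT": 5, "TTC": 5})  # only one 2-fold family
        with pytest.raises(ci.EncUndefinedError):
            ci.enc(counts)

    def test_scale_invariance_of_proportions(self):
        base = count_codons(generate_biased_set(0.4, n=3, length=400, seed=3))
        doubled = CodonCountTable({c: 2 * n for c, n in base.counts.items()})
        # p_j unchanged; F-hat moves toward sum p^2, so ENc shifts but stays in range
        for res in (ci.enc(base), ci.enc(doubled)):
            assert 20.0 <= res.enc <= 61.0
            assert all(0 < f <= 1 for f in res.per_family_F.values())

    def test_monotone_in_bias_strength(self):
        encs = [
            ci.enc(count_codons(generate_biased_set(t, n=5, length=800, seed=2))).enc
            for t in (0.0, 0.5, 1.0)
        ]
        assert encs[0] > encs[1] > encs[2]
        assert encs[2] == pytest.approx(20.0)


class TestEncExpected:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_spot_values(self, s, expected):
        assert ci.enc_expected(s) == pytest.approx(expected)

    @given(st.floats(min_value=0, max_value=1))
    @settings(max_examples=80, deadline=None)
    def test_symmetry_up_to_linear_term(self, s):
        assert ci.enc_expected(s) - s == pytest.approx(
            ci.enc_expected(1 - s) - (1 - s), rel=1e-12
        )

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            ci.enc_expected(1.2)


def _reference_with(freqs: dict[str, float]) -> ReferenceUsageTable:
    base = generate_reference_table(seed=9)
    f = dict(base.frequencies)
    c = dict(base.raw_counts)
    f.update(freqs)
    for k, v in freqs.items():
        c[k] = v * 10
    return ReferenceUsageTable(species="custom", frequencies=f, raw_counts=c)


class TestCai:
    def test_all_optimal_query_scores_one(self):
        ref = generate_reference_table(seed=1)
        counts = {
            max(SYN_FAMILIES[aa], key=lambda c: ref.frequencies[c]): 5
            for aa in DEGENERATE_AAS
        }
        assert ci.cai(CodonCountTable(counts), ref).cai == pytest.approx(1.0)

    def test_single_codon_ratio(self):
        ref = _reference_with({"TTT": 30.0, "TTC": 10.0})
        res = ci.cai(CodonCountTable({"TTC": 1}), ref)
        assert res.cai == pytest.approx(10 / 30)

    def test_zero_reference_frequency_uses_pseudocount(self):
        ref = _reference_with({"TTT": 30.0, "TTC": 0.0})
        res = ci.cai(CodonCountTable({"TTC": 1}), ref)
        assert 0 < res.cai < 0.1  # finite, small

    def test_reference_monotonicity(self):
        """A query scores at least as high against its own usage as against a
        reference that demotes its modal codons."""
        seqs = generate_biased_set(0.8, n=3, length=500, seed=4)
        counts = count_codons(seqs)
        total = counts.total_codons
        own_freqs = {c: n / total * 1000 for c, n in counts.counts.items()}
        own = ReferenceUsageTable(
            "own",
            {c: max(f, 1e-9) for c, f in own_freqs.items()},
            {c: max(n, 1) for c, n in counts.counts.items()},
        )
        # demote: invert each family's preference
        inv_freqs = {}
        for aa, fam in SYN_FAMILIES.items():
            fmax = max(own.frequencies[c] for c in fam)
            for c in fam:
                inv_freqs[c] = fmax - own.frequencies[c] + 1.0
        for c in set(own.frequencies) - set(inv_freqs):
            inv_freqs[c] = own.frequencies[c]
        demoted = ReferenceUsageTable("demoted", inv_freqs,
                                      {c: 10 for c in inv_freqs})
        assert ci.cai(counts, own).cai >= ci.cai(counts, demoted).cai

    def test_geometric_mean_weighting(self):
        ref = _reference_with({"TTT": 30.0, "TTC": 10.0})
        res = ci.cai(CodonCountTable({"TTT": 1, "TTC": 1}), ref)
        assert res.cai == pytest.approx(math.sqrt(1.0 * (10 / 30)))


class TestP2:
    EXPECTED = {  # published per-species class means and P2, 2 decimals
        "homo_sapiens": (0.71, 1.00, 1.07, 1.09, 0.93),
        "rattus_norvegicus": (0.69, 0.76, 1.23, 1.37, 1.02),
        "bos_taurus": (0.66, 0.82, 1.32, 1.32, 0.96),
        "mus_musculus": (0.69, 0.84, 1.15, 1.27, 0.99),
        "pongo_abelii": (0.69, 0.94, 1.06, 1.12, 0.95),
    }

    def test_chain_reproduces_published_table(self, published_rscu):
        for species, (ssu, wwu, ssc, wwc, p2_val) in self.EXPECTED.items():
            res = ci.p2(published_rscu[species])
            # 2-decimal agreement: absolute half-unit-in-last-place bound
            assert res.sSU == pytest.approx(ssu, abs=0.00501), species
            assert res.wWU == pytest.approx(wwu, abs=0.00501), species
            assert res.sSC == pytest.approx(ssc, abs=0.00501), species
            assert res.wWC == pytest.approx(wwc, abs=0.00501), species
            assert res.p2 == pytest.approx(p2_val, abs=0.00501), species

    def test_mean_of_species_matches_overall(self, published_rscu):
        vals = [ci.p2(published_rscu[s]).p2 for s in self.EXPECTED]
        assert round(float(np.mean(vals)), 2) == 0.97

    def test_uniform_rscu_gives_one(self):
        table = RSCUTable(label="flat", values={c: 1.0 for c in RSCU_CODONS})
        assert ci.p2(table).p2 == pytest.approx(1.0)

    def test_count_mode_on_balanced_counts(self):
        counts = CodonCountTable({c: 10 for c in
                                  ci.WWC_CODONS + ci.WWU_CODONS + ci.SSC_CODONS + ci.SSU_CODONS})
        res = ci.p2(counts, mode=ci.COUNT_CLASSIC)
        assert res.p2 == pytest.approx(0.5)
        assert not res.translational_selection

    def test_mode_type_mismatch(self, published_rscu):
        with pytest.raises(TypeError):
            ci.p2(published_rscu["homo_sapiens"], mode=ci.COUNT_CLASSIC)
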