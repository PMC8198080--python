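"""K2P distances, neighbor joining, Newick output."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from cubkit.phylogeny import (
    DistanceMatrix,
    NoSitesError,
    SaturationError,
    k2p,
    k2p_matrix,
    neighbor_joining,
    tree_distance_matrix,
    trim_to_common_length,
    write_newick,
)
from cubkit.sequence_io import CodingSequence


def _mutate(seq: str, n_transitions: int, n_transversions: int) -> str:
    transition = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversion = {"A": "C", "G": "T", "C": "G", "T": "A"}
    out = list(seq)
    for i in range(n_transitions):
        out[i] = transition[out[i]]
    for i in range(n_transitions, n_transitions + n_transversions):
        out[i] = transversion[out[i]]
    return "".join(out)


class TestK2P:
    def test_identical_sequences(self):
        r = k2p("ACGTACGT", "ACGTACGT")
        assert r.d == 0 and r.P == 0 and r.Q == 0

    def test_hand_computed_case(self):
        seq = "ACGT" * 25
        other = _mutate(seq, 10, 5)
        r = k2p(seq, other)
        assert r.P == pytest.approx(0.10)
        assert r.Q == pytest.approx(0.05)
        expected = -0.5 * math.log(1 - 2 * 0.10 - 0.05) - 0.25 * math.log(1 - 2 * 0.05)
        assert r.d == pytest.approx(expected)
        assert r.d == pytest.approx(0.17018, abs=1e-5)

    def test_pairwise_deletion(self):
        r = k2p("ACG-ACGT", "ACGTAC-T")
        assert r.sites_used == 6

    def test_all_gap_pair_errors(self):
        with pytest.raises(NoSitesError):
            k2p("----", "ACGT")

    def test_saturation_errors(self):
        with pytest.raises(SaturationError):
            k2p("AAAAAAAAAA", "GGGGGGGGGG")

    def test_jukes_cantor_limit(self):
        """With transitions:transversions = 1:2 and low divergence, K2P
        approaches the Jukes-Cantor correction."""
        n = 3000
        seq = "ACGT" * (n // 4)
        for subs in (15, 30):  # P+Q <= 0.05 regime (per-site 0.005..0.01 x3)
            other = _mutate(seq, subs, 2 * subs)
            r = k2p(seq, other)
            p_total = 3 * subs / n
            jc = -0.75 * math.log(1 - 4 * p_total / 3)
            assert r.d == pytest.approx(jc, abs=1e-3)


class TestK2PMatrix:
    def test_identical_sequences_zero_matrix(self):
        seqs = [CodingSequence(l, "t", "ACGTACGTACGT") for l in "ABC"]
        m = k2p_matrix(seqs)
        assert np.allclose(m.d, 0)

    def test_order_invariance_up_to_permutation(self):
        base = "ACGT" * 30
        seqs = [
            CodingSequence("A", "t", base),
            CodingSequence("B", "t", _mutate(base, 3, 2)),
            CodingSequence("C", "t", _mutate(base, 8, 4)),
        ]
        m1 = k2p_matrix(seqs)
        m2 = k2p_matrix(seqs[::-1])
        for a, b in itertools.combinations(range(3), 2):
            ra, rb = m2.labels.index(m1.labels[a]), m2.labels.index(m1.labels[b])
            assert m1.d[a, b] == pytest.approx(m2.d[ra, rb])

    def test_unequal_lengths_error(self):
        seqs = [CodingSequence("A", "t", "ACGTAC"), CodingSequence("B", "t", "ACG")]
        with pytest.raises(ValueError, match="equal length"):
            k2p_matrix(seqs)

    def test_trim_to_common_length(self):
        seqs = [CodingSequence("A", "t", "ACGTACGTA"), CodingSequence("B", "t", "ACGTAC")]
        trimmed = trim_to_common_length(seqs)
        assert {len(s.bases) for s in trimmed} == {6}


def _random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """Random binary tree built by successive joins -> (labels, patristic
    matrix). Distances are accumulated independently of the package's tree
    code: each cluster carries leaf-to-root distances, and joining clusters
    with fresh branch lengths fixes all cross distances."""
    labels = [f"t{i}" for i in range(n_taxa)]
    d = {l: {} for l in labels}
    clusters = [{l: 0.0} for l in labels]  # leaf -> distance to cluster root
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        b1, b2 = rng.uniform(0.05, 1.0, size=2)
        a_map, b_map = clusters[i], clusters[j]
        for la, da in a_map.items():
            for lb, db in b_map.items():
                d[la][lb] = d[lb][la] = da + b1 + db + b2
        merged = {l: v + b1 for l, v in a_map.items()}
        merged.update({l: v + b2 for l, v in b_map.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    D = np.zeros((n_taxa, n_taxa))
    for a, la in enumerate(labels):
        for b, lb in enumerate(labels):
            if a != b:
                D[a, b] = d[la][lb]
    return labels, D


class TestNeighborJoining:
    def test_four_taxon_topology_vs_brute_force(self):
        # additive matrix for ((A,B),(C,D)) with internal edge 3
        D = np.array([[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]],
                     dtype=float)
        labels = ("A", "B", "C", "D")
        # brute force: the split minimizing the four-point condition
        def split_score(pair):
            (a, b), (c, d) = pair, tuple(x for x in range(4) if x not in pair)
            return D[a, b] + D[c, d]
        best = min(itertools.combinations(range(4), 2), key=split_score)
        assert best == (0, 1)  # oracle: A,B together
        tree = neighbor_joining(DistanceMatrix(labels, D, D * 0, D * 0,
                                               np.zeros_like(D, dtype=int)))
        newick = write_newick(tree)
        dt = dendropy.Tree.get(data=newick, schema="newick")
        splits = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                  for e in dt.edges() if e.head_node.is_internal()}
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), D, D * 0, D * 0,
                                               np.zeros_like(D, dtype=int)))
        labels, M = tree_distance_matrix(tree)
        assert labels == ("A", "B", "C")
        assert np.allclose(M, D)

    @pytest.mark.parametrize("n_taxa", [4, 5, 6, 8])
    def test_additive_matrix_recovery(self, n_taxa):
        """NJ reproduces the generating tree's path lengths exactly on
        additive matrices (uniqueness of the tree metric)."""
        rng = np.random.default_rng(n_taxa * 17)
        labels, D = _random_additive_matrix(rng, n_taxa)
        tree = neighbor_joining(
            DistanceMatrix(tuple(labels), D, D * 0, D * 0,
                           np.zeros_like(D, dtype=int))
        )
        out_labels, M = tree_distance_matrix(tree)
        order = [out_labels.index(l) for l in labels]
        assert np.allclose(M[np.ix_(order, order)], D, atol=1e-8)

    def test_matches_independent_nj_topology(self):
        """Same unrooted topology as scikit-bio's NJ on a noisy matrix."""
        import skbio

        rng = np.random.default_rng(5)
        labels, D = _random_additive_matrix(rng, 6)
        noise = rng.uniform(-0.01, 0.01, D.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        Dn = np.clip(D + noise, 0, None)
        tree = neighbor_joining(
            DistanceMatrix(tuple(labels), Dn, Dn * 0, Dn * 0,
                           np.zeros_like(Dn, dtype=int))
        )
        mine = dendropy.Tree.get(data=write_newick(tree), schema="newick")
        ref_nwk = str(skbio.tree.nj(skbio.DistanceMatrix(Dn, ids=labels)))
        ns = mine.taxon_namespace
        ref = dendropy.Tree.get(data=ref_nwk, schema="newick", taxon_namespace=ns)
        mine.encode_bipartitions()
        ref.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(mine, ref)
        assert rf == 0

    def test_negative_distance_rejected(self):
        D = np.array([[0, -1, 2], [-1, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B", "C"), D, D * 0, D * 0,
                                            np.zeros_like(D, dtype=int)))


class TestNewick:
    def _simple_tree(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        return neighbor_joining(DistanceMatrix(("C", "A", "B"), D, D * 0, D * 0,
                                               np.zeros_like(D, dtype=int)))

    def test_three_taxon_shape(self):
        nwk = write_newick(self._simple_tree())
        assert nwk.startswith("(") and nwk.endswith(";")
        assert nwk.count(",") == 2

    def test_roundtrip_preserves_topology_and_lengths(self):
        tree = self._simple_tree()
        nwk = write_newick(tree)
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        labels, M = tree_distance_matrix(tree)
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        M[i, j], abs=1e-5
                    )

    def test_labels_with_spaces_are_quoted(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        tree = neighbor_joining(
            DistanceMatrix(("tax A", "tax B", "tax C"), D, D * 0, D * 0,
                           np.zeros_like(D, dtype=int))
        )
        nwk = write_newick(tree)
        assert "'tax A'" in nwk
        dt = dendropy.Tree.get(data=nwk, schema="newick")
        assert {t.label for t in dt.taxon_namespace} == {"tax A", "tax B", "tax C"}

    def test_deterministic_child_ordering(self):
        a = write_newick(self._simple_tree())
        b = write_newick(self._simple_tree())
        assert a == b


def test_species_like_set_groups_rodents_and_primates():
    """Synthetic species-like CDSs evolved with rodents closer to each other
    than to primates recover the expected grouping."""
    rng = np.random.default_rng(12)
    base = "".join(rng.choice(list("ACGT"), size=600))

    def evolve(seq, n_subs, rng):
        out = list(seq)
        sites = rng.choice(len(out), size=n_subs, replace=False)
        for i in sites:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
        return "".join(out)

    primate_anc = evolve(base, 30, rng)
    rodent_anc = evolve(base, 40, rng)
    seqs = [
        CodingSequence("human", "t", evolve(primate_anc, 8, rng)),
        CodingSequence("orangutan", "t", evolve(primate_anc, 9, rng)),
        CodingSequence("rat", "t", evolve(rodent_anc, 12, rng)),
        CodingSequence("mouse", "t", evolve(rodent_anc, 11, rng)),
        CodingSequence("cattle", "t", evolve(base, 35, rng)),
    ]
    tree = neighbor_joining(k2p_matrix(seqs))
    dt = dendropy.Tree.get(data=write_newick(tree), schema="newick")
    splits = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in dt.edges() if e.head_node.is_internal()}
    assert frozenset({"rat", "mouse"}) in splits
    assert frozenset({"human", "orangutan"}) in splits
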