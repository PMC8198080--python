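"""Kimura two-parameter distances and neighbor-joining trees.

K2P separates transitions (A↔G, C↔T; proportion P) from transversions
(proportion Q):

    d = −½·ln(1 − 2P − Q) − ¼·ln(1 − 2Q)

in substitutions per site. Sites where either sequence carries a gap or
ambiguous base are excluded pairwise (pairwise deletion). The tree is built
with the Saitou–Nei neighbor-joining agglomeration and written as Newick
with deterministic (lexicographic) child ordering.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import CodingSequence

log = logging.getLogger(__name__)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


class SaturationError(ValueError):
    """Divergence too high for the K2P log corrections."""


class NoSitesError(ValueError):
    """No comparable sites after pairwise deletion."""


@dataclass(frozen=True)
class K2PResult:
    d: float
    P: float
    Q: float
    sites_used: int


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    sites_used: np.ndarray

    def as_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for i, lab in enumerate(self.labels):
            lines.append(lab + "\t" + "\t".join(f"{v:.6f}" for v in self.d[i]))
        return "\n".join(lines) + "\n"


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name or ""]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree held at an internal node of degree 3 (or a leaf pair)."""

    root: TreeNode

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(self.root.leaves()))


def k2p(seq_a: str, seq_b: str) -> K2PResult:
    """K2P distance between two aligned nucleotide strings."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    transitions = transversions = sites = 0
    for x, y in zip(a, b):
        if x not in _VALID or y not in _VALID:
            continue
        sites += 1
        if x == y:
            continue
        if (x in _PURINES) == (y in _PURINES):
            transitions += 1
        else:
            transversions += 1
    if sites == 0:
        raise NoSitesError("NO_SITES: no comparable positions")
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"SATURATION: P={P:.4f}, Q={Q:.4f}")
    d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
    return K2PResult(d=float(d), P=P, Q=Q, sites_used=sites)


def trim_to_common_length(seqs: list[CodingSequence]) -> list[CodingSequence]:
    """Convenience for unaligned equal-gene CDS sets: truncate every sequence
    to the shortest length present (kept as a multiple of 3)."""
    if not seqs:
        raise ValueError("no sequences")
    n = min(len(s.bases) for s in seqs)
    n -= n % 3
    return [CodingSequence(s.id, s.species, s.bases[:n]) for s in seqs]


def k2p_matrix(aligned: list[CodingSequence]) -> DistanceMatrix:
    """All-pairs K2P distances over equal-length (aligned) sequences."""
    if len(aligned) < 2:
        raise ValueError("need at least two sequences")
    lengths = {len(s.bases) for s in aligned}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not equal length: {sorted(lengths)}")
    n = len(aligned)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        try:
            res = k2p(aligned[i].bases, aligned[j].bases)
        except ValueError as exc:
            raise type(exc)(f"pair ({aligned[i].id}, {aligned[j].id}): {exc}") from exc
        d[i, j] = d[j, i] = res.d
        P[i, j] = P[j, i] = res.P
        Q[i, j] = Q[j, i] = res.Q
        sites[i, j] = sites[j, i] = res.sites_used
    np.fill_diagonal(sites, lengths.pop())
    return DistanceMatrix(
        labels=tuple(s.id for s in aligned), d=d, P=P, Q=Q, sites_used=sites
    )


def neighbor_joining(m: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Ties are broken by the lowest active-index pair; negative branch lengths
    are clamped to 0 with a logged note.
    """
    D = np.array(m.d, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(D < 0):
        raise ValueError("negative distances")
    n = len(m.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")

    def _clamp(x: float) -> float:
        if x < 0:
            log.info("negative branch length %.6g clamped to 0", x)
            return 0.0
        return x

    nodes = [TreeNode(name=l) for l in m.labels]
    active = list(range(n))  # indices into the growing distance matrix
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_idx = n

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    node_of = {i: nodes[i] for i in range(n)}
    while len(active) > 3:
        r = len(active)
        row_sums = {i: sum(get(i, k) for k in active) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * get(i, j) - row_sums[i] - row_sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        dij = get(i, j)
        li = _clamp(dij / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2)))
        lj = _clamp(dij - (dij / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))))
        new = TreeNode(children=[(node_of[i], li), (node_of[j], lj)])
        u = next_idx
        next_idx += 1
        for k in active:
            if k in (i, j):
                continue
            duk = max((get(i, k) + get(j, k) - dij) / 2.0, 0.0)
            dist[(min(u, k), max(u, k))] = duk
        active = [k for k in active if k not in (i, j)] + [u]
        node_of[u] = new
    i, j, k = active
    li = _clamp((get(i, j) + get(i, k) - get(j, k)) / 2.0)
    lj = _clamp((get(i, j) + get(j, k) - get(i, k)) / 2.0)
    lk = _clamp((get(i, k) + get(j, k) - get(i, j)) / 2.0)
    root = TreeNode(children=[(node_of[i], li), (node_of[j], lj), (node_of[k], lk)])
    return PhyloTree(root=root)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node: TreeNode) -> str:
    if not node.children:
        return _quote(node.name or "")
    parts = sorted(node.children, key=lambda cl: min(cl[0].leaves()))
    inner = ",".join(f"{_newick_node(c)}:{l:.6f}" for c, l in parts)
    return f"({inner})"


def write_newick(tree: PhyloTree) -> str:
    """Newick text with branch lengths; children ordered by smallest leaf label."""
    return _newick_node(tree.root) + ";"


def tree_distance_matrix(tree: PhyloTree) -> tuple[tuple[str, ...], np.ndarray]:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""
    dists: dict[str, dict[str, float]] = {}

    def walk(node: TreeNode) -> dict[str, float]:
        # distances from every leaf under `node` to `node`
        if not node.children:
            return {node.name or "": 0.0}
        below: list[dict[str, float]] = []
        for child, bl in node.children:
            sub = walk(child)
            below.append({leaf: d + bl for leaf, d in sub.items()})
        for a_map, b_map in itertools.combinations(below, 2):
            for la, da in a_map.items():
                for lb, db in b_map.items():
                    dists.setdefault(la, {})[lb] = da + db
                    dists.setdefault(lb, {})[la] = da + db
        merged: dict[str, float] = {}
        for mp in below:
            merged.update(mp)
        return merged

    walk(tree.root)
    labels = tuple(sorted(dists))
    out = np.zeros((len(labels), len(labels)))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                out[i, j] = dists[a][b]
    return labels, out
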