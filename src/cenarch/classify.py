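"""Family classification of centromeric retrotransposons and NJ trees.

Elements are assigned to named families (e.g. the five centromeric
retrotransposon families of wheat, CRW1–CRW5) by best alignment identity
against a labelled consensus library; the superfamily (Gypsy/Copia/unknown)
is inherited from the assigned family.  For clade-level views a
neighbor-joining tree is built on Kimura two-parameter distances, and
element leaves can be labelled by their nearest reference leaf.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .dating import SubstitutionCounts, count_substitutions, kimura2p


@dataclasses.dataclass
class FamilyEntry:
    family_id: str
    superfamily: str
    consensus: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 100:
            raise ValueError("consensus must be at least 100 nt")


@dataclasses.dataclass
class FamilyLibrary:
    entries: list[FamilyEntry]
    min_identity: float = 0.80

    def __post_init__(self) -> None:
        ids = [e.family_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("family ids must be unique")


def _global_alignment(a: str, b: str) -> tuple[str, str]:
    """Global (NW) alignment via edlib; returns gapped strings."""
    res = edlib.align(a, b, mode="NW", task="path")
    nice = edlib.getNiceAlignment(res, a, b)
    return nice["query_aligned"], nice["target_aligned"]


def alignment_identity(a: str, b: str) -> float:
    """Matches over aligned columns of the global alignment (gaps count against)."""
    qa, ta = _global_alignment(a.upper(), b.upper())
    matches = sum(1 for x, y in zip(qa, ta) if x == y and x != "-")
    return matches / len(qa)


def best_hit_assign(
    element_seq: str, library: FamilyLibrary
) -> tuple[str, str, float]:
    """Assign an element to its best-matching family.

    Returns (family_id, superfamily, identity); families below
    ``min_identity`` yield ("other", "unknown", identity).
    """
    if not element_seq:
        raise ValueError("element sequence must be non-empty")
    if not library.entries:
        raise ValueError("library is empty")
    best_fam, best_id = None, -1.0
    for entry in library.entries:
        ident = alignment_identity(element_seq, entry.consensus)
        if ident > best_id:
            best_fam, best_id = entry, ident
    if best_id >= library.min_identity:
        return best_fam.family_id, best_fam.superfamily, best_id
    return "other", "unknown", best_id


def pairwise_distance_matrix(
    seqs: Sequence[str], ids: Optional[Sequence[str]] = None
) -> tuple[pd.DataFrame, set]:
    """All-vs-all K2P distance matrix from global alignments.

    Saturated pairs (K2P undefined) are set to 1.1x the largest finite
    distance and flagged.  The matrix is symmetric with a zero diagonal;
    K2P distances need not satisfy the triangle inequality.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = list(ids) if ids is not None else [f"seq{i}" for i in range(len(seqs))]
    n = len(seqs)
    D = np.zeros((n, n))
    flags: set = set()
    saturated: list[tuple[int, int]] = []
    for i, j in itertools.combinations(range(n), 2):
        counts = count_substitutions(_global_alignment(seqs[i].upper(), seqs[j].upper()))
        try:
            d = kimura2p(counts)
        except ValueError:
            saturated.append((i, j))
            continue
        D[i, j] = D[j, i] = d
    if saturated:
        flags.add("saturated_pairs")
        cap = D.max() * 1.1 if D.max() > 0 else 1.0
        for i, j in saturated:
            D[i, j] = D[j, i] = cap
    return pd.DataFrame(D, index=ids, columns=ids), flags


# ---------------------------------------------------------------- NJ tree


@dataclasses.dataclass
class TreeNode:
    name: str
    children: list = dataclasses.field(default_factory=list)  # (TreeNode, length)

    def is_leaf(self) -> bool:
        return not self.children


@dataclasses.dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root; Newick output."""

    root: TreeNode
    leaf_names: list[str]
    flags: set = dataclasses.field(default_factory=set)

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(f"{fmt(c)}:{l:.6f}" for c, l in node.children)
            return f"({inner})"

        return fmt(self.root) + ";"

    def _adjacency(self) -> dict:
        adj: dict[str, list[tuple[str, float]]] = {}

        def walk(node: TreeNode) -> None:
            adj.setdefault(node.name, [])
            for child, length in node.children:
                adj[node.name].append((child.name, length))
                adj.setdefault(child.name, []).append((node.name, length))
                walk(child)

        walk(self.root)
        return adj

    def path_lengths(self) -> pd.DataFrame:
        """Leaf-to-leaf path length matrix (sum of branch lengths)."""
        adj = self._adjacency()
        leaves = self.leaf_names
        out = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for src in leaves:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for dst in leaves:
                out.loc[src, dst] = dist[dst]
        return out


def neighbor_joining(
    matrix, taxa: Optional[Sequence[str]] = None
) -> PhyloTree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion are broken by the lexicographically smallest
    (sorted) pair of node labels, so the topology is deterministic.
    Negative branch lengths are clamped to zero and flagged.  For an
    additive matrix the tree's leaf-to-leaf path lengths reproduce the
    input exactly.
    """
    if isinstance(matrix, pd.DataFrame):
        taxa = list(matrix.index)
        D = matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(matrix, dtype=float)
        if taxa is None:
            taxa = [f"t{i}" for i in range(len(D))]
        taxa = list(taxa)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = len(taxa)
    flags: set = set()

    def clamp(x: float) -> float:
        if x < 0:
            flags.add("negative_branch_clamped")
            return 0.0
        return x

    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        flags.add("degenerate_two_taxa")
        a, b = TreeNode(taxa[0]), TreeNode(taxa[1])
        root = TreeNode("root", [(a, clamp(D[0, 1] / 2)), (b, clamp(D[0, 1] / 2))])
        return PhyloTree(root=root, leaf_names=taxa, flags=flags)

    nodes: dict[str, TreeNode] = {t: TreeNode(t) for t in taxa}
    active = list(taxa)
    dist = {
        (a, b): float(D[i, j])
        for i, a in enumerate(taxa)
        for j, b in enumerate(taxa)
        if i != j
    }

    def d(a: str, b: str) -> float:
        return dist[(a, b)]

    counter = itertools.count(1)
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active), 2):
            q = (m - 2) * d(a, b) - r[a] - r[b]
            key = (q, a, b)
            if best is None or key < best:
                best = key
        _, a, b = best
        la = d(a, b) / 2 + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        u = f"_nj{next(counter)}"
        nodes[u] = TreeNode(u, [(nodes[a], clamp(la)), (nodes[b], clamp(lb))])
        for c in active:
            if c in (a, b):
                continue
            duc = (d(a, c) + d(b, c) - d(a, b)) / 2
            dist[(u, c)] = dist[(c, u)] = duc
        active = [c for c in active if c not in (a, b)] + [u]

    # final three nodes joined at a central vertex (closed form)
    a, b, c = sorted(active)
    la = clamp((d(a, b) + d(a, c) - d(b, c)) / 2)
    lb = clamp((d(a, b) + d(b, c) - d(a, c)) / 2)
    lc = clamp((d(a, c) + d(b, c) - d(a, b)) / 2)
    root = TreeNode("root", [(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return PhyloTree(root=root, leaf_names=taxa, flags=flags)


def clade_report(
    tree: PhyloTree, reference_leaves: dict[str, str]
) -> dict[str, str]:
    """Label each element leaf with the family of its nearest reference leaf.

    Nearness is tree path length; reference leaves map id -> family.
    """
    if not reference_leaves:
        raise ValueError("need at least one reference leaf")
    paths = tree.path_lengths()
    refs = [r for r in reference_leaves if r in paths.index]
    if not refs:
        raise ValueError("no reference leaf present in the tree")
    out: dict[str, str] = {}
    for leaf in tree.leaf_names:
        if leaf in reference_leaves:
            continue
        nearest = min(refs, key=lambda r: (paths.loc[leaf, r], r))
        out[leaf] = reference_leaves[nearest]
    return out
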