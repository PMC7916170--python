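"""Neighbor-joining trees, bootstrap support, and clade extraction.

NJ with deterministic tie-breaking stands in for full likelihood inference:
the claim carried by this stage is clade-structure recovery (which lineages
group together and how well the data support the split), not branch-length
or model-parameter estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .msa import Supermatrix, distance_matrix


@dataclass
class PhyloTree:
    """An unrooted tree as an adjacency map over node ids.

    Leaves carry taxon names; internal edges may carry bootstrap supports
    in [0, 100], keyed by the bipartition (the leaf side not containing the
    reference taxon, as a frozenset).
    """

    adjacency: dict[int, dict[int, float]]
    leaf_names: dict[int, str]
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(self.leaf_names.values())

    def leaves(self) -> list[int]:
        return sorted(self.leaf_names)

    def _side(self, a: int, b: int) -> frozenset:
        """Leaf names reachable from b without crossing edge (a, b)."""
        stack, seen, names = [b], {a, b}, []
        while stack:
            cur = stack.pop()
            if cur in self.leaf_names:
                names.append(self.leaf_names[cur])
            for nxt in self.adjacency[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return frozenset(names)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each as the side excluding the reference
        (lexicographically smallest) taxon."""
        ref = min(self.taxa)
        out: set[frozenset] = set()
        for a in self.adjacency:
            for b in self.adjacency[a]:
                if a < b:
                    side = self._side(a, b)
                    if ref in side:
                        side = frozenset(self.taxa) - side
                    if 1 < len(side) < len(self.taxa) - 1:
                        out.add(side)
        return out

    def newick(self, root: int | None = None) -> str:
        """Serialize, rooted arbitrarily at an internal node; bootstrap
        supports appear as internal node labels."""
        if root is None:
            internal = [n for n in self.adjacency if n not in self.leaf_names]
            root = min(internal) if internal else min(self.adjacency)
        ref = min(self.taxa)
        all_taxa = frozenset(self.taxa)

        def fmt(node: int, parent: int | None) -> str:
            children = [n for n in self.adjacency[node] if n != parent]
            if not children and node in self.leaf_names:
                return self.leaf_names[node]
            inner = ",".join(
                f"{fmt(c, node)}:{self.adjacency[node][c]:.6f}" for c in children
            )
            label = ""
            if parent is not None:
                side = self._side(parent, node)
                key = side if ref not in side else all_taxa - side
                if key in self.supports:
                    label = f"{self.supports[key]:.0f}"
            return f"({inner}){label}"

        return fmt(root, None) + ";"


def nj_tree(distances: pd.DataFrame) -> PhyloTree:
    """Neighbor-joining with deterministic tie-breaking.

    The Q-criterion minimum is selected with ties broken by the
    lexicographically lowest cluster-label pair; negative branch lengths are
    clamped to zero. Raises ``ValueError`` on a non-symmetric matrix.
    """
    D = distances.to_numpy(dtype=float)
    taxa = [str(t) for t in distances.index]
    if list(distances.index) != list(distances.columns) or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric with matching labels")
    if len(taxa) < 3:
        raise ValueError("nj_tree needs >= 3 taxa")

    adjacency: dict[int, dict[int, float]] = {}
    leaf_names: dict[int, str] = {}
    next_id = 0

    def new_node() -> int:
        nonlocal next_id
        nid = next_id
        next_id += 1
        adjacency[nid] = {}
        return nid

    def connect(a: int, b: int, length: float) -> None:
        length = max(0.0, float(length))
        adjacency[a][b] = length
        adjacency[b][a] = length

    active: list[int] = []
    labels: dict[int, str] = {}  # tie-break label = smallest leaf name in cluster
    for name in taxa:
        nid = new_node()
        leaf_names[nid] = name
        labels[nid] = name
        active.append(nid)
    dist = {
        frozenset((active[i], active[j])): D[i, j]
        for i in range(len(taxa))
        for j in range(i + 1, len(taxa))
    }

    while len(active) > 3:
        r = len(active)
        total = {
            a: sum(dist[frozenset((a, b))] for b in active if b != a)
            for a in active
        }
        best = None
        for ii in range(r):
            for jj in range(ii + 1, r):
                a, b = active[ii], active[jj]
                q = (r - 2) * dist[frozenset((a, b))] - total[a] - total[b]
                key = tuple(sorted((labels[a], labels[b])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, a, b)
        _, _, a, b = best
        dab = dist[frozenset((a, b))]
        la = 0.5 * dab + (total[a] - total[b]) / (2 * (r - 2))
        lb = dab - la
        u = new_node()
        connect(u, a, la)
        connect(u, b, lb)
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((u, c))] = 0.5 * (
                dist[frozenset((a, c))] + dist[frozenset((b, c))] - dab
            )
        active = [n for n in active if n not in (a, b)] + [u]
        labels[u] = min(labels[a], labels[b])

    a, b, c = active
    u = new_node()
    dab = dist[frozenset((a, b))]
    dac = dist[frozenset((a, c))]
    dbc = dist[frozenset((b, c))]
    connect(u, a, 0.5 * (dab + dac - dbc))
    connect(u, b, 0.5 * (dab + dbc - dac))
    connect(u, c, 0.5 * (dac + dbc - dab))
    return PhyloTree(adjacency, leaf_names)


def bootstrap_support(sm: Supermatrix, n_reps: int = 100, seed: int = 0,
                      max_distance: float = 10.0) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Columns are resampled with replacement per replicate; the support of
    each original bipartition is the percentage of replicate trees that
    contain it. Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(distance_matrix(sm, max_distance))
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    ncol = sm.n_columns
    arr = np.array([list(sm.rows[t]) for t in sm.taxa])
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = {
            t: "".join(arr[i, cols]) for i, t in enumerate(sm.taxa)
        }
        rep = Supermatrix(sm.taxa, rep_rows, [("all", (0, ncol))])
        try:
            rep_tree = nj_tree(distance_matrix(rep, max_distance))
        except ValueError:  # a pair lost all comparable columns
            continue
        rep_splits = rep_tree.bipartitions()
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    tree.supports = {s: 100.0 * c / n_reps for s, c in counts.items()}
    return tree


@dataclass
class CladeReport:
    monophyletic: bool
    support: float | None
    taxa: frozenset


def extract_clades(tree: PhyloTree, outgroup: str,
                   group_labels: dict[str, set | list]
                   ) -> dict[str, CladeReport]:
    """Root on the outgroup and test each labelled group for monophyly.

    A group is monophyletic iff its taxa form one side of a bipartition not
    containing the outgroup (single-taxon groups are trivially
    monophyletic). The reported support is the bootstrap value of that
    bipartition where the tree carries supports.
    """
    taxa = set(tree.taxa)
    if outgroup not in taxa:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    ref = min(tree.taxa)
    all_taxa = frozenset(tree.taxa)
    # all clades of the tree rooted at the outgroup
    rooted_clades: set[frozenset] = set()
    for a in tree.adjacency:
        for b in tree.adjacency[a]:
            if a < b:
                side = tree._side(a, b)
                for s in (side, all_taxa - side):
                    if outgroup not in s and s:
                        rooted_clades.add(s)
    out: dict[str, CladeReport] = {}
    for label, members in group_labels.items():
        members = frozenset(members)
        missing = members - taxa
        if missing:
            raise ValueError(f"group {label!r} has unknown taxa {sorted(missing)}")
        mono = len(members) == 1 or members in rooted_clades
        support = None
        key = members if ref not in members else all_taxa - members
        if mono and key in tree.supports:
            support = tree.supports[key]
        out[label] = CladeReport(mono, support, members)
    return out
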