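"""Per-window Jukes-Cantor phylogenetics: pruning likelihood, branch-length
optimization with a minimum-branch-length floor, topology search, and
nonparametric bootstrap support.

The substitution model is Jukes-Cantor throughout: uniform stationary
frequencies (1/4), equal exchangeabilities, no rate heterogeneity.  For a
branch of length ``t`` substitutions/site the transition probabilities are::

    P(same)      = 1/4 + 3/4 * exp(-4t/3)
    P(different) = 1/4 - 1/4 * exp(-4t/3)

Gap and N characters are missing data: their partial-likelihood vectors are
all ones, so an all-missing column contributes exactly 0 to the
log-likelihood.  Likelihoods are computed over compressed site patterns and
are invariant to the (arbitrary) rooting used internally.

Free parameters are branch lengths only (JC has none of its own), so a fit
over ``t`` taxa contributes ``k = 2t - 3`` parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from nowsize.core_io import GAP, Alignment

__all__ = [
    "PhyloTree",
    "WindowFit",
    "SearchConfig",
    "jc_log_likelihood",
    "optimize_branch_lengths",
    "search_topology",
    "bootstrap_support",
    "canonical_topology",
    "compress_patterns",
    "jc_distance_matrix",
    "neighbor_joining",
    "all_unrooted_topologies",
]


class PhylogenyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Tree representation
# ---------------------------------------------------------------------------

class PhyloTree:
    """An unrooted tree with branch lengths in substitutions/site.

    Leaves are nodes ``0 .. t-1`` in the order of ``taxa``; internal nodes
    follow.  Edges are mutable ``[u, v, length]`` triples.  For ``t >= 4``
    the tree is binary-unrooted (``t - 2`` internal nodes, ``2t - 3`` edges);
    ``t = 3`` is the single star topology and ``t = 2`` a single edge.
    """

    __slots__ = ("taxa", "edges", "_canon")

    def __init__(self, taxa: Sequence[str], edges: Iterable[Sequence[float]]):
        self.taxa = list(taxa)
        self.edges = [[int(u), int(v), float(l)] for u, v, l in edges]
        self._canon: Optional[str] = None

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, taxa: Optional[Sequence[str]] = None) -> "PhyloTree":
        """Parse a newick string (rooted or unrooted); a bifurcating root is
        suppressed so the result is unrooted.

        ``taxa`` fixes the leaf order; by default leaves are sorted by label.
        """
        import dendropy

        dtree = dendropy.Tree.get(data=newick, schema="newick")
        labels = [leaf.taxon.label for leaf in dtree.leaf_node_iter()]
        if taxa is None:
            taxa = sorted(labels)
        if set(labels) != set(taxa):
            raise PhylogenyError("newick leaves do not match the requested taxa")
        index = {name: i for i, name in enumerate(taxa)}
        next_id = len(taxa)
        edges: list[list[float]] = []

        def build(node) -> int:
            nonlocal next_id
            if node.is_leaf():
                return index[node.taxon.label]
            children = node.child_nodes()
            if node.parent_node is None and len(children) == 2:
                # suppress the bifurcating root: join its two children
                a, b = children
                ia, ib = build(a), build(b)
                edges.append([ia, ib, (a.edge.length or 0.0) + (b.edge.length or 0.0)])
                return -1
            me = next_id
            next_id += 1
            for ch in children:
                ic = build(ch)
                edges.append([me, ic, ch.edge.length or 0.0])
            return me

        root_id = build(dtree.seed_node)
        if root_id == -1 and len(taxa) > 2:
            # the suppressed root joined two clades directly; nothing else to do
            pass
        return cls(taxa, edges)

    def copy(self) -> "PhyloTree":
        t = PhyloTree(self.taxa, [list(e) for e in self.edges])
        return t

    # -- basic structure ----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_nodes(self) -> int:
        return max(max(u, v) for u, v, _ in self.edges) + 1 if self.edges else 1

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per node: list of (neighbor, edge index)."""
        adj: list[list[tuple[int, int]]] = [[] for _ in range(self.n_nodes)]
        for i, (u, v, _) in enumerate(self.edges):
            adj[u].append((v, i))
            adj[v].append((u, i))
        return adj

    def internal_edges(self) -> list[int]:
        t = self.n_taxa
        return [i for i, (u, v, _) in enumerate(self.edges) if u >= t and v >= t]

    def branch_lengths(self) -> np.ndarray:
        return np.array([e[2] for e in self.edges])

    def sum_internal_branch_lengths(self) -> float:
        return float(sum(self.edges[i][2] for i in self.internal_edges()))

    # -- topology identity --------------------------------------------------

    @property
    def canonical_topology(self) -> str:
        if self._canon is None:
            self._canon = canonical_topology(self)
        return self._canon

    def invalidate(self) -> None:
        self._canon = None

    def bipartitions(self) -> set[int]:
        """Bitmasks (normalized: bit of taxon 0 clear) of internal-edge splits."""
        t = self.n_taxa
        adj = self.adjacency()
        full = (1 << t) - 1
        masks = set()
        for ei in self.internal_edges():
            u, v, _ = self.edges[ei]
            mask = _leafset_mask(adj, u, v, t)
            if mask & 1:
                mask ^= full
            masks.add(mask)
        return masks

    # -- output -------------------------------------------------------------

    def to_newick(self, support: Optional[dict[int, float]] = None, precision: int = 10) -> str:
        """Newick with branch lengths; ``support`` maps edge index -> value
        written as an internal-node label."""
        if self.n_taxa == 2:
            d = self.edges[0][2]
            return f"({self.taxa[0]}:{0.0:.{precision}g},{self.taxa[1]}:{d:.{precision}g});"
        adj = self.adjacency()
        root = next(n for n in range(self.n_taxa, self.n_nodes) if adj[n])

        def render(node: int, parent: int) -> str:
            parts = []
            for nbr, ei in adj[node]:
                if nbr == parent:
                    continue
                length = self.edges[ei][2]
                if nbr < self.n_taxa:
                    parts.append(f"{self.taxa[nbr]}:{length:.{precision}g}")
                else:
                    label = ""
                    if support is not None and ei in support:
                        label = f"{support[ei]:.4g}"
                    parts.append(f"({render(nbr, node)}){label}:{length:.{precision}g}")
            return ",".join(parts)

        return f"({render(root, -1)});"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_taxa} taxa, {self.canonical_topology})"


def _leafset_mask(adj, node: int, banned: int, t: int) -> int:
    """Bitmask of leaves reachable from ``node`` without crossing to ``banned``."""
    mask = 0
    stack = [(node, banned)]
    while stack:
        cur, par = stack.pop()
        if cur < t:
            mask |= 1 << cur
            continue
        for nbr, _ in adj[cur]:
            if nbr != par:
                stack.append((nbr, cur))
    return mask


def canonical_topology(tree: PhyloTree) -> str:
    """Canonical string for the unrooted leaf-labelled topology.

    The tree is rooted at the neighbor of the lexicographically smallest
    taxon (that taxon included as a child) and children are sorted by their
    canonical substrings; branch lengths are ignored.  Two trees share the
    same unrooted topology iff their canonical strings are equal.
    """
    if tree.n_taxa < 3:
        raise PhylogenyError("canonical topology requires >= 3 leaves")
    adj = tree.adjacency()
    smallest = min(range(tree.n_taxa), key=lambda i: tree.taxa[i])
    root = adj[smallest][0][0]

    def canon(node: int, parent: int) -> str:
        if node < tree.n_taxa:
            return tree.taxa[node]
        parts = sorted(canon(nbr, node) for nbr, _ in adj[node] if nbr != parent)
        return "(" + ",".join(parts) + ")"

    parts = sorted([tree.taxa[smallest]] + [
        canon(nbr, root) for nbr, _ in adj[root] if nbr != smallest
    ])
    return "(" + ",".join(parts) + ");"


# ---------------------------------------------------------------------------
# Fit containers / configuration
# ---------------------------------------------------------------------------

@dataclass
class WindowFit:
    """Maximum-likelihood result for one window."""

    interval: tuple[int, int]
    tree: PhyloTree
    lnL: float
    k: int
    n_taxa_with_data: int
    n_unique_sequences: int
    mean_support: Optional[float] = None

    @property
    def topology_id(self) -> str:
        return self.tree.canonical_topology


@dataclass
class SearchConfig:
    """Controls for the per-window ML fit.

    ``blmin`` is the minimum branch length; when fitting windows it is set to
    ``1/window_size`` so every branch represents at least one substitution,
    penalizing spurious resolution in uninformative windows.
    """

    blmin: float = 1e-6
    blmax: float = 10.0
    strategy: str = "auto"  # auto | exhaustive | nni
    bootstrap_reps: int = 1000
    tolerance: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.blmin < self.blmax):
            raise ValueError("require 0 < blmin < blmax")
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")

    def with_blmin(self, blmin: float) -> "SearchConfig":
        return SearchConfig(blmin, self.blmax, self.strategy,
                            self.bootstrap_reps, self.tolerance, self.seed)


# ---------------------------------------------------------------------------
# Pattern compression
# ---------------------------------------------------------------------------

def compress_patterns(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical alignment columns.

    Returns ``(patterns, weights)`` where ``patterns`` is ``(t, P)`` uint8 and
    ``weights`` counts how many columns carry each pattern.
    """
    cols = np.ascontiguousarray(data.T)
    void = cols.view(np.dtype((np.void, cols.shape[1])))
    _, idx, counts = np.unique(void.ravel(), return_index=True, return_counts=True)
    patterns = cols[idx].T.astype(np.uint8)
    return np.ascontiguousarray(patterns), counts.astype(np.float64)


def _tip_partials(patterns: np.ndarray) -> list[np.ndarray]:
    """Per-leaf (P, 4) partial-likelihood arrays; missing -> all ones."""
    out = []
    for row in patterns:
        P = row.shape[0]
        L = np.zeros((P, 4))
        observed = row < GAP
        L[observed, row[observed]] = 1.0
        L[~observed] = 1.0
        out.append(L)
    return out


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _branch_message(L: np.ndarray, length: float) -> np.ndarray:
    """Propagate a partial-likelihood array across a branch under JC."""
    e = math.exp(-4.0 * length / 3.0)
    S = L.sum(axis=1, keepdims=True)
    return 0.25 * (1.0 - e) * S + e * L


def _subtree_partial(tree: PhyloTree, adj, tips: list[np.ndarray],
                     node: int, parent: int) -> tuple[np.ndarray, np.ndarray]:
    """Partial likelihood at ``node`` of the component not crossing ``parent``.

    Returns ``(L, logscale)`` with per-pattern scaling to avoid underflow.
    """
    t = tree.n_taxa
    if node < t:
        return tips[node], np.zeros(tips[node].shape[0])
    L = None
    logscale = None
    for nbr, ei in adj[node]:
        if nbr == parent:
            continue
        Lc, sc = _subtree_partial(tree, adj, tips, nbr, node)
        msg = _branch_message(Lc, tree.edges[ei][2])
        if L is None:
            L, logscale = msg, sc.copy()
        else:
            L = L * msg
            logscale = logscale + sc
    # rescale
    m = L.max(axis=1)
    m[m == 0.0] = 1.0
    L = L / m[:, None]
    logscale = logscale + np.log(m)
    return L, logscale


def _lnl_from_patterns(tree: PhyloTree, tips: list[np.ndarray], weights: np.ndarray) -> float:
    if tree.n_taxa == 2:
        # single edge: root at leaf 1
        msg = _branch_message(tips[0], tree.edges[0][2])
        site = 0.25 * (tips[1] * msg).sum(axis=1)
        return float(weights @ np.log(site))
    adj = tree.adjacency()
    root = next(n for n in range(tree.n_taxa, tree.n_nodes) if adj[n])
    L, sc = _subtree_partial(tree, adj, tips, root, -1)
    site = 0.25 * L.sum(axis=1)
    return float(weights @ (np.log(site) + sc))


def jc_log_likelihood(aln: Alignment, tree: PhyloTree) -> float:
    """Felsenstein-pruning log-likelihood of ``aln`` on ``tree`` under JC.

    ``tree`` leaves must be a subset of the alignment taxa; at least two of
    them must carry data.  The result does not depend on the internal rooting.
    """
    sub = aln.subset(tree.taxa)
    if int(sub.taxa_with_data().sum()) < 2:
        raise PhylogenyError("likelihood undefined: fewer than 2 taxa with data")
    patterns, weights = compress_patterns(sub.data)
    return _lnl_from_patterns(tree, _tip_partials(patterns), weights)


# ---------------------------------------------------------------------------
# Branch-length optimization
# ---------------------------------------------------------------------------

def _edge_coefficients(A, Asc, B, Bsc, weights):
    """For an edge of length t separating partials A (at one end) and B (at
    the other), the per-pattern site likelihood is ``c1 + c2 * exp(-4t/3)``
    times ``exp(Asc + Bsc)``.  Returns (c1, c2, weighted scale constant)."""
    SA = A.sum(axis=1)
    SB = B.sum(axis=1)
    dot = (A * B).sum(axis=1)
    c1 = 0.0625 * SA * SB
    c2 = 0.25 * dot - c1
    return c1, c2, float(weights @ (Asc + Bsc))


def _brent_edge(c1, c2, wconst, weights, blmin, blmax):
    """Maximize the edge-profile likelihood over t in [blmin, blmax].

    In terms of e = exp(-4t/3) the profile lnL(e) = sum w log(c1 + c2 e) is
    concave (a weighted sum of logs of affine functions), so its derivative
    g(e) = sum w c2/(c1 + c2 e) is monotone and a safeguarded Newton
    iteration on g converges in a handful of steps.
    """
    lo = math.exp(-4.0 * blmax / 3.0)
    hi = math.exp(-4.0 * blmin / 3.0)

    def grad(e):
        r = c2 / (c1 + c2 * e)
        return float(weights @ r), r

    g_hi, _ = grad(hi)
    g_lo, _ = grad(lo)
    if g_hi >= 0.0:  # still increasing at the shortest branch: clamp to blmin
        e = hi
    elif g_lo <= 0.0:  # still decreasing at the longest branch: clamp to blmax
        e = lo
    else:
        a, b = lo, hi  # bracket with g(a) > 0 > g(b); g is decreasing in e
        e = 0.5 * (a + b)
        for _ in range(60):
            ge, r = grad(e)
            if ge > 0.0:
                a = e
            else:
                b = e
            gp = -float(weights @ (r * r))
            e_new = e - ge / gp if gp != 0.0 else 0.5 * (a + b)
            if not (a < e_new < b):
                e_new = 0.5 * (a + b)
            if abs(e_new - e) <= 1e-11 + 1e-9 * e:
                e = e_new
                break
            e = e_new
    t = min(max(-0.75 * math.log(e), blmin), blmax)
    e = math.exp(-4.0 * t / 3.0)
    lnl = float(weights @ np.log(c1 + c2 * e)) + wconst
    return t, lnl


def _root_structure(tree: PhyloTree):
    """Rooted view of the unrooted tree: (adj, root, parent, parent_edge,
    preorder node list).  Root is the first internal node."""
    adj = tree.adjacency()
    t = tree.n_taxa
    root = next((n for n in range(t, tree.n_nodes) if adj[n]), 1 if t == 2 else 0)
    n = tree.n_nodes
    parent = [-2] * n
    parent_edge = [-1] * n
    parent[root] = -1
    order = [root]
    stack = [root]
    while stack:
        u = stack.pop()
        for nbr, ei in adj[u]:
            if parent[nbr] == -2:
                parent[nbr] = u
                parent_edge[nbr] = ei
                order.append(nbr)
                stack.append(nbr)
    return adj, root, parent, parent_edge, order


def _down_pass(tree, tips, adj, root, parent, order):
    """Subtree partials D[v] (viewed at v, excluding the parent side)."""
    n = tree.n_nodes
    P = tips[0].shape[0]
    zeros = np.zeros(P)
    down = [None] * n
    dscale = [None] * n
    for u in reversed(order):
        if u < tree.n_taxa:
            down[u] = tips[u]
            dscale[u] = zeros
            continue
        L = None
        sc = zeros
        for nbr, ei in adj[u]:
            if nbr == parent[u]:
                continue
            msg = _branch_message(down[nbr], tree.edges[ei][2])
            L = msg if L is None else L * msg
            sc = sc + dscale[nbr]
        m = L.max(axis=1)
        m[m == 0.0] = 1.0
        down[u] = L / m[:, None]
        dscale[u] = sc + np.log(m)
    return down, dscale


def _root_lnl(down, dscale, root, weights) -> float:
    site = 0.25 * down[root].sum(axis=1)
    return float(weights @ (np.log(site) + dscale[root]))


def _sweep_optimize(tree: PhyloTree, tips, weights, blmin: float, blmax: float,
                    tolerance: float, max_sweeps: int = 20) -> float:
    """Iterative branch-length smoothing: each sweep makes one preorder pass
    optimizing every branch by bounded 1-D likelihood maximization given the
    current values of the others, until the exact lnL improves by less than
    ``tolerance``.  Returns the exact lnL of the final tree."""
    for e in tree.edges:
        e[2] = min(max(e[2], blmin), blmax)
    if tree.n_taxa == 2:
        c1, c2, wconst = _edge_coefficients(
            tips[0], np.zeros(tips[0].shape[0]), tips[1],
            np.zeros(tips[0].shape[0]), weights)
        best_t, lnl = _brent_edge(c1, c2, wconst, weights, blmin, blmax)
        tree.edges[0][2] = best_t
        return lnl
    adj, root, parent, parent_edge, order = _root_structure(tree)
    prev = None
    P = tips[0].shape[0]
    zeros = np.zeros(P)
    for _ in range(max_sweeps):
        down, dscale = _down_pass(tree, tips, adj, root, parent, order)
        lnl = _root_lnl(down, dscale, root, weights)
        if prev is not None and lnl - prev < tolerance:
            return lnl
        prev = lnl
        # up pass: Uat[u] is the partial at u of everything outside u's
        # subtree; each edge (u, child) is optimized when first visited
        uat = [None] * tree.n_nodes
        uscale = [None] * tree.n_nodes
        uat[root] = np.ones((P, 4))
        uscale[root] = zeros
        for u in order:
            children = [(nbr, ei) for nbr, ei in adj[u] if nbr != parent[u]]
            for v, ei in children:
                A = uat[u]
                Asc = uscale[u]
                for w, we in children:
                    if w == v:
                        continue
                    A = A * _branch_message(down[w], tree.edges[we][2])
                    Asc = Asc + dscale[w]
                c1, c2, wconst = _edge_coefficients(A, Asc, down[v], dscale[v], weights)
                best_t, _ = _brent_edge(c1, c2, wconst, weights, blmin, blmax)
                tree.edges[ei][2] = best_t
                if v >= tree.n_taxa:
                    U = _branch_message(A, best_t)
                    m = U.max(axis=1)
                    m[m == 0.0] = 1.0
                    uat[v] = U / m[:, None]
                    uscale[v] = Asc + np.log(m)
    down, dscale = _down_pass(tree, tips, adj, root, parent, order)
    return _root_lnl(down, dscale, root, weights)


def optimize_branch_lengths(aln: Alignment, tree: PhyloTree,
                            config: SearchConfig) -> tuple[PhyloTree, float]:
    """Coordinate-ascent branch-length optimization on a fixed topology.

    Each branch is optimized in turn by bounded 1-D likelihood maximization,
    clamped to ``[blmin, blmax]``; sweeps repeat until the total lnL improves
    by less than ``config.tolerance``.  Returns ``(tree, lnL)`` with the tree
    modified in place.
    """
    sub = aln.subset(tree.taxa)
    patterns, weights = compress_patterns(sub.data)
    tips = _tip_partials(patterns)
    lnl = _sweep_optimize(tree, tips, weights, config.blmin, config.blmax,
                          config.tolerance)
    if not np.isfinite(lnl):
        raise PhylogenyError("non-finite likelihood during branch optimization")
    tree.invalidate()
    return tree, lnl


# ---------------------------------------------------------------------------
# Distances and neighbor joining
# ---------------------------------------------------------------------------

def jc_distance_matrix(data: np.ndarray, blmax: float = 10.0) -> np.ndarray:
    """Pairwise JC-corrected distances, d = -(3/4) ln(1 - 4p/3).

    ``p`` is computed over pairwise complete (non-missing) sites; saturated or
    data-free pairs are assigned ``blmax``.
    """
    t = data.shape[0]
    D = np.zeros((t, t))
    present = data < GAP
    for i in range(t):
        for j in range(i + 1, t):
            both = present[i] & present[j]
            n = int(both.sum())
            if n == 0:
                d = blmax
            else:
                p = float((data[i, both] != data[j, both]).mean())
                if p >= 0.7499:
                    d = blmax
                else:
                    d = -0.75 * math.log1p(-4.0 * p / 3.0)
            D[i, j] = D[j, i] = min(d, blmax)
    return D


def neighbor_joining(taxa: Sequence[str], D: np.ndarray) -> PhyloTree:
    """Classic Saitou-Nei neighbor joining; returns an unrooted binary tree.

    Ties in the Q matrix are broken by smallest (i, j) index pair so the
    result is deterministic.  Negative branch-length estimates are clamped
    to zero (the fit floor is applied later by the optimizer).
    """
    t = len(taxa)
    if t == 2:
        return PhyloTree(taxa, [[0, 1, max(D[0, 1], 0.0)]])
    nodes = list(range(t))
    D = D.astype(float).copy()
    active = list(range(t))
    next_id = t
    edges: list[list[float]] = []
    Dm = {(i, j): D[i, j] for i in range(t) for j in range(t)}

    def dist(a, b):
        return Dm[(a, b)] if (a, b) in Dm else Dm[(b, a)]

    while len(active) > 3:
        n = len(active)
        totals = {a: sum(dist(a, b) for b in active if b != a) for a in active}
        best = None
        for ii in range(n):
            for jj in range(ii + 1, n):
                a, b = active[ii], active[jj]
                q = (n - 2) * dist(a, b) - totals[a] - totals[b]
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (totals[a] - totals[b]) / (2.0 * (n - 2))
        lb = dab - la
        new = next_id
        next_id += 1
        edges.append([new, a, max(la, 0.0)])
        edges.append([new, b, max(lb, 0.0)])
        for c in active:
            if c in (a, b):
                continue
            Dm[(new, c)] = 0.5 * (dist(a, c) + dist(b, c) - dab)
        active = [c for c in active if c not in (a, b)] + [new]
    if len(active) == 3:
        a, b, c = active
        center = next_id
        la = 0.5 * (dist(a, b) + dist(a, c) - dist(b, c))
        lb = 0.5 * (dist(a, b) + dist(b, c) - dist(a, c))
        lc = 0.5 * (dist(a, c) + dist(b, c) - dist(a, b))
        edges.append([center, a, max(la, 0.0)])
        edges.append([center, b, max(lb, 0.0)])
        edges.append([center, c, max(lc, 0.0)])
    else:  # two remaining (t == 2 handled above, so this is t == 3 collapse)
        a, b = active
        edges.append([a, b, max(dist(a, b), 0.0)])
    return PhyloTree(taxa, edges)


# ---------------------------------------------------------------------------
# Topology enumeration and NNI
# ---------------------------------------------------------------------------

def all_unrooted_topologies(taxa: Sequence[str]) -> list[PhyloTree]:
    """Every unrooted binary topology over ``taxa`` (3, 15, 105, ... trees).

    Built by stepwise leaf insertion into every edge; intended for <= 6 taxa.
    """
    t = len(taxa)
    if t < 3:
        raise PhylogenyError("need >= 3 taxa to enumerate topologies")
    base = [[t, 0, 0.1], [t, 1, 0.1], [t, 2, 0.1]]
    trees = [(base, t + 1)]
    for leaf in range(3, t):
        new_trees = []
        for edges, next_id in trees:
            for ei in range(len(edges)):
                e2 = [list(e) for e in edges]
                u, v, l = e2[ei]
                mid = next_id
                e2[ei] = [u, mid, l / 2]
                e2.append([mid, v, l / 2])
                e2.append([mid, leaf, 0.1])
                new_trees.append((e2, next_id + 1))
        trees = new_trees
    return [PhyloTree(taxa, edges) for edges, _ in trees]


def _up_pass(tree, tips, adj, root, parent, order, down, dscale):
    """Outside-subtree partials Uat[v] (viewed at v) for every internal v."""
    P = tips[0].shape[0]
    uat = [None] * tree.n_nodes
    uscale = [None] * tree.n_nodes
    uat[root] = np.ones((P, 4))
    uscale[root] = np.zeros(P)
    for u in order:
        if u < tree.n_taxa:
            continue
        children = [(nbr, ei) for nbr, ei in adj[u] if nbr != parent[u]]
        for v, ei in children:
            if v < tree.n_taxa:
                continue
            A = uat[u]
            Asc = uscale[u]
            for w, we in children:
                if w == v:
                    continue
                A = A * _branch_message(down[w], tree.edges[we][2])
                Asc = Asc + dscale[w]
            U = _branch_message(A, tree.edges[ei][2])
            m = U.max(axis=1)
            m[m == 0.0] = 1.0
            uat[v] = U / m[:, None]
            uscale[v] = Asc + np.log(m)
    return uat, uscale


def _best_nni_move(tree, tips, weights, config):
    """Best NNI rearrangement scored by re-optimizing only the central edge.

    Around an internal edge with subtrees {X1, X2} | {Y1, Y2}, the two
    alternative arrangements {X1, Y1} | {X2, Y2} and {X1, Y2} | {X2, Y1} are
    evaluated with the four outer branch lengths held fixed.  Returns
    ``(gain, swap_edge, with_edge, central_edge, new_length)`` for the best
    move, or None if no internal edge exists.
    """
    adj, root, parent, parent_edge, order = _root_structure(tree)
    down, dscale = _down_pass(tree, tips, adj, root, parent, order)
    uat, uscale = _up_pass(tree, tips, adj, root, parent, order, down, dscale)
    base_lnl = _root_lnl(down, dscale, root, weights)
    best = None
    for ei in tree.internal_edges():
        u, v, central_len = tree.edges[ei]
        if parent[u] == v:  # orient so that v is the child
            u, v = v, u
        # components around the edge, each as (partial at the edge end,
        # scale, message already crossed?) -- parent-side of u is viewed at u
        u_side = []
        for nbr, we in adj[u]:
            if we == ei:
                continue
            if nbr == parent[u]:
                u_side.append((uat[u], uscale[u], None, we))
            else:
                u_side.append((down[nbr], dscale[nbr], tree.edges[we][2], we))
        v_side = []
        for nbr, we in adj[v]:
            if we == ei:
                continue
            v_side.append((down[nbr], dscale[nbr], tree.edges[we][2], we))

        def crossed(comp):
            L, sc, length, _ = comp
            return (L, sc) if length is None else (_branch_message(L, length), sc)

        # the swapped u-side component must be a real subtree edge
        keep, swap = u_side
        if swap[2] is None:
            keep, swap = swap, keep
        Xk, Xks = crossed(keep)
        Xs, Xss = crossed(swap)
        Y = [crossed(c) for c in v_side]
        cur_A = Xk * Xs
        cur_Asc = Xks + Xss
        cur_B = Y[0][0] * Y[1][0]
        cur_Bsc = Y[0][1] + Y[1][1]
        c1, c2, wconst = _edge_coefficients(cur_A, cur_Asc, cur_B, cur_Bsc, weights)
        _, cur_lnl = _brent_edge(c1, c2, wconst, weights, config.blmin, config.blmax)
        for yi in (0, 1):
            A = Xk * Y[yi][0]
            Asc = Xks + Y[yi][1]
            B = Xs * Y[1 - yi][0]
            Bsc = Xss + Y[1 - yi][1]
            c1, c2, wconst = _edge_coefficients(A, Asc, B, Bsc, weights)
            new_len, cand_lnl = _brent_edge(c1, c2, wconst, weights,
                                            config.blmin, config.blmax)
            gain = cand_lnl - cur_lnl
            if best is None or gain > best[0]:
                best = (gain, swap[3], v_side[yi][3], ei, new_len, u, v)
    return best


def _apply_nni(tree: PhyloTree, move) -> None:
    _, swap_edge, with_edge, central_edge, new_len, u, v = move
    for edge_idx, old, new in ((swap_edge, u, v), (with_edge, v, u)):
        edge = tree.edges[edge_idx]
        if edge[0] == old:
            edge[0] = new
        else:
            edge[1] = new
    tree.edges[central_edge][2] = new_len
    tree.invalidate()


def _search_nni(tips, weights, taxa, patterns, config: SearchConfig) -> tuple[PhyloTree, float]:
    # distances must weight compressed patterns by their column counts
    D = _weighted_jc_distances(patterns, weights, config.blmax)
    tree = neighbor_joining(taxa, D)
    lnl = _sweep_optimize(tree, tips, weights, config.blmin, config.blmax,
                          config.tolerance)
    threshold = max(config.tolerance, 1e-9)
    for _ in range(50):  # hill-climb to a local optimum
        move = _best_nni_move(tree, tips, weights, config)
        if move is None or move[0] <= threshold:
            break
        _apply_nni(tree, move)
        lnl = _sweep_optimize(tree, tips, weights, config.blmin, config.blmax,
                              config.tolerance)
    return tree, lnl


def _weighted_jc_distances(patterns: np.ndarray, weights: np.ndarray,
                           blmax: float) -> np.ndarray:
    t = patterns.shape[0]
    D = np.zeros((t, t))
    present = patterns < GAP
    for i in range(t):
        for j in range(i + 1, t):
            both = present[i] & present[j]
            n = float(weights[both].sum())
            if n == 0:
                d = blmax
            else:
                diff = float(weights[both & (patterns[i] != patterns[j])].sum())
                p = diff / n
                d = blmax if p >= 0.7499 else -0.75 * math.log1p(-4.0 * p / 3.0)
            D[i, j] = D[j, i] = min(d, blmax)
    return D


def search_topology(aln: Alignment, config: SearchConfig,
                    interval: Optional[tuple[int, int]] = None) -> WindowFit:
    """ML topology search for one window.

    Taxa without any data in the window are excluded from the fit (the caller
    is expected to have applied an analyzability filter first).  For up to 5
    taxa with data every unrooted topology is optimized exhaustively; for more
    the search starts from a JC-distance neighbor-joining tree and hill-climbs
    with NNI rearrangements.  Exact likelihood ties are broken toward the
    lexicographically smallest canonical topology.
    """
    mask = aln.taxa_with_data()
    taxa = [t for t, m in zip(aln.taxa, mask) if m]
    t = len(taxa)
    if t < 3:
        raise PhylogenyError(
            "window has fewer than 3 taxa with data; filter with is_analyzable first"
        )
    sub = aln.subset(taxa)
    patterns, weights = compress_patterns(sub.data)
    tips = _tip_partials(patterns)
    fit_tree, fit_lnl = _search_patterns(tips, weights, taxa, patterns, config)
    n_unique = int(np.unique(
        np.ascontiguousarray(sub.data).view(
            np.dtype((np.void, sub.data.shape[1]))).ravel()).shape[0])
    iv = interval if interval is not None else (0, aln.length)
    return WindowFit(
        interval=iv,
        tree=fit_tree,
        lnL=fit_lnl,
        k=2 * t - 3,
        n_taxa_with_data=t,
        n_unique_sequences=n_unique,
    )


def _search_patterns(tips, weights, taxa, patterns, config: SearchConfig):
    t = len(taxa)
    strategy = config.strategy
    if strategy == "auto":
        strategy = "exhaustive" if t <= 5 else "nni"
    if t == 3 or strategy == "exhaustive":
        if t == 3:
            candidates = [PhyloTree(taxa, [[3, 0, 0.1], [3, 1, 0.1], [3, 2, 0.1]])]
        else:
            candidates = all_unrooted_topologies(taxa)
        best = None
        for cand in candidates:
            lnl = _sweep_optimize(cand, tips, weights, config.blmin,
                                  config.blmax, config.tolerance)
            key = (-lnl, cand.canonical_topology)
            if best is None or _tie_better(key, best[0], config.tolerance):
                best = (key, cand, lnl)
        return best[1], best[2]
    return _search_nni(tips, weights, taxa, patterns, config)


def _tie_better(key, best_key, tol) -> bool:
    # smaller -lnL wins; within tol, lexicographically smaller canonical id wins
    if key[0] < best_key[0] - tol * 1e-3:
        return True
    if key[0] > best_key[0] + tol * 1e-3:
        return False
    return key[1] < best_key[1]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(aln: Alignment, fit: WindowFit, config: SearchConfig) -> Optional[float]:
    """Mean nonparametric bootstrap support of the fitted tree's internal
    branches, as a percentage in [0, 100].

    Columns are resampled with replacement and the topology search rerun per
    replicate; the support of an internal branch is the percentage of
    replicates whose ML tree contains the same bipartition.  Windows with
    fewer than four unique sequences get no support (``None``), mirroring the
    practice of skipping bootstrapping for such windows.
    """
    if fit.n_unique_sequences < 4 or config.bootstrap_reps == 0:
        return None
    taxa = fit.tree.taxa
    sub = aln.subset(taxa)
    patterns, weights = compress_patterns(sub.data)
    tips = _tip_partials(patterns)
    n_sites = int(round(weights.sum()))
    p = weights / weights.sum()
    target = fit.tree.bipartitions()
    if not target:
        return None
    rng = np.random.default_rng(config.seed)
    counts = {m: 0 for m in target}
    for _ in range(config.bootstrap_reps):
        w = rng.multinomial(n_sites, p).astype(np.float64)
        nz = w > 0
        rep_tree, _ = _search_patterns(
            [L[nz] for L in tips], w[nz], taxa, patterns[:, nz], config)
        found = rep_tree.bipartitions()
        for m in target:
            if m in found:
                counts[m] += 1
    supports = [100.0 * counts[m] / config.bootstrap_reps for m in target]
    return float(np.mean(supports))
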