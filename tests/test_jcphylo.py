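"""Jukes-Cantor engine: pruning likelihood, optimization, search, bootstrap.

The independent oracle for the pruning algorithm is brute-force enumeration
of all internal-node state assignments; the oracle for two-taxon cases is
the closed-form JC pair likelihood.
"""

import itertools
import math

import numpy as np
import pytest

from nowsize.core_io import Alignment, encode_sequence
from nowsize.jcphylo import (
    PhyloTree,
    PhylogenyError,
    SearchConfig,
    all_unrooted_topologies,
    bootstrap_support,
    canonical_topology,
    jc_log_likelihood,
    neighbor_joining,
    optimize_branch_lengths,
    search_topology,
)

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def jc_p(same: bool, t: float) -> float:
    e = math.exp(-4.0 * t / 3.0)
    return 0.25 + 0.75 * e if same else 0.25 - 0.25 * e


def brute_force_lnl_full(tree: PhyloTree, aln: Alignment) -> float:
    """Enumerate all internal AND missing-leaf state assignments per site."""
    data = aln.subset(tree.taxa).data
    t = tree.n_taxa
    internal = sorted({n for e in tree.edges for n in e[:2] if n >= t})
    total = 0.0
    for site in data.T:
        missing = [i for i in range(t) if site[i] >= 4]
        free = internal + missing
        site_lik = 0.0
        for states in itertools.product(range(4), repeat=len(free)):
            assign = dict(zip(free, states))
            prod = 0.25
            for u, v, length in tree.edges:
                su = assign[u] if u in assign else site[u]
                sv = assign[v] if v in assign else site[v]
                prod *= jc_p(su == sv, length)
            site_lik += prod
        total += math.log(site_lik)
    return total


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

class TestLikelihood:
    def test_two_taxon_closed_forms(self):
        tree = PhyloTree(["a", "b"], [[0, 1, 0.1]])
        e = math.exp(-4.0 * 0.1 / 3.0)
        same = Alignment.from_sequences(["a", "b"], ["A", "A"])
        diff = Alignment.from_sequences(["a", "b"], ["A", "C"])
        assert jc_log_likelihood(same, tree) == pytest.approx(
            math.log(0.25 * (0.25 + 0.75 * e)), abs=1e-9)
        assert jc_log_likelihood(diff, tree) == pytest.approx(
            math.log(0.25 * (0.25 - 0.25 * e)), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_pruning_matches_brute_force(self, seed, n_taxa):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(n_taxa)]
        trees = all_unrooted_topologies(taxa)
        tree = trees[rng.integers(len(trees))]
        for e in tree.edges:
            e[2] = float(rng.uniform(0.01, 0.5))
        chars = "ACGT-N"
        seqs = ["".join(rng.choice(list(chars), size=6)) for _ in taxa]
        # ensure at least two taxa have data
        seqs[0] = "ACGTAC"
        seqs[1] = "ACGTAA"
        aln = Alignment.from_sequences(taxa, seqs)
        assert jc_log_likelihood(aln, tree) == pytest.approx(
            brute_force_lnl_full(tree, aln), abs=1e-8)

    def test_all_missing_column_contributes_zero(self, quartet_tree):
        base = Alignment.from_sequences(list("ABCD"), ["ACG", "ACG", "ACT", "AGT"])
        padded = Alignment.from_sequences(
            list("ABCD"), ["ACG-", "ACGN", "ACT-", "AGTN"])
        assert jc_log_likelihood(padded, quartet_tree) == pytest.approx(
            jc_log_likelihood(base, quartet_tree), abs=1e-10)

    def test_invariant_to_leaf_order(self, quartet_tree, quartet_alignment):
        lnl = jc_log_likelihood(quartet_alignment, quartet_tree)
        # same topology expressed with permuted leaf ids
        perm = PhyloTree(
            ["D", "C", "B", "A"],
            [[4, 3, 0.05], [4, 2, 0.05], [5, 1, 0.05], [5, 0, 0.05], [4, 5, 0.2]],
        )
        assert jc_log_likelihood(quartet_alignment, perm) == pytest.approx(lnl, abs=1e-10)

    def test_fewer_than_two_taxa_with_data_rejected(self):
        aln = Alignment.from_sequences(["a", "b"], ["ACGT", "----"])
        tree = PhyloTree(["a", "b"], [[0, 1, 0.1]])
        with pytest.raises(PhylogenyError):
            jc_log_likelihood(aln, tree)

    def test_lnl_nonpositive_for_nonempty_windows(self, quartet_alignment):
        cfg = SearchConfig(blmin=1e-4, seed=1)
        fit = search_topology(quartet_alignment, cfg)
        assert fit.lnL <= 0.0


# ---------------------------------------------------------------------------
# Branch-length optimization
# ---------------------------------------------------------------------------

class TestOptimization:
    def test_identical_sequences_clamp_to_blmin(self):
        aln = Alignment.from_sequences(["a", "b"], ["ACGT" * 50] * 2)
        tree = PhyloTree(["a", "b"], [[0, 1, 0.3]])
        cfg = SearchConfig(blmin=1e-3, seed=1)
        tree, _ = optimize_branch_lengths(aln, tree, cfg)
        assert tree.edges[0][2] == pytest.approx(1e-3, rel=1e-3)

    def test_pairwise_distance_recovery(self):
        # evolve two sequences at path length 0.1 and invert the JC distance
        rng = np.random.default_rng(7)
        n = 100_000
        a = rng.integers(0, 4, size=n, dtype=np.uint8)
        e = math.exp(-4.0 * 0.1 / 3.0)
        hit = rng.random(n) < 0.75 * (1 - e)
        b = a.copy()
        b[hit] = (a[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        from nowsize.core_io import decode_sequence

        aln = Alignment.from_sequences(["a", "b"], [decode_sequence(a), decode_sequence(b)])
        tree = PhyloTree(["a", "b"], [[0, 1, 0.5]])
        cfg = SearchConfig(blmin=1e-6, seed=1)
        tree, _ = optimize_branch_lengths(aln, tree, cfg)
        assert tree.edges[0][2] == pytest.approx(0.1, abs=0.005)

    def test_reoptimization_is_a_fixed_point(self, quartet_alignment, quartet_tree):
        cfg = SearchConfig(blmin=1e-4, tolerance=1e-4, seed=1)
        t1, lnl1 = optimize_branch_lengths(quartet_alignment, quartet_tree.copy(), cfg)
        t2, lnl2 = optimize_branch_lengths(quartet_alignment, t1.copy(), cfg)
        assert abs(lnl2 - lnl1) < 10 * cfg.tolerance

    def test_optimization_never_decreases_lnl(self, quartet_alignment, quartet_tree):
        start = jc_log_likelihood(quartet_alignment, quartet_tree)
        cfg = SearchConfig(blmin=1e-4, seed=1)
        _, lnl = optimize_branch_lengths(quartet_alignment, quartet_tree.copy(), cfg)
        assert lnl >= start - cfg.tolerance

    @pytest.mark.parametrize("blmin_pair", [(1e-4, 1e-2), (1e-3, 1e-1)])
    def test_raising_blmin_never_improves_lnl(self, quartet_alignment, quartet_tree,
                                              blmin_pair):
        lo, hi = blmin_pair
        _, lnl_lo = optimize_branch_lengths(
            quartet_alignment, quartet_tree.copy(), SearchConfig(blmin=lo, seed=1))
        _, lnl_hi = optimize_branch_lengths(
            quartet_alignment, quartet_tree.copy(), SearchConfig(blmin=hi, seed=1))
        assert lnl_hi <= lnl_lo + 1e-6


# ---------------------------------------------------------------------------
# Topology search
# ---------------------------------------------------------------------------

class TestSearch:
    def test_recovers_strong_quartet_signal(self, quartet_alignment, quartet_tree):
        fit = search_topology(quartet_alignment, SearchConfig(blmin=1e-4, seed=1))
        assert fit.topology_id == quartet_tree.canonical_topology
        assert fit.k == 5

    def test_exhaustive_is_its_own_oracle(self, quartet_alignment):
        # the chosen topology must beat the other two in optimized lnL
        cfg = SearchConfig(blmin=1e-4, seed=1)
        fit = search_topology(quartet_alignment, cfg)
        lnls = {}
        for cand in all_unrooted_topologies(list("ABCD")):
            cand, lnl = optimize_branch_lengths(quartet_alignment, cand, cfg)
            lnls[cand.canonical_topology] = lnl
        assert fit.topology_id == max(lnls, key=lnls.get)

    def test_identical_sequences_tie_break_lexicographic(self):
        aln = Alignment.from_sequences(list("ABCD"), ["ACGTACGTAC"] * 4)
        fit = search_topology(aln, SearchConfig(blmin=1e-3, seed=1))
        ids = sorted(t.canonical_topology for t in all_unrooted_topologies(list("ABCD")))
        assert fit.topology_id == ids[0]

    def test_parameter_count_seven_taxa(self, five_taxon_trees):
        from nowsize.coalsim import Locus, TruthMap, simulate_sequences

        taxa = [f"t{i}" for i in range(7)]
        tree = PhyloTree(taxa, [[7, 0, 0.05], [7, 1, 0.05], [8, 2, 0.05],
                                [8, 3, 0.05], [9, 4, 0.05], [9, 5, 0.05],
                                [10, 6, 0.05], [7, 10, 0.05], [8, 10, 0.05],
                                [9, 10, 0.05]])
        truth = TruthMap([Locus(0, 1000, tree, tree.canonical_topology)], 1000)
        aln = simulate_sequences(truth, taxa, seed=3)
        fit = search_topology(aln, SearchConfig(blmin=1e-3, seed=1))
        assert fit.k == 11
        assert fit.n_taxa_with_data == 7

    def test_nni_matches_exhaustive_on_five_taxa(self, five_taxon_trees):
        from nowsize.coalsim import Locus, TruthMap, simulate_sequences

        t1, _ = five_taxon_trees
        hits = 0
        trials = 20
        for i in range(trials):
            truth = TruthMap([Locus(0, 2000, t1, t1.canonical_topology)], 2000)
            aln = simulate_sequences(truth, t1.taxa, seed=100 + i)
            ex = search_topology(aln, SearchConfig(blmin=5e-4, strategy="exhaustive", seed=1))
            nni = search_topology(aln, SearchConfig(blmin=5e-4, strategy="nni", seed=1))
            if ex.topology_id == nni.topology_id:
                hits += 1
        assert hits >= trials - 1

    def test_too_few_taxa_rejected(self):
        aln = Alignment.from_sequences(list("abcd"), ["ACGT", "ACGT", "----", "----"])
        with pytest.raises(PhylogenyError):
            search_topology(aln, SearchConfig(seed=1))

    def test_taxa_without_data_excluded(self):
        aln = Alignment.from_sequences(
            list("abcde"),
            ["ACGTACGTAC", "ACGTACGTAA", "ACGAACGTAC", "AGGTACGAAC", "-" * 10],
        )
        fit = search_topology(aln, SearchConfig(blmin=1e-2, seed=1))
        assert fit.n_taxa_with_data == 4
        assert fit.k == 5
        assert "e" not in fit.tree.taxa


# ---------------------------------------------------------------------------
# Canonical topology
# ---------------------------------------------------------------------------

class TestCanonicalTopology:
    def test_unrooted_equivalence(self):
        a = PhyloTree(list("ABCD"), [[4, 0, 1], [4, 1, 1], [5, 2, 1], [5, 3, 1], [4, 5, 1]])
        b = PhyloTree(list("ABCD"), [[4, 2, 9], [4, 3, 9], [5, 1, 9], [5, 0, 9], [4, 5, 9]])
        assert a.canonical_topology == b.canonical_topology

    def test_distinct_splits_differ(self):
        ab_cd = PhyloTree(list("ABCD"), [[4, 0, 1], [4, 1, 1], [5, 2, 1], [5, 3, 1], [4, 5, 1]])
        ac_bd = PhyloTree(list("ABCD"), [[4, 0, 1], [4, 2, 1], [5, 1, 1], [5, 3, 1], [4, 5, 1]])
        assert ab_cd.canonical_topology != ac_bd.canonical_topology

    def test_exactly_three_quartet_topologies(self):
        ids = {t.canonical_topology for t in all_unrooted_topologies(list("ABCD"))}
        assert len(ids) == 3

    def test_branch_lengths_ignored(self, quartet_tree):
        other = quartet_tree.copy()
        for e in other.edges:
            e[2] *= 7.7
        assert other.canonical_topology == quartet_tree.canonical_topology

    def test_agrees_with_dendropy_rf_distance(self, five_taxon_trees):
        """Cross-check: equal canonical IDs iff unrooted RF distance is 0."""
        import dendropy

        t1, t2 = five_taxon_trees
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=t2.to_newick(), schema="newick", taxon_namespace=tns)
        d1b = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=tns)
        for t in (d1, d2, d1b):
            t.encode_bipartitions()
        rf_12 = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        rf_11 = dendropy.calculate.treecompare.symmetric_difference(d1, d1b)
        assert (t1.canonical_topology == t2.canonical_topology) == (rf_12 == 0)
        assert rf_11 == 0 and t1.canonical_topology == t1.canonical_topology


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

class TestNeighborJoining:
    def test_recovers_additive_distances(self, five_taxon_trees):
        t1, _ = five_taxon_trees
        # additive distance matrix from the tree itself
        n = t1.n_taxa
        D = np.zeros((n, n))
        adj = t1.adjacency()
        for i in range(n):
            # BFS accumulating path lengths
            dist = {i: 0.0}
            stack = [i]
            while stack:
                u = stack.pop()
                for nbr, ei in adj[u]:
                    if nbr not in dist:
                        dist[nbr] = dist[u] + t1.edges[ei][2]
                        stack.append(nbr)
            for j in range(n):
                D[i, j] = dist[j]
        nj = neighbor_joining(t1.taxa, D)
        assert nj.canonical_topology == t1.canonical_topology


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

class TestBootstrap:
    def test_few_unique_sequences_undefined(self):
        aln = Alignment.from_sequences(
            list("abcd"), ["ACGTACGTAC", "ACGTACGTAC", "ACGTACGTAA", "ACGTACGTAA"])
        cfg = SearchConfig(blmin=1e-2, bootstrap_reps=10, seed=1)
        fit = search_topology(aln, cfg)
        assert fit.n_unique_sequences == 2
        assert bootstrap_support(aln, fit, cfg) is None

    def test_zero_reps_undefined(self, quartet_alignment):
        cfg = SearchConfig(blmin=1e-4, bootstrap_reps=0, seed=1)
        fit = search_topology(quartet_alignment, cfg)
        assert bootstrap_support(quartet_alignment, fit, cfg) is None

    def test_clean_signal_near_full_support(self, quartet_alignment):
        cfg = SearchConfig(blmin=1e-4, bootstrap_reps=50, seed=1)
        fit = search_topology(quartet_alignment, cfg)
        support = bootstrap_support(quartet_alignment, fit, cfg)
        assert 90.0 <= support <= 100.0

    def test_support_bounds(self, five_taxon_trees):
        from nowsize.coalsim import Locus, TruthMap, simulate_sequences

        t1, _ = five_taxon_trees
        truth = TruthMap([Locus(0, 300, t1, t1.canonical_topology)], 300)
        aln = simulate_sequences(truth, t1.taxa, seed=11)
        cfg = SearchConfig(blmin=1e-3, bootstrap_reps=30, seed=2)
        fit = search_topology(aln, cfg)
        support = bootstrap_support(aln, fit, cfg)
        if support is not None:
            assert 0.0 <= support <= 100.0
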