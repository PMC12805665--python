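"""Shared fixtures: small alignments and hand-built trees/truth maps."""

from __future__ import annotations

import numpy as np
import pytest

from nowsize.coalsim import Locus, TruthMap, simulate_sequences
from nowsize.core_io import Alignment
from nowsize.jcphylo import PhyloTree


@pytest.fixture
def quartet_tree() -> PhyloTree:
    """4-taxon tree AB|CD with a solid internal branch."""
    return PhyloTree(
        ["A", "B", "C", "D"],
        [[4, 0, 0.05], [4, 1, 0.05], [5, 2, 0.05], [5, 3, 0.05], [4, 5, 0.2]],
    )


@pytest.fixture
def quartet_alignment(quartet_tree) -> Alignment:
    """2 kb alignment simulated on the AB|CD quartet."""
    truth = TruthMap([Locus(0, 2000, quartet_tree, quartet_tree.canonical_topology)], 2000)
    return simulate_sequences(truth, ["A", "B", "C", "D"], seed=5)


def make_truth(segments, taxa=None) -> TruthMap:
    """Build a TruthMap from (length, tree) pairs laid end to end."""
    loci = []
    pos = 0
    for length, tree in segments:
        topo = (tree.canonical_topology if tree.n_taxa >= 3
                else "(" + ",".join(sorted(tree.taxa)) + ");")
        loci.append(Locus(pos, pos + length, tree, topo))
        pos += length
    return TruthMap(loci, pos)


@pytest.fixture
def five_taxon_trees() -> tuple[PhyloTree, PhyloTree]:
    """Two distinct 5-taxon topologies with strong internal branches."""
    taxa = ["A", "B", "C", "D", "E"]
    t1 = PhyloTree(taxa, [[5, 0, 0.06], [5, 1, 0.06], [6, 2, 0.06], [6, 3, 0.06],
                          [7, 4, 0.06], [5, 7, 0.08], [6, 7, 0.08]])
    t2 = PhyloTree(taxa, [[5, 0, 0.06], [5, 2, 0.06], [6, 1, 0.06], [6, 3, 0.06],
                          [7, 4, 0.06], [5, 7, 0.08], [6, 7, 0.08]])
    return t1, t2
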