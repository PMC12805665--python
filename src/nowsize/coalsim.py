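"""Coalescent simulation of gene trees and Jukes-Cantor sequence evolution.

This is the package's synthetic-data generator.  Gene trees are drawn from a
multispecies coalescent with recombination on a dated species tree, with
introgression modeled as instantaneous admixture pulses; sequences are then
evolved locus by locus under Jukes-Cantor and concatenated.  The per-site
truth (which genealogy generated which sites) is retained in a
:class:`TruthMap` so downstream accuracy measures can compare window
estimates against it.

Time conventions
----------------
Species-tree node ages are given in Myr and converted to ms-style coalescent
units (one unit = 4Ne generations) with a conversion factor
``myr_per_coalunit`` (default 0.75, i.e. 4Ne generations correspond to
0.75 Myr).  ``rho`` is the ms-style population-scaled recombination parameter
4Nr over the whole simulated segment.  Branch lengths of the output gene
trees are in substitutions/site: coalescent-unit lengths multiplied by
``mutation_scale``.

The default demography (:func:`heliconius_model`) emulates a 7-taxon
*Heliconius* erato-sara clade chromosome: six ingroup species, one outgroup,
and three bidirectional introgression events.  Dates and admixture fractions
are configuration defaults calibrated so that simulated chromosomes match the
headline characteristics of such data (locus counts under recombination, a
dominant-topology site share near one half, and a low single-digit percentage
of parsimony-informative sites); all of them are exposed as inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import msprime
import numpy as np

from nowsize.core_io import Alignment
from nowsize.jcphylo import PhyloTree, canonical_topology

__all__ = [
    "IntrogressionEvent",
    "SimulationModel",
    "Locus",
    "TruthMap",
    "heliconius_model",
    "HELICONIUS_SPECIES_TREE",
    "ILS_SCALES",
    "myr_to_coalescent",
    "simulate_gene_trees",
    "simulate_sequences",
    "truth_topology_weights",
]


class SimulationConfigError(ValueError):
    pass


def myr_to_coalescent(time_myr: float, myr_per_coalunit: float = 0.75) -> float:
    """Convert a time in Myr to coalescent units (4Ne generations)."""
    if myr_per_coalunit <= 0:
        raise ValueError("myr_per_coalunit must be positive")
    return time_myr / myr_per_coalunit


@dataclass(frozen=True)
class IntrogressionEvent:
    """An instantaneous admixture pulse between two coexisting branches.

    ``donor`` and ``recipient`` name species-tree branches (a leaf label, or
    an internal branch as the '+'-joined sorted labels of its clade).  With
    ``bidirectional=True`` the event is realized as two pulses at the same
    time with the same probability ``gamma``, one in each direction.
    """

    donor: str
    recipient: str
    time_myr: float
    gamma: float
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise SimulationConfigError(f"gamma must be in [0,1], got {self.gamma}")


# Dated species tree for the erato-sara clade plus outgroup (ages in Myr,
# encoded as newick branch lengths).  Node ages: erato/himera 1.7,
# demeter/sara 3.0, +telesiphe 3.5, +hecalesia 3.9, crown 4.5, root 12.5.
HELICONIUS_SPECIES_TREE = (
    "(((erato:1.7,himera:1.7):2.8,"
    "(hecalesia:3.9,(telesiphe:3.5,(demeter:3.0,sara:3.0):0.5):0.4):0.6):8.0,"
    "melpomene:12.5);"
)

# Branch-length multipliers (in coalescent units) defining the ILS levels.
ILS_SCALES = {"low": 1.5, "medium": 1.0, "high": 0.6}

# Internal msprime scaling: haploid populations of this many chromosomes;
# one ms coalescent unit (4Ne generations) = 2 * _HAPLOID_POP generations.
_HAPLOID_POP = 10_000.0
_GENS_PER_UNIT = 2.0 * _HAPLOID_POP

_DEFAULT_INTROGRESSION = (
    IntrogressionEvent("himera", "erato", time_myr=0.4, gamma=0.10),
    IntrogressionEvent("telesiphe", "hecalesia", time_myr=2.0, gamma=0.05,
                       bidirectional=False),
    IntrogressionEvent("telesiphe", "demeter+sara", time_myr=3.35, gamma=0.10),
)


@dataclass
class SimulationModel:
    """Everything needed to simulate one chromosome alignment."""

    species_tree: str = HELICONIUS_SPECIES_TREE
    myr_per_coalunit: float = 0.75
    ils_scale: float = 1.0
    introgression_events: tuple[IntrogressionEvent, ...] = _DEFAULT_INTROGRESSION
    rho: float = 0.0
    total_length: int = 10_000_000
    mutation_scale: float = 0.0075
    seed: int = 1
    # long chromosomes are simulated as independent blocks of this many
    # sites (rho apportioned pro rata); recombination makes distant regions
    # effectively independent anyway, and the full-ARG bookkeeping needed
    # for ms-style locus boundaries is kept to a bounded memory footprint.
    block_length: int = 1_000_000

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise SimulationConfigError("rho must be >= 0")
        if self.total_length < 1:
            raise SimulationConfigError("total_length must be >= 1")
        if self.mutation_scale <= 0:
            raise SimulationConfigError("mutation_scale must be positive")
        if self.ils_scale <= 0:
            raise SimulationConfigError("ils_scale must be positive")


def heliconius_model(rho: float = 0.0, ils: str = "medium", *,
                     total_length: int = 10_000_000, seed: int = 1,
                     introgression: bool = True, **overrides) -> SimulationModel:
    """The default 7-taxon butterfly scenario at a given recombination level.

    ``rho`` is typically one of {0, 20, 200, 2000} for a 10 Mb chromosome;
    ``ils`` selects the branch-length scaling level (low/medium/high).
    ``introgression=False`` drops the three admixture pulses.
    """
    if ils not in ILS_SCALES:
        raise SimulationConfigError(f"unknown ILS level {ils!r}; use {sorted(ILS_SCALES)}")
    events = _DEFAULT_INTROGRESSION if introgression else ()
    return SimulationModel(
        ils_scale=ILS_SCALES[ils],
        introgression_events=events,
        rho=rho,
        total_length=total_length,
        seed=seed,
        **overrides,
    )


@dataclass
class Locus:
    """One non-recombining segment: interval, gene tree, topology ID."""

    start: int
    end: int
    tree: PhyloTree
    topology_id: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class TruthMap:
    """Ordered loci tiling ``[0, total_length)`` exactly."""

    loci: list[Locus]
    total_length: int

    def __post_init__(self) -> None:
        pos = 0
        for loc in self.loci:
            if loc.start != pos or loc.end <= loc.start:
                raise SimulationConfigError("loci must tile the segment without gaps")
            pos = loc.end
        if pos != self.total_length:
            raise SimulationConfigError(
                f"loci end at {pos}, expected total_length {self.total_length}"
            )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def mean_locus_length(self) -> float:
        return self.total_length / self.n_loci

    def merge_same_topology(self) -> "TruthMap":
        """Merged view: adjacent loci sharing a topology become one locus.

        The merged locus keeps the first member's gene tree; use it only for
        topology-level summaries (window-length comparisons), not sequence
        simulation.
        """
        merged: list[Locus] = []
        for loc in self.loci:
            if merged and merged[-1].topology_id == loc.topology_id:
                prev = merged[-1]
                merged[-1] = Locus(prev.start, loc.end, prev.tree, prev.topology_id)
            else:
                merged.append(Locus(loc.start, loc.end, loc.tree, loc.topology_id))
        return TruthMap(merged, self.total_length)

    def topology_intervals(self) -> list[tuple[int, int, str]]:
        return [(l.start, l.end, l.topology_id) for l in self.loci]

    def to_tsv(self, path: str | Path, header_comment: str = "") -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            fh.write("start\tend\ttopology_id\tnewick\n")
            for loc in self.loci:
                fh.write(f"{loc.start}\t{loc.end}\t{loc.topology_id}\t{loc.tree.to_newick()}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthMap":
        loci: list[Locus] = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("start\t"):
                    continue
                start, end, topo, newick = line.rstrip("\n").split("\t")
                tree = PhyloTree.from_newick(newick)
                loci.append(Locus(int(start), int(end), tree, topo))
        return cls(loci, loci[-1].end if loci else 0)


# ---------------------------------------------------------------------------
# Species tree -> msprime demography
# ---------------------------------------------------------------------------

def _parse_species_tree(newick: str, myr_per_coalunit: float, ils_scale: float):
    """Return (taxa, nodes) where nodes is a list of
    (population_name, age_coal, child_population_names) in increasing age."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    ages: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
        else:
            child = node.child_nodes()[0]
            ages[node] = ages[child] + (child.edge.length or 0.0)

    def popname(node) -> str:
        # internal branches are addressable as the '_'-joined sorted labels
        # of their clade (msprime population names must be identifiers)
        if node.is_leaf():
            return node.taxon.label
        leaves = sorted(l.taxon.label for l in node.leaf_iter())
        return "_".join(leaves)

    taxa = sorted(l.taxon.label for l in tree.leaf_node_iter())
    nodes = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        age_coal = myr_to_coalescent(ages[node], myr_per_coalunit) * ils_scale
        children = [popname(c) for c in node.child_nodes()]
        nodes.append((popname(node), age_coal, children))
    nodes.sort(key=lambda x: x[1])
    return taxa, nodes


def _population_lifetimes(taxa, nodes) -> dict[str, tuple[float, float]]:
    """Map population name -> (birth_age, merge_age) in coalescent units."""
    spans: dict[str, tuple[float, float]] = {t: (0.0, np.inf) for t in taxa}
    for name, age, children in nodes:
        spans[name] = (age, np.inf)
    for name, age, children in nodes:
        for ch in children:
            birth, _ = spans[ch]
            spans[ch] = (birth, age)
    return spans


def _build_demography(model: SimulationModel):
    taxa, nodes = _parse_species_tree(
        model.species_tree, model.myr_per_coalunit, model.ils_scale
    )
    spans = _population_lifetimes(taxa, nodes)
    dem = msprime.Demography()
    # Haploid populations of 2N chromosomes: pairwise coalescence at rate
    # 1/(2N) per generation, so one ms coalescent unit (4Ne generations)
    # equals _GENS_PER_UNIT msprime generations.  N is arbitrary (everything
    # is expressed in coalescent units); a comfortably large value avoids
    # the numerical issues tiny population sizes can cause.
    for t in taxa:
        dem.add_population(name=t, initial_size=_HAPLOID_POP)
    for name, age, children in nodes:
        dem.add_population(name=name, initial_size=_HAPLOID_POP)
    events = []
    for name, age, children in nodes:
        events.append(("split", age * _GENS_PER_UNIT, name, children))
    scale = model.ils_scale / model.myr_per_coalunit
    for ev in model.introgression_events:
        t_coal = ev.time_myr * scale
        for direction, (donor, recipient) in enumerate(_pulse_directions(ev)):
            for pop in (donor, recipient):
                if pop not in spans:
                    raise SimulationConfigError(
                        f"introgression event references unknown branch {pop!r}"
                    )
                birth, merge = spans[pop]
                if not (birth <= t_coal < merge):
                    raise SimulationConfigError(
                        f"introgression {donor}->{recipient} at {ev.time_myr} Myr "
                        f"falls outside the lifetime of branch {pop!r}"
                    )
            # the reverse pulse of a bidirectional event is offset by half a
            # generation (2.5e-5 coalescent units) so that no lineage can be
            # moved twice at one instant, which the ARG recorder rejects
            t_gens = t_coal * _GENS_PER_UNIT + 0.5 * direction
            events.append(("pulse", t_gens, donor, recipient, ev.gamma))
    events.sort(key=lambda e: e[1])
    for ev in events:
        if ev[0] == "split":
            _, t_gens, name, children = ev
            dem.add_population_split(time=t_gens, derived=children, ancestral=name)
        else:
            _, t_gens, donor, recipient, gamma = ev
            # backwards in time, lineages in the recipient trace to the donor
            dem.add_mass_migration(time=t_gens, source=recipient, dest=donor,
                                   proportion=gamma)
    dem.sort_events()
    return taxa, dem


def _pulse_directions(ev: IntrogressionEvent):
    donor = ev.donor.replace("+", "_")
    recipient = ev.recipient.replace("+", "_")
    yield donor, recipient
    if ev.bidirectional:
        yield recipient, donor


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_gene_trees(model: SimulationModel) -> TruthMap:
    """Simulate the sequence of marginal genealogies along the chromosome.

    One haploid sample is taken per species.  Returns a :class:`TruthMap`
    whose locus boundaries are the recombination breakpoints that fall in
    material ancestral to the sample -- the segments an ms ``-T`` run prints
    one tree for.  Adjacent loci can therefore carry identical genealogies
    (a recombining lineage that coalesces straight back leaves the marginal
    tree unchanged); :meth:`TruthMap.merge_same_topology` provides the
    merged, topology-only view.  ``rho = 0`` yields exactly one locus.
    Deterministic given ``model.seed``.

    Chromosomes longer than ``model.block_length`` are simulated as
    independent consecutive blocks with ``rho`` apportioned by length (no
    recombination requires no blocking, so ``rho = 0`` still gives a single
    chromosome-spanning locus).
    """
    taxa, dem = _build_demography(model)
    L = model.total_length
    if model.rho == 0 or L <= model.block_length:
        blocks = [(0, L)]
    else:
        starts = list(range(0, L, model.block_length))
        blocks = [(s, min(s + model.block_length, L)) for s in starts]
    loci: list[Locus] = []
    for i, (start, end) in enumerate(blocks):
        block_rho = model.rho * (end - start) / L
        block_loci = _simulate_block(
            model, taxa, dem, end - start, block_rho,
            seed=(model.seed * 1000 + i) % (2**31 - 1) + 1,
        )
        for loc in block_loci:
            loci.append(Locus(loc.start + start, loc.end + start, loc.tree,
                              loc.topology_id))
    return TruthMap(loci, L)


def _simulate_block(model: SimulationModel, taxa, dem, L: int, rho: float,
                    seed: int) -> list[Locus]:
    # rho is 4Nr over the block: per link and per generation this is
    # rho / ((L-1) * _GENS_PER_UNIT) with our haploid scaling
    rate = 0.0 if L <= 1 else rho / ((L - 1) * _GENS_PER_UNIT)
    # record_full_arg keeps every recombination node, so tree intervals match
    # the ms segment semantics rather than only genealogy-changing breakpoints
    ts = msprime.sim_ancestry(
        samples={t: 1 for t in taxa},
        demography=dem,
        sequence_length=L,
        recombination_rate=rate,
        ploidy=1,
        discrete_genome=True,
        record_full_arg=True,
        random_seed=seed,
    )
    # Locus boundaries come from the full ARG, but identical marginal
    # genealogies are converted only once: the simplified tree sequence
    # merges intervals whose tree is unchanged, and each breakpoint interval
    # is then mapped back onto its covering distinct genealogy.
    breaks = [int(b) for b in ts.breakpoints()]
    tsq = ts.simplify()
    sample_taxon = {}
    pop_names = {p.id: p.metadata["name"] for p in tsq.populations()}
    for s in tsq.samples():
        sample_taxon[int(s)] = pop_names[tsq.node(s).population]
    taxon_index = {t: i for i, t in enumerate(taxa)}
    distinct: list[tuple[int, PhyloTree]] = []  # (right end, tree)
    topo_cache: dict[tuple, str] = {}
    for tree in tsq.trees():
        ptree, shape_key = _tskit_to_phylo(
            tree, sample_taxon, taxon_index, taxa, model.mutation_scale
        )
        topo = topo_cache.get(shape_key)
        if topo is None:
            topo = canonical_topology(ptree)
            topo_cache[shape_key] = topo
        ptree._canon = topo
        distinct.append((int(tree.interval.right), ptree))
    loci: list[Locus] = []
    j = 0
    for start, end in zip(breaks[:-1], breaks[1:]):
        if end <= start:
            continue
        while distinct[j][0] <= start:
            j += 1
        ptree = distinct[j][1]
        loci.append(Locus(start, end, ptree, ptree.canonical_topology))
    return loci


def _tskit_to_phylo(tree, sample_taxon, taxon_index, taxa, mutation_scale):
    """Convert one tskit marginal tree to an unrooted PhyloTree.

    Unary nodes (recombination and common-ancestor records of the full ARG)
    are collapsed; the binary root is suppressed.  Returns the tree plus a
    hashable shape key used to cache canonical-topology strings.
    """
    t = len(taxa)
    n_samples = t
    root = None
    for r in tree.roots:
        if tree.num_samples(r) == n_samples:
            root = r
            break
    if root is None:
        raise SimulationConfigError("marginal tree does not connect all samples")
    next_internal = t
    edges: list[list[float]] = []

    def collapse(u: int) -> tuple[int, float]:
        """Resolve ``u`` past unary chains; returns (my node id, node time)."""
        nonlocal next_internal
        children = tree.children(u)
        while len(children) == 1:
            u = children[0]
            children = tree.children(u)
        if tree.is_leaf(u):
            return taxon_index[sample_taxon[u]], tree.time(u)
        me = next_internal
        next_internal += 1
        my_time = tree.time(u)
        for ch in children:
            cid, ctime = collapse(ch)
            length = (my_time - ctime) / _GENS_PER_UNIT * mutation_scale
            edges.append([me, cid, length])
        return me, my_time

    root_id, _ = collapse(root)
    # suppress the binary root to obtain the unrooted tree
    incident = [e for e in edges if e[0] == root_id]
    if len(incident) == 2:
        (_, a, la), (_, b, lb) = incident
        edges = [e for e in edges if e[0] != root_id] + [[a, b, la + lb]]
    shape = tuple(sorted((min(u, v), max(u, v)) for u, v, _ in edges))
    return PhyloTree(taxa, edges), shape


def simulate_sequences(truth: TruthMap, taxa: Sequence[str], seed: int = 1) -> Alignment:
    """Evolve sequences under JC along each locus tree and concatenate.

    Uniform base frequencies, equal exchangeabilities, no rate heterogeneity
    and no indels; each locus evolves independently from a uniform random
    root state.  Branch lengths are read as substitutions/site.  The output
    alignment length equals ``truth.total_length``; deterministic given
    ``seed``.
    """
    taxa = list(taxa)
    rng = np.random.default_rng(seed)
    n = len(taxa)
    out = np.empty((n, truth.total_length), dtype=np.uint8)
    for loc in truth.loci:
        tree = loc.tree
        if sorted(tree.taxa) != sorted(taxa):
            raise SimulationConfigError(
                f"locus [{loc.start},{loc.end}) tree has leaves {tree.taxa}, "
                f"expected {taxa}"
            )
        states = _evolve_jc(tree, loc.length, rng)
        for leaf_idx, taxon in enumerate(tree.taxa):
            out[taxa.index(taxon), loc.start:loc.end] = states[leaf_idx]
    return Alignment(taxa, out)


def _evolve_jc(tree: PhyloTree, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Simulate JC states for every leaf of an unrooted tree."""
    t = tree.n_taxa
    adj = tree.adjacency()
    root = next((node for node in range(t, tree.n_nodes) if adj[node]), 0)
    states = {root: rng.integers(0, 4, size=n_sites, dtype=np.uint8)}
    stack = [(root, -1)]
    leaf_states = np.empty((t, n_sites), dtype=np.uint8)
    if root < t:
        leaf_states[root] = states[root]
    while stack:
        node, parent = stack.pop()
        for nbr, ei in adj[node]:
            if nbr == parent:
                continue
            length = tree.edges[ei][2]
            child = _jc_mutate(states[node], length, rng)
            states[nbr] = child
            if nbr < t:
                leaf_states[nbr] = child
            stack.append((nbr, node))
    return leaf_states


def _jc_mutate(parent: np.ndarray, length: float, rng: np.random.Generator) -> np.ndarray:
    e = np.exp(-4.0 * length / 3.0)
    p_change = 0.75 * (1.0 - e)
    child = parent.copy()
    hit = rng.random(parent.shape[0]) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        child[hit] = (parent[hit] + rng.integers(1, 4, size=n_hit, dtype=np.uint8)) % 4
    return child


def truth_topology_weights(truth: TruthMap) -> dict[str, float]:
    """Fraction of sites carried by each canonical unrooted topology."""
    weights: dict[str, float] = {}
    for loc in truth.loci:
        weights[loc.topology_id] = weights.get(loc.topology_id, 0.0) + loc.length
    total = float(truth.total_length)
    return {k: v / total for k, v in weights.items()}
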