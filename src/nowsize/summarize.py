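"""Topology-distribution summaries and post-processing of window fits.

These are the descriptive statistics applied to the trees from the selected
window size: topology counts and proportions (optionally restricted to
well-supported trees and/or spaced-out windows so that each counted tree is
likely independent), run lengths of consecutive identical topologies, and
per-topology internal-branch and informative-site statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from nowsize.core_io import Alignment
from nowsize.jcphylo import WindowFit

__all__ = [
    "TopologySummary",
    "topology_distribution",
    "run_lengths",
    "internal_branch_stats",
    "parsimony_informative_sites",
]


@dataclass
class TopologySummary:
    counts: dict[str, int]
    proportions: dict[str, float]
    run_lengths: list[int]
    support_min: Optional[float] = None
    spacing: Optional[int] = None

    @property
    def n_windows(self) -> int:
        return sum(self.counts.values())


def _apply_filters(fits: Sequence[WindowFit], support_min: Optional[float],
                   spacing: Optional[int]) -> list[WindowFit]:
    kept = list(fits)
    if support_min is not None:
        # fits without a defined support (e.g. <4 unique sequences) are
        # excluded whenever a support threshold is active
        kept = [f for f in kept if f.mean_support is not None
                and f.mean_support >= support_min]
    if spacing is not None and spacing > 0:
        window = fits[0].interval[1] - fits[0].interval[0] if fits else 1
        spaced: list[WindowFit] = []
        last_start = None
        for f in kept:
            if last_start is None or f.interval[0] - last_start >= spacing * window:
                spaced.append(f)
                last_start = f.interval[0]
        kept = spaced
    return kept


def topology_distribution(fits: Sequence[WindowFit],
                          support_min: Optional[float] = None,
                          spacing: Optional[int] = None) -> TopologySummary:
    """Counts and proportions of canonical topologies over the fits.

    ``support_min`` keeps only fits whose mean bootstrap support reaches the
    threshold (fits with undefined support are dropped).  ``spacing`` then
    greedily keeps a fit only if it starts at least ``spacing`` windows after
    the last kept one, reducing multiple counting of one non-recombining
    block.  Fits must be ordered by genomic position.
    """
    kept = _apply_filters(fits, support_min, spacing)
    counts: dict[str, int] = {}
    for f in kept:
        counts[f.topology_id] = counts.get(f.topology_id, 0) + 1
    total = sum(counts.values())
    proportions = {k: v / total for k, v in counts.items()} if total else {}
    return TopologySummary(
        counts=counts,
        proportions=proportions,
        run_lengths=run_lengths(kept),
        support_min=support_min,
        spacing=spacing,
    )


def run_lengths(fits: Sequence[WindowFit]) -> list[int]:
    """Lengths of maximal runs of consecutive windows with one topology.

    A run is broken by a topology change or by a genomic gap between
    consecutive fits (e.g. windows removed by filtering).
    """
    runs: list[int] = []
    prev: Optional[WindowFit] = None
    for f in fits:
        contiguous = prev is not None and prev.interval[1] == f.interval[0]
        if prev is not None and contiguous and prev.topology_id == f.topology_id:
            runs[-1] += 1
        else:
            runs.append(1)
        prev = f
    return runs


def parsimony_informative_sites(window: Alignment) -> int:
    """Columns with >= 2 distinct bases each present in >= 2 sequences."""
    data = window.data
    counts = np.zeros((4, data.shape[1]), dtype=np.int32)
    for base in range(4):
        counts[base] = (data == base).sum(axis=0)
    informative = (counts >= 2).sum(axis=0) >= 2
    return int(informative.sum())


def internal_branch_stats(fits: Sequence[WindowFit], aln: Alignment,
                          ) -> dict[str, tuple[float, float]]:
    """Per topology: mean sum of internal branch lengths and mean count of
    parsimony-informative sites over that topology's windows."""
    sums: dict[str, list[float]] = {}
    infos: dict[str, list[float]] = {}
    for f in fits:
        topo = f.topology_id
        sums.setdefault(topo, []).append(f.tree.sum_internal_branch_lengths())
        infos.setdefault(topo, []).append(
            float(parsimony_informative_sites(aln.window(*f.interval)))
        )
    return {
        topo: (float(np.mean(sums[topo])), float(np.mean(infos[topo])))
        for topo in sums
    }
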