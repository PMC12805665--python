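"""Non-overlapping window analysis over a grid of window sizes.

For each candidate size the alignment is tiled with equal windows, every
window receives a Jukes-Cantor ML tree (with the branch-length floor
``blmin = 1/window_size``), and the per-window log-likelihoods and parameter
counts are summed so that the sizes can be compared with information
criteria::

    AIC = -2 ln(L) + 2 K
    BIC = -2 ln(L) + K ln(n)

where ln(L) is the total log-likelihood across all windows, K the total
number of free parameters (branch lengths) across all windows, and n the
number of sites across all windows.  Lower is better; the size with the
lowest AIC is selected, with exact ties resolved toward the larger window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

from nowsize.core_io import Alignment, make_windows
from nowsize.jcphylo import SearchConfig, WindowFit, search_topology

__all__ = [
    "ScoreSummary",
    "FitCache",
    "aggregate_scores",
    "fit_windows",
    "now_analysis",
    "select_best_size",
    "summaries_to_tsv",
    "SIM16_SIZES",
    "default_size_grid",
]

# The 16-size grid used for 10 Mb simulation studies (100 bp to the full
# concatenated chromosome).
SIM16_SIZES = (
    100, 200, 500, 1_000, 2_000, 5_000, 10_000, 20_000, 50_000,
    100_000, 200_000, 500_000, 1_000_000, 2_000_000, 5_000_000, 10_000_000,
)


def default_size_grid(alignment_length: int, start: int = 64_000) -> list[int]:
    """Powers-of-two halvings from ``start`` down to 125 bp, plus the full
    length (a concatenated analysis)."""
    sizes = []
    s = start
    while s >= 125 and s <= alignment_length:
        sizes.append(s)
        s //= 2
    if alignment_length not in sizes:
        sizes.append(alignment_length)
    return sorted(sizes)


class WindowAnalyzabilityError(RuntimeError):
    pass


@dataclass
class ScoreSummary:
    """Aggregated information-criterion scores for one window size."""

    window_size: int
    total_lnL: float
    K: int
    n_sites: int
    n_windows: int

    @property
    def AIC(self) -> float:
        return -2.0 * self.total_lnL + 2.0 * self.K

    @property
    def BIC(self) -> float:
        return -2.0 * self.total_lnL + self.K * math.log(self.n_sites)


class FitCache:
    """Memoizes per-window fits keyed by (start, end, blmin).

    The stepwise procedure revisits the same windows at the same floor when
    a window size appears in two consecutive pairwise comparisons.
    """

    def __init__(self) -> None:
        self._store: dict[tuple[int, int, float], WindowFit] = {}

    def get(self, key: tuple[int, int, float]) -> Optional[WindowFit]:
        return self._store.get(key)

    def put(self, key: tuple[int, int, float], fit: WindowFit) -> None:
        self._store[key] = fit

    def __len__(self) -> int:
        return len(self._store)


def aggregate_scores(fits: Sequence[WindowFit], n_sites: int,
                     window_size: Optional[int] = None) -> ScoreSummary:
    """Sum lnL and k over windows and apply the AIC/BIC formulas."""
    if not fits:
        raise ValueError("cannot aggregate an empty fit list")
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    if window_size is None:
        window_size = fits[0].interval[1] - fits[0].interval[0]
    total_lnL = float(sum(f.lnL for f in fits))
    K = int(sum(f.k for f in fits))
    return ScoreSummary(window_size, total_lnL, K, n_sites, len(fits))


def fit_windows(aln: Alignment, intervals: Sequence[tuple[int, int]],
                blmin: float, config: SearchConfig,
                cache: Optional[FitCache] = None) -> list[WindowFit]:
    """ML-fit every interval, honoring the shared fit cache."""
    cfg = config.with_blmin(blmin)
    fits = []
    for start, end in intervals:
        key = (start, end, blmin)
        fit = cache.get(key) if cache is not None else None
        if fit is None:
            fit = search_topology(aln.window(start, end), cfg, interval=(start, end))
            if cache is not None:
                cache.put(key, fit)
        fits.append(fit)
    return fits


def now_analysis(aln: Alignment, sizes: Sequence[int], config: SearchConfig,
                 cache: Optional[FitCache] = None,
                 min_taxa_with_data: int = 3, strict: bool = True,
                 ) -> dict[int, tuple[ScoreSummary, list[WindowFit]]]:
    """Run the non-overlapping window analysis for every size in the grid.

    All sizes analyze the same alignment, so AIC values are directly
    comparable across sizes (up to the dropped trailing remainders).  Any
    window that fails the analyzability rule raises: alignments with missing
    data should go through the stepwise procedure instead, which keeps the
    compared alignments identical by joint filtering.
    """
    sizes = sorted(set(sizes))
    for s in sizes:
        if s > aln.length:
            raise ValueError(f"window size {s} exceeds alignment length {aln.length}")
    if cache is None:
        cache = FitCache()
    results: dict[int, tuple[ScoreSummary, list[WindowFit]]] = {}
    for size in sizes:
        part = make_windows(aln.length, size)
        part.apply_analyzability(aln, min_taxa_with_data, strict=strict)
        if not all(part.analyzable):
            bad = part.analyzable.index(False)
            raise WindowAnalyzabilityError(
                f"window {bad + 1} of size {size} is not analyzable; use the "
                "stepwise procedure for alignments with missing data"
            )
        fits = fit_windows(aln, part.intervals, 1.0 / size, config, cache)
        n_sites = size * part.n_windows
        results[size] = (aggregate_scores(fits, n_sites, size), fits)
    return results


def select_best_size(summaries: dict[int, ScoreSummary] | Sequence[ScoreSummary],
                     criterion: str = "AIC") -> int:
    """Window size with the lowest criterion score; ties go to the larger size."""
    if isinstance(summaries, dict):
        items = list(summaries.values())
    else:
        items = list(summaries)
    if not items:
        raise ValueError("no summaries to select from")
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    best = None
    for s in items:
        score = getattr(s, criterion)
        if best is None or score < best[0] or (score == best[0] and s.window_size > best[1]):
            best = (score, s.window_size)
    return best[1]


def summaries_to_tsv(summaries: dict[int, ScoreSummary], path: str | Path) -> None:
    rows = sorted(summaries.values(), key=lambda s: s.window_size)
    best_aic = min(s.AIC for s in rows)
    with open(path, "w") as fh:
        fh.write("window_size\tn_windows\ttotal_lnL\tK\tn_sites\tAIC\tBIC\tdelta_AIC\n")
        for s in rows:
            fh.write(
                f"{s.window_size}\t{s.n_windows}\t{s.total_lnL:.6f}\t{s.K}\t"
                f"{s.n_sites}\t{s.AIC:.6f}\t{s.BIC:.6f}\t{s.AIC - best_aic:.6f}\n"
            )
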