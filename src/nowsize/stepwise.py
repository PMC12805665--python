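"""Stepwise non-overlapping window procedure for alignments with missing data.

Comparing AIC scores between two window sizes assumes both analyses saw the
same alignment.  Empirical chromosome alignments contain regions where too
few taxa carry data for a likelihood to exist, and the smaller the window the
more such regions surface.  The stepwise procedure therefore compares only
two sizes at a time -- a size and its half -- and removes any large window
whose own fit, or either of its halves' fits, would be impossible, from
*both* sides of the comparison.  The retained site sets at the two sizes are
then identical and their AICs comparable.

The chain starts at a large size (64 kb by default), halves while the
smaller size keeps winning, and stops at the first comparison won by the
larger size (that size is selected) or at the floor (125 bp by default,
which cannot be halved further); if the final comparison still favored the
smaller size the result is flagged as "still declining", meaning the best
size is at most the floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from nowsize.core_io import Alignment, is_analyzable, make_windows
from nowsize.jcphylo import SearchConfig, WindowFit, bootstrap_support
from nowsize.now_scoring import FitCache, aggregate_scores, fit_windows

logger = logging.getLogger(__name__)

__all__ = ["StepwiseStep", "StepwiseResult", "joint_filter", "stepwise_now", "report_chain"]


@dataclass
class StepwiseStep:
    """One pairwise comparison between a window size and its half."""

    size_large: int
    size_small: int
    retained_sites: int
    aic_large: float
    aic_small: float

    @property
    def winner(self) -> int:
        return self.size_large if self.aic_large <= self.aic_small else self.size_small

    @property
    def delta_aic(self) -> float:
        """AIC(small) - AIC(large); positive means the larger size wins."""
        return self.aic_small - self.aic_large


@dataclass
class StepwiseResult:
    steps: list[StepwiseStep]
    best_size: int
    retained_fraction_at_best: float
    fits_at_best: list[WindowFit]
    still_declining: bool = False


def joint_filter(aln: Alignment, size_large: int, size_small: int,
                 min_taxa_with_data: int = 3, strict: bool = True,
                 ) -> tuple[list[tuple[int, int]], list[tuple[int, int]], int]:
    """Windows analyzable at *both* sizes of a halving pair.

    A large window is retained iff it and both of its halves pass the
    analyzability rule; its two halves are then retained on the small side,
    so the retained site sets at the two sizes are identical by construction.
    Returns ``(windows_large, windows_small, retained_sites)``.
    """
    if size_large != 2 * size_small:
        raise ValueError("size_large must be exactly twice size_small")
    if size_large > aln.length:
        raise ValueError(f"window size {size_large} exceeds alignment length")
    part = make_windows(aln.length, size_large)
    large: list[tuple[int, int]] = []
    small: list[tuple[int, int]] = []
    for start, end in part.intervals:
        mid = start + size_small
        ok = (
            is_analyzable(aln.window(start, end), min_taxa_with_data, strict=strict)
            and is_analyzable(aln.window(start, mid), min_taxa_with_data, strict=strict)
            and is_analyzable(aln.window(mid, end), min_taxa_with_data, strict=strict)
        )
        if ok:
            large.append((start, end))
            small.append((start, mid))
            small.append((mid, end))
    return large, small, len(large) * size_large


def stepwise_now(aln: Alignment, start_size: int, floor_size: int,
                 config: SearchConfig, min_taxa_with_data: int = 3,
                 strict: bool = True, full_chain: bool = False,
                 support: bool = False,
                 cache: Optional[FitCache] = None) -> StepwiseResult:
    """Run the pairwise-halving chain and select the best window size.

    At each step the pair ``(w, w/2)`` is compared on jointly filtered
    windows with ``blmin = 1/w`` and ``1/(w/2)`` respectively.  By default
    the chain descends while the smaller size keeps improving the AIC and
    stops at the first comparison the larger size wins; ``full_chain=True``
    records every comparison down to the floor (the selected size is the
    same) for reporting.  ``support=True`` adds bootstrap support to the
    fits at the selected size.
    """
    if start_size > aln.length:
        raise ValueError("start_size exceeds alignment length")
    if floor_size < 1:
        raise ValueError("floor_size must be >= 1")
    w = start_size
    if _chain_misses_floor(start_size, floor_size):
        logger.warning(
            "start_size %d is not a power-of-two multiple of floor_size %d; "
            "the chain will stop once halving passes below the floor",
            start_size, floor_size,
        )
    if cache is None:
        cache = FitCache()
    steps: list[StepwiseStep] = []
    best_size: Optional[int] = None
    best_fits: list[WindowFit] = []
    best_retained = 0
    still_declining = False
    while w // 2 >= floor_size:
        half = w // 2
        large, small, retained = joint_filter(
            aln, w, half, min_taxa_with_data, strict=strict
        )
        if retained == 0:
            logger.warning("no window analyzable at both %d and %d; chain stops", w, half)
            break
        fits_large = fit_windows(aln, large, 1.0 / w, config, cache)
        fits_small = fit_windows(aln, small, 1.0 / half, config, cache)
        aic_large = aggregate_scores(fits_large, retained, w).AIC
        aic_small = aggregate_scores(fits_small, retained, half).AIC
        step = StepwiseStep(w, half, retained, aic_large, aic_small)
        steps.append(step)
        if step.winner == w:
            if best_size is None:
                best_size, best_fits, best_retained = w, fits_large, retained
            if not full_chain:
                break
        else:
            if best_size is None and half // 2 < floor_size:
                # reached the floor with the AIC still declining
                best_size, best_fits, best_retained = half, fits_small, retained
                still_declining = True
        w = half
    if best_size is None:
        # no comparison could be made at all: keep the start size
        part = make_windows(aln.length, start_size)
        keep = [
            iv for iv in part.intervals
            if is_analyzable(aln.window(*iv), min_taxa_with_data, strict=strict)
        ]
        best_size = start_size
        best_fits = fit_windows(aln, keep, 1.0 / start_size, config, cache)
        best_retained = len(keep) * start_size
    if support:
        for fit in best_fits:
            fit.mean_support = bootstrap_support(
                aln.window(*fit.interval), fit, config.with_blmin(1.0 / best_size)
            )
    return StepwiseResult(
        steps=steps,
        best_size=best_size,
        retained_fraction_at_best=best_retained / aln.length,
        fits_at_best=best_fits,
        still_declining=still_declining,
    )


def _chain_misses_floor(start_size: int, floor_size: int) -> bool:
    w = start_size
    while w > floor_size:
        w //= 2
    return w != floor_size


def report_chain(result: StepwiseResult) -> pd.DataFrame:
    """Per-step table of the halving chain plus the selection summary."""
    rows = []
    for step in result.steps:
        rows.append({
            "size_large": step.size_large,
            "size_small": step.size_small,
            "retained_sites": step.retained_sites,
            "AIC_large": step.aic_large,
            "AIC_small": step.aic_small,
            "delta_AIC": step.delta_aic,
            "winner": step.winner,
        })
    df = pd.DataFrame(rows)
    df.attrs["best_size"] = result.best_size
    df.attrs["retained_fraction_at_best"] = result.retained_fraction_at_best
    df.attrs["still_declining"] = result.still_declining
    return df
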