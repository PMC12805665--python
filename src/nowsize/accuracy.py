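"""Accuracy of a window analysis against simulated truth.

Two measures are used.  *Site accuracy* is the percentage of alignment sites
whose covering window was assigned the same unrooted topology that the site
was simulated from::

    site accuracy = (sites with correct topology) / (total sites) * 100

*RMSE* compares the simulated (predicted, P) and estimated (observed, O)
topology-weight distributions over the union of topologies appearing in
either::

    RMSE = sqrt( sum_i (P_i - O_i)^2 / n ),   n = |union|

Observed weights are site-weighted by default (each window contributes its
size in sites); a window-counted variant is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from nowsize.coalsim import TruthMap, truth_topology_weights
from nowsize.jcphylo import WindowFit
from nowsize.now_scoring import ScoreSummary, select_best_size

__all__ = [
    "AccuracyReport",
    "site_accuracy",
    "rmse",
    "observed_topology_weights",
    "accuracy_report",
    "criterion_loss",
]


@dataclass
class AccuracyReport:
    window_size: int
    site_accuracy: float
    rmse: float
    predicted_weights: dict[str, float]
    observed_weights: dict[str, float]

    @property
    def n_topologies(self) -> int:
        return len(set(self.predicted_weights) | set(self.observed_weights))


def site_accuracy(truth: TruthMap, fits: Sequence[WindowFit],
                  denominator: str = "full") -> float:
    """Percent of sites whose window topology matches the simulated truth.

    An interval sweep over the truth loci and the (sorted, disjoint) fitted
    windows counts matching sites.  With ``denominator="full"`` every site of
    the simulated chromosome counts, so sites in a dropped trailing remainder
    (or any uncovered region) are scored as incorrect -- appropriate for
    plain non-overlapping window runs.  With ``denominator="covered"`` only
    sites inside fitted windows count, appropriate for stepwise runs where
    jointly filtered regions were excluded from the analysis by design.
    """
    if denominator not in ("full", "covered"):
        raise ValueError("denominator must be 'full' or 'covered'")
    fits = sorted(fits, key=lambda f: f.interval[0])
    covered = 0
    correct = 0
    loci = truth.loci
    li = 0
    for fit in fits:
        w_start, w_end = fit.interval
        if w_end > truth.total_length:
            raise ValueError("fitted windows extend beyond the truth map")
        covered += w_end - w_start
        topo = fit.topology_id
        # advance to the first locus overlapping this window
        while li > 0 and loci[li].start > w_start:
            li -= 1
        while loci[li].end <= w_start:
            li += 1
        j = li
        while j < len(loci) and loci[j].start < w_end:
            loc = loci[j]
            if loc.topology_id == topo:
                correct += min(loc.end, w_end) - max(loc.start, w_start)
            j += 1
    denom = truth.total_length if denominator == "full" else covered
    if denom == 0:
        raise ValueError("no sites to score")
    return 100.0 * correct / denom


def rmse(P: dict[str, float], O: dict[str, float]) -> float:
    """Root mean squared error between two topology-weight distributions.

    The index set is the union of topologies present in either distribution;
    topologies absent from one side contribute weight 0 there.
    """
    union = set(P) | set(O)
    if not union:
        raise ValueError("cannot compute RMSE over an empty topology set")
    sq = sum((P.get(t, 0.0) - O.get(t, 0.0)) ** 2 for t in union)
    return math.sqrt(sq / len(union))


def observed_topology_weights(fits: Sequence[WindowFit],
                              mode: str = "site") -> dict[str, float]:
    """Topology-weight distribution of a window analysis.

    ``mode="site"`` weights each window by its length in sites (comparable
    to the site-weighted truth); ``mode="window"`` counts windows.
    """
    if mode not in ("site", "window"):
        raise ValueError("mode must be 'site' or 'window'")
    weights: dict[str, float] = {}
    for fit in fits:
        w = (fit.interval[1] - fit.interval[0]) if mode == "site" else 1.0
        weights[fit.topology_id] = weights.get(fit.topology_id, 0.0) + w
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


def accuracy_report(truth: TruthMap, fits: Sequence[WindowFit],
                    window_size: Optional[int] = None,
                    denominator: str = "full",
                    weight_mode: str = "site") -> AccuracyReport:
    """Site accuracy plus RMSE of one window size against the truth."""
    if window_size is None:
        window_size = fits[0].interval[1] - fits[0].interval[0]
    P = truth_topology_weights(truth)
    O = observed_topology_weights(fits, weight_mode)
    return AccuracyReport(
        window_size=window_size,
        site_accuracy=site_accuracy(truth, fits, denominator),
        rmse=rmse(P, O),
        predicted_weights=P,
        observed_weights=O,
    )


def criterion_loss(reports: dict[int, AccuracyReport],
                   summaries: dict[int, ScoreSummary],
                   criterion: str = "AIC") -> tuple[float, float]:
    """Accuracy sacrificed by trusting a criterion to pick the window size.

    Returns ``(site_accuracy_loss, rmse_gain)``: the gap between the best
    site accuracy on the grid and the accuracy at the criterion-selected
    size, and the corresponding excess RMSE.  Both are >= 0 by construction.
    """
    if set(reports) != set(summaries):
        raise ValueError("reports and summaries must cover the same size grid")
    selected = select_best_size(summaries, criterion)
    best_acc = max(r.site_accuracy for r in reports.values())
    min_rmse = min(r.rmse for r in reports.values())
    loss = best_acc - reports[selected].site_accuracy
    gain = reports[selected].rmse - min_rmse
    return loss, gain
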