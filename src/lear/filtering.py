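"""Off-target and low-detection filtering of trace tables.

Off-target localizations (probes bound at the wrong genomic site, or spots
mis-assigned to a trace) sit implausibly far from their genomic neighbors.
The screening metric is the *minimum distance to a neighboring locus*: for
every localization, the Euclidean distance to the nearest localized genomic
neighbor (previous/next locus in genomic order, skipping missing loci up to
a gap of two positions), taking the smaller of the two sides.  Spots whose
metric exceeds a threshold — by default the 0.995 quantile of the pooled
metric — are marked missing.  A separate filter drops traces whose
detection efficiency (#localized loci / L) falls below a cutoff (the
multi-way contact analyses use >= 0.95).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trace_io import TraceSet

__all__ = [
    "FilterReport",
    "min_neighbor_distance",
    "filter_off_target",
    "filter_by_detection",
]


@dataclass
class FilterReport:
    n_localizations_in: int
    n_removed: int
    reason: str  # off_target | low_detection
    threshold: float | None = None
    min_neighbor_dist: np.ndarray | None = None  # (N, L), NaN = undefined
    detection_efficiency: np.ndarray | None = None  # per trace
    n_traces_in: int | None = None
    n_traces_out: int | None = None
    removed_index: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_retained(self) -> int:
        return self.n_localizations_in - self.n_removed


def min_neighbor_distance(ts: TraceSet, max_gap: int = 2) -> np.ndarray:
    """Per-localization minimum Euclidean distance to a genomic neighbor.

    Returns an (N, L) array in nm; ``NaN`` marks missing localizations and
    localizations with no localized neighbor within ``max_gap`` genomic
    positions (the metric is undefined there, they are never removed).
    Repeat-imaged loci use the genomic neighbors of their initial partner.
    """
    P = ts.positions
    n, L, _ = P.shape
    loc = ts.localized
    roles = ts.locus_table["role"].to_numpy()
    init = np.flatnonzero(roles == "initial")
    order = {ell: k for k, ell in enumerate(init)}  # genomic rank among initial loci

    # neighbor indices (in locus space) for each locus, per side
    def side_candidates(ell: int, direction: int) -> list[int]:
        if roles[ell] == "initial":
            rank = order[ell]
        else:
            partner = next((a for a, r in ts.repeat_pairs if r == ell), None)
            if partner is None:
                return []
            rank = order[partner]
        out = []
        for g in range(1, max_gap + 1):
            k = rank + direction * g
            if 0 <= k < init.size:
                out.append(int(init[k]))
        return out

    metric = np.full((n, L), np.nan)
    for ell in range(L):
        prev_c = side_candidates(ell, -1)
        next_c = side_candidates(ell, +1)
        here = loc[:, ell]
        best = np.full(n, np.inf)
        for cands in (prev_c, next_c):
            side = np.full(n, np.nan)
            taken = np.zeros(n, dtype=bool)
            for c in cands:  # nearest localized candidate wins; farther ones skipped
                use = loc[:, c] & ~taken
                if use.any():
                    d = np.linalg.norm(P[use, ell, :] - P[use, c, :], axis=1)
                    side[use] = d
                    taken |= use
            best = np.fmin(best, np.where(np.isnan(side), np.inf, side))
        defined = here & np.isfinite(best)
        metric[defined, ell] = best[defined]
    return metric


def filter_off_target(
    ts: TraceSet,
    threshold: float | None = None,
    quantile: float = 0.995,
    force: bool = False,
    max_gap: int = 2,
) -> tuple[TraceSet, FilterReport]:
    """Mark localizations with implausibly large neighbor distances missing.

    Parameters
    ----------
    threshold : absolute cutoff in nm; if None, the ``quantile`` of the
        pooled metric is used (default 0.995 — the tail the screening plots
        single out).
    force : allow removing more than 20% of localizations (guard against a
        mis-set unit or threshold).
    """
    if threshold is None:
        if not (0.9 < quantile < 1.0):
            raise ValueError("quantile must lie in (0.9, 1)")
    elif threshold <= 0:
        raise ValueError("threshold must be positive")

    metric = min_neighbor_distance(ts, max_gap=max_gap)
    pooled = metric[np.isfinite(metric)]
    thr = float(np.quantile(pooled, quantile)) if threshold is None else float(threshold)

    remove = np.isfinite(metric) & (metric > thr)
    n_in = int(ts.localized.sum())
    n_rm = int(remove.sum())
    if n_in and n_rm / n_in > 0.20 and not force:
        raise ValueError(
            f"threshold {thr:.1f} nm would remove {n_rm}/{n_in} localizations "
            "(> 20%); pass force=True if intentional"
        )
    pos = ts.positions.copy()
    pos[remove] = np.nan
    report = FilterReport(
        n_localizations_in=n_in,
        n_removed=n_rm,
        reason="off_target",
        threshold=thr,
        min_neighbor_dist=metric,
        removed_index=np.argwhere(remove),
    )
    return ts.with_positions(pos), report


def filter_by_detection(ts: TraceSet, min_eff: float) -> tuple[TraceSet, FilterReport]:
    """Drop traces whose detection efficiency is below ``min_eff`` (keep >=)."""
    if not (0.0 < min_eff <= 1.0):
        raise ValueError("min_eff must lie in (0, 1]")
    eff = ts.detection_efficiency()
    keep = eff >= min_eff
    if not keep.any():
        raise ValueError(
            f"no trace reaches detection efficiency {min_eff}; lower min_eff"
        )
    out = ts.subset_traces(np.flatnonzero(keep))
    report = FilterReport(
        n_localizations_in=int(ts.localized.sum()),
        n_removed=int(ts.localized[~keep].sum()),
        reason="low_detection",
        detection_efficiency=eff,
        n_traces_in=ts.n_traces,
        n_traces_out=int(keep.sum()),
        removed_index=np.flatnonzero(~keep),
    )
    if report.n_traces_out == 0:
        warnings.warn("all traces dropped")
    return out, report
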