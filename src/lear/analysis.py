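"""Contact-frequency maps, multi-way contact statistics and error metrics.

*Contact frequency* is the proportion of traces in which two (or k) loci
are all mutually within a distance threshold — 150 nm and 200 nm are the
conventional choices for kilobase-scale tracing data.  Multi-way (k-way)
frequencies are compared against the expectation under independence of the
pairwise contact events (the product of all C(k,2) pairwise frequencies);
excess over that baseline quantifies cooperativity.  k-way tuples are only
reported when every pair of the tuple has at least 1000 co-localized
traces.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .trace_io import TraceSet

__all__ = [
    "ContactMap",
    "MultiwayTable",
    "contact_frequency",
    "multiway_contact_frequency",
    "expected_independent_multiway",
    "contact_map_difference",
    "relative_error_per_locus",
    "relative_error_per_trace",
]


@dataclass
class ContactMap:
    """Pairwise contact frequencies with a data-sufficiency mask.

    ``freq`` is (L, L), symmetric, NaN on the diagonal and wherever the
    co-localized count falls below ``min_n`` (those entries are also True
    in ``mask``).
    """

    freq: np.ndarray
    counts: np.ndarray
    threshold: float
    min_n: int

    @property
    def mask(self) -> np.ndarray:
        return ~np.isfinite(self.freq)


@dataclass
class MultiwayTable:
    """k-way contact statistics per locus tuple.

    ``observed[t]`` is the fraction of fully localized traces where all
    pairwise distances within tuple ``tuples[t]`` are <= threshold;
    ``expected[t]`` is the independence baseline from the pairwise map.
    ``usable`` requires every pairwise co-localized count >= min_pair_n.
    """

    k: int
    tuples: np.ndarray  # (T, k) locus indices
    observed: np.ndarray
    expected: np.ndarray
    n_complete: np.ndarray  # traces with all k loci localized
    min_pair_count: np.ndarray
    usable: np.ndarray
    threshold: float
    min_pair_n: int


def _pairwise_contacts(ts: TraceSet, threshold: float):
    """Boolean (N, L, L) contact tensor and (L, L) co-localized counts."""
    P = ts.positions
    N, L, _ = P.shape
    loc = ts.localized
    contact = np.zeros((N, L, L), dtype=bool)
    counts = np.zeros((L, L), dtype=np.int64)
    for a in range(L):
        d = np.linalg.norm(P[:, [a], :] - P, axis=2)  # (N, L)
        both = loc[:, [a]] & loc
        contact[:, a, :] = both & (d <= threshold)
        counts[a] = both.sum(axis=0)
    return contact, counts


def contact_frequency(ts: TraceSet, threshold: float, min_n: int = 50) -> ContactMap:
    """Pairwise contact frequency at a distance threshold (nm).

    The denominator of each pair is the number of traces with both loci
    localized; pairs below ``min_n`` such traces are masked.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    contact, counts = _pairwise_contacts(ts, threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = contact.sum(axis=0) / counts
    freq[counts < min_n] = np.nan
    np.fill_diagonal(freq, np.nan)
    return ContactMap(freq, counts, float(threshold), min_n)


def multiway_contact_frequency(
    ts: TraceSet,
    k: int,
    threshold: float,
    min_pair_n: int = 1000,
    tuples=None,
) -> MultiwayTable:
    """k-way contact frequencies (k in {3, 4}) with independence baseline.

    A trace counts as a k-way contact when all C(k,2) pairwise distances
    are <= threshold; the denominator is the number of traces with all k
    loci localized.  Tuples where any pair has fewer than ``min_pair_n``
    co-localized traces are flagged unusable.
    """
    if k not in (3, 4):
        raise ValueError("only 3- and 4-way contacts are supported")
    L = ts.n_loci
    contact, counts = _pairwise_contacts(ts, threshold)
    loc = ts.localized
    if tuples is None:
        tuples = np.array(list(itertools.combinations(range(L), k)), dtype=int)
    else:
        tuples = np.asarray(tuples, dtype=int)

    # pairwise frequencies for the independence baseline (unmasked counts)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pair_freq = contact.sum(axis=0) / counts

    if k == 3 and len(tuples) > 2000:
        return _multiway3_fast(tuples, contact, counts, loc, pair_freq,
                               float(threshold), min_pair_n)

    T = len(tuples)
    observed = np.full(T, np.nan)
    expected = np.full(T, np.nan)
    n_complete = np.zeros(T, dtype=np.int64)
    min_pair = np.zeros(T, dtype=np.int64)
    for t, tup in enumerate(tuples):
        pairs = list(itertools.combinations(tup, 2))
        all_loc = np.all(loc[:, tup], axis=1)
        n_complete[t] = int(all_loc.sum())
        hit = all_loc.copy()
        for a, b in pairs:
            hit &= contact[:, a, b]
        if n_complete[t] > 0:
            observed[t] = hit.sum() / n_complete[t]
        min_pair[t] = min(counts[a, b] for a, b in pairs)
        expected[t] = float(np.prod([pair_freq[a, b] for a, b in pairs]))
    usable = min_pair >= min_pair_n
    return MultiwayTable(k, tuples, observed, expected, n_complete, min_pair,
                         usable, float(threshold), min_pair_n)


def _multiway3_fast(tuples, contact, counts, loc, pair_freq, threshold, min_pair_n):
    """Vectorized 3-way statistics over all (i, j, m) tuples."""
    L = contact.shape[1]
    hit3 = np.zeros((L, L, L), dtype=np.int64)
    n3 = np.zeros((L, L, L), dtype=np.int64)
    for i in range(L):
        for j in range(i + 1, L):
            both = contact[:, i, j]
            hit3[i, j] = (contact[:, i, :] & contact[:, j, :] & both[:, None]).sum(axis=0)
            n3[i, j] = ((loc[:, i] & loc[:, j])[:, None] & loc).sum(axis=0)
    ii, jj, mm = tuples[:, 0], tuples[:, 1], tuples[:, 2]
    n_complete = n3[ii, jj, mm]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        observed = np.where(n_complete > 0, hit3[ii, jj, mm] / np.maximum(n_complete, 1), np.nan)
    expected = pair_freq[ii, jj] * pair_freq[ii, mm] * pair_freq[jj, mm]
    min_pair = np.minimum(np.minimum(counts[ii, jj], counts[ii, mm]), counts[jj, mm])
    usable = min_pair >= min_pair_n
    return MultiwayTable(3, tuples, observed, expected, n_complete, min_pair,
                         usable, threshold, min_pair_n)


def expected_independent_multiway(cm: ContactMap, k: int, tuples=None) -> tuple[np.ndarray, np.ndarray]:
    """Independence-expected k-way frequencies from a pairwise map.

    Returns ``(tuples, expected)`` where expected is the product of the
    C(k,2) pairwise frequencies of each tuple; NaN where any pair of the
    tuple is masked in the map.
    """
    if k not in (3, 4):
        raise ValueError("only 3- and 4-way contacts are supported")
    L = cm.freq.shape[0]
    if tuples is None:
        tuples = np.array(list(itertools.combinations(range(L), k)), dtype=int)
    else:
        tuples = np.asarray(tuples, dtype=int)
    expected = np.empty(len(tuples))
    for t, tup in enumerate(tuples):
        expected[t] = float(np.prod([cm.freq[a, b] for a, b in itertools.combinations(tup, 2)]))
    return tuples, expected


def contact_map_difference(cm1: ContactMap, cm2: ContactMap) -> np.ndarray:
    """Elementwise cm1 - cm2; NaN wherever either map is masked."""
    if cm1.freq.shape != cm2.freq.shape:
        raise ValueError("contact maps cover different loci")
    if cm1.threshold != cm2.threshold:
        raise ValueError("contact maps use different thresholds")
    return cm1.freq - cm2.freq


def _distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-localization Euclidean distances, (N, L); NaN where undefined."""
    return np.linalg.norm(a - b, axis=2)


def relative_error_per_locus(A: TraceSet, O: TraceSet, T: TraceSet) -> np.ndarray:
    """Per-locus relative localization error after correction.

    For each locus: mean ||A - T|| over traces divided by mean ||O - T||.
    Values below 1 mean the correction moved localizations closer to the
    truth on average; identity corrections give exactly 1.
    """
    da = _distances(A.positions, T.positions)
    do = _distances(O.positions, T.positions)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(da, axis=0) / np.nanmean(do, axis=0)


def relative_error_per_trace(A: TraceSet, O: TraceSet, T: TraceSet, eps: float = 1e-6) -> np.ndarray:
    """Per-trace mean of the per-locus error ratios ||A-T|| / ||O-T||.

    Loci where the pre-correction error is below ``eps`` nm are skipped;
    traces with no remaining term are NaN (with a warning).
    """
    da = _distances(A.positions, T.positions)
    do = _distances(O.positions, T.positions)
    ratio = np.where(do >= eps, da / np.where(do >= eps, do, 1.0), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(ratio, axis=1)
    if np.isnan(out).any():
        warnings.warn("some traces had no usable error ratio (all terms skipped)")
    return out
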