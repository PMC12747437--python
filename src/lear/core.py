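"""The LEAR correction: goal variances, likelihood, stochastic descent.

The observed coordinate of locus α in trace i is ``O_i^α = T_i^α + ε_i^α``
with independent localization errors ε.  For any partner locus β the
displacement variance decomposes as::

    Var(O^α - O^β) = Var(T^α - O^β) + Var(ε^α)

so, given an estimate of ``Var(ε^α)``, the *goal variance*
``μ_{α,β} ≈ Var(T^α - O^β)`` is the empirical displacement variance minus
the error variance.  A candidate adjustment ``A^α = O^α + C^α`` is scored
by how probable its achieved variances are under the sampling distribution
of a variance (normal by the CLT, with a distribution-free standard error
``σ_{α,β} = sqrt((m₄ - m₂²)/n)`` from the sample central moments):

    log l[A^α] = Σ_β log N( Var(A^α - O^β) | μ_{α,β}, σ_{α,β} )

Each locus and each imaging dimension is corrected independently (runs
share no state, so the loop parallelizes trivially); maximization uses a
greedy stochastic descent over per-trace shift proposals.  The likelihood
is translation-invariant, so the per-locus mean of the corrections is
subtracted (zero-mean gauge), preserving ensemble centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._descent import descent_kernel
from .error_model import ErrorModel
from .trace_io import TraceSet

__all__ = [
    "GoalVarianceTable",
    "OptimizerConfig",
    "compute_goal_variances",
    "goal_variance_logdensity",
    "locus_log_likelihood",
    "optimize_locus",
    "run_lear",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GoalVarianceTable:
    """Goal-variance statistics for every ordered locus pair, one dimension.

    All arrays are (L, L), indexed [α, β]:

    n        co-localized trace count
    var      empirical Var(O^α - O^β), ddof=1, nm²
    mu       goal mean μ_{α,β} = max(var - σ_α², floor), nm²
    sigma    CLT uncertainty σ_{α,β}, nm²
    usable   n >= min_n and β != α
    """

    dim: int
    n: np.ndarray
    var: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    usable: np.ndarray
    min_n: int
    floor: float


@dataclass
class OptimizerConfig:
    """Tuning knobs of the stochastic descent; all runs are seed-determined.

    proposal_scale is a fraction of the locus error STD σ_α and is annealed
    geometrically each sweep; convergence is declared when the mean accepted
    |Δ log-likelihood| per visited localization falls below ``tol``.
    """

    seed: int = 0
    sweeps: int = 200
    proposal_scale: float = 0.5
    anneal: float = 0.95
    min_n: int = 50
    floor: float = 1.0  # variance floor, nm²
    rounds: int = 1
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if min(self.sweeps, self.proposal_scale, self.anneal, self.min_n,
               self.floor, self.rounds, self.tol) <= 0:
            raise ValueError("all optimizer parameters must be positive")


def compute_goal_variances(
    ts: TraceSet,
    em: ErrorModel,
    dim: int,
    min_n: int = 50,
    floor: float = 1.0,
    positions: np.ndarray | None = None,
) -> GoalVarianceTable:
    """Empirical displacement variances and goal statistics for one dimension.

    Statistics are pairwise-complete: a trace contributes to pair (α, β)
    only if both loci are localized in it.  Goal means falling below the
    variance floor (error estimate exceeding the empirical variance) are
    floored with a warning; uncertainties are floored at ``floor / 10``.
    """
    X = (ts.positions if positions is None else positions)[:, :, dim]
    L = X.shape[1]
    if em.sigma.shape[0] != L:
        raise ValueError("error model does not cover all loci")
    finite = np.isfinite(X)
    n = np.zeros((L, L))
    var = np.full((L, L), np.nan)
    mu = np.full((L, L), np.nan)
    se = np.full((L, L), np.nan)
    for a in range(L):
        diffs = np.where(finite[:, [a]] & finite, X[:, [a]] - X, np.nan)
        cnt = np.isfinite(diffs).sum(axis=0).astype(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m = np.nanmean(diffs, axis=0)
            c = diffs - m
            m2 = np.nanmean(c * c, axis=0)
            m4 = np.nanmean(c ** 4, axis=0)
        ok = cnt >= 2
        v = np.where(ok, m2 * cnt / np.maximum(cnt - 1.0, 1.0), np.nan)
        n[a] = cnt
        var[a] = v
        g = v - em.sigma[a, dim] ** 2
        mu[a] = np.maximum(g, floor)
        se[a] = np.sqrt(np.maximum((m4 - m2 ** 2) / np.maximum(cnt, 1.0), (floor / 10.0) ** 2))
    usable = (n >= max(min_n, 2)) & ~np.eye(L, dtype=bool)
    if np.any(usable & (var - em.sigma[:, [dim]] ** 2 < floor)):
        warnings.warn(
            "some goal variances fell below the variance floor (error estimate "
            "exceeds the empirical displacement variance); floored"
        )
    return GoalVarianceTable(dim, n, var, mu, se, usable, min_n, floor)


def goal_variance_logdensity(v, mu, sigma):
    """Log normal density of an achieved variance at (μ, σ); all in nm²."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be > 0")
    z = (np.asarray(v, dtype=float) - np.asarray(mu, dtype=float)) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


def _pairwise_var(a_col: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Var(a_col - X[:, β]) per column, pairwise-complete, ddof=1."""
    diffs = a_col[:, None] - X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cnt = np.isfinite(diffs).sum(axis=0)
        m = np.nanmean(diffs, axis=0)
        m2 = np.nanmean((diffs - m) ** 2, axis=0)
    return m2 * cnt / np.maximum(cnt - 1.0, 1.0)


def locus_log_likelihood(
    alpha: int,
    a_col: np.ndarray,
    ts: TraceSet,
    gvt: GoalVarianceTable,
) -> float:
    """Goal-variance log-likelihood of an adjusted column for locus α.

    Partner positions are the *observed* ones; the sum runs over usable
    partners β only.
    """
    use = np.flatnonzero(gvt.usable[alpha])
    if use.size == 0:
        raise ValueError(f"locus {alpha} has no usable partner")
    X = ts.positions[:, :, gvt.dim]
    v = _pairwise_var(np.asarray(a_col, dtype=float), X[:, use])
    return float(np.sum(goal_variance_logdensity(v, gvt.mu[alpha, use], gvt.sigma[alpha, use])))


def _rng_for(seed: int, dim: int, alpha: int, round_: int) -> np.random.Generator:
    """Independent, reproducible stream per (locus, dim, round)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), round_, dim, alpha]))


def optimize_locus(
    alpha: int,
    ts: TraceSet,
    gvt: GoalVarianceTable,
    cfg: OptimizerConfig,
    sigma_alpha: float,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Stochastic descent on the corrections of a single locus, one dimension.

    Per sweep, localized traces are visited in seeded random order; each
    visit proposes ``C_i += δ`` with ``δ ~ Normal(0, proposal_scale · σ_α)``
    (annealed) and accepts only strict likelihood improvements, so the
    likelihood trace never decreases.  Returns the zero-mean correction
    column and a diagnostics dict with the per-sweep log-likelihood.
    """
    use = np.flatnonzero(gvt.usable[alpha])
    if use.size == 0:
        raise ValueError(f"locus {alpha} has no usable partner")
    X = ts.positions[:, :, gvt.dim]
    o_col = X[:, alpha]
    visit = np.flatnonzero(np.isfinite(o_col))
    if visit.size == 0:
        return np.zeros_like(o_col), {"loglik": np.array([]), "sweeps": 0,
                                      "initial_loglik": np.nan, "final_loglik": np.nan}
    if rng is None:
        rng = _rng_for(cfg.seed, gvt.dim, alpha, 0)

    scale0 = cfg.proposal_scale * max(float(sigma_alpha), np.sqrt(cfg.floor))
    # anneal geometrically but keep a floor so late sweeps can still polish
    scales = np.maximum(scale0 * cfg.anneal ** np.arange(cfg.sweeps), 1e-4 * scale0)
    order = np.empty((cfg.sweeps, visit.size), dtype=np.int64)
    for s in range(cfg.sweeps):
        order[s] = rng.permutation(visit)
    props = rng.standard_normal((cfg.sweeps, visit.size))

    cur = o_col.copy()
    obs = np.ascontiguousarray(X[:, use])
    valid = np.isfinite(o_col)[:, None] & np.isfinite(obs)
    neg_q, used = descent_kernel(
        cur, obs, valid, gvt.mu[alpha, use].copy(), gvt.sigma[alpha, use].copy(),
        order, props, scales, cfg.tol,
    )
    c = np.where(np.isfinite(o_col), cur - o_col, 0.0)
    c[visit] -= c[visit].mean()  # translation gauge: likelihood is shift-invariant

    const = float(np.sum(-np.log(gvt.sigma[alpha, use]) - 0.5 * _LOG_2PI))
    logl = neg_q[: used + 1] + const
    if np.any(np.diff(logl) < 0):  # acceptance rule forbids this
        raise AssertionError("likelihood decreased during descent")
    if used == cfg.sweeps and -(neg_q[used] - neg_q[used - 1]) > cfg.tol * visit.size:
        warnings.warn(f"locus {alpha} dim {gvt.dim}: sweep cap reached before convergence")
    return c, {"loglik": logl, "sweeps": used, "initial_loglik": logl[0], "final_loglik": logl[-1]}


def run_lear(
    ts: TraceSet,
    em: ErrorModel,
    cfg: OptimizerConfig | None = None,
) -> tuple[TraceSet, dict]:
    """Apply the correction to every locus and dimension of a trace set.

    Goal variances are computed from the original observed data; each
    (locus, dimension) optimization is independent with its own RNG stream
    derived from ``cfg.seed``, so serial and parallel execution agree
    bit-for-bit.  Optional extra rounds (``cfg.rounds > 1``, off by default)
    recompute goal variances against the previously adjusted partners.
    Loci without a usable partner pass through unadjusted.

    Returns the adjusted trace set (``A = O + C``) and a diagnostics dict.
    """
    if cfg is None:
        cfg = OptimizerConfig()
    L, D = ts.n_loci, ts.n_dims
    if em.sigma.shape != (L, D):
        raise ValueError(f"error model shape {em.sigma.shape} does not cover ({L}, {D})")
    positions = ts.positions
    corrections = np.zeros_like(positions)
    diagnostics: dict = {"per_locus": {}, "skipped": [], "goal_gaps": {}}

    for round_ in range(cfg.rounds):
        base = positions if round_ == 0 else positions + corrections
        new_c = np.zeros_like(positions)
        for d in range(D):
            gvt = compute_goal_variances(ts, em, d, cfg.min_n, cfg.floor, positions=base)
            for alpha in range(L):
                if not gvt.usable[alpha].any():
                    if round_ == 0:
                        diagnostics["skipped"].append((alpha, d))
                        warnings.warn(f"locus {alpha} dim {d}: no usable partner, passed through")
                    continue
                rng = _rng_for(cfg.seed, d, alpha, round_)
                c, info = optimize_locus(alpha, ts.with_positions(base), gvt,
                                         cfg, em.sigma[alpha, d], rng=rng)
                new_c[:, alpha, d] = c
                diagnostics["per_locus"][(alpha, d, round_)] = info
            # achieved-vs-goal gaps for this round/dim
            adj = base[:, :, d] + new_c[:, :, d]
            gaps = np.full((L, L), np.nan)
            for alpha in range(L):
                use = np.flatnonzero(gvt.usable[alpha])
                if use.size:
                    v = _pairwise_var(adj[:, alpha], base[:, use, d])
                    gaps[alpha, use] = (v - gvt.mu[alpha, use]) / gvt.sigma[alpha, use]
            diagnostics["goal_gaps"][(d, round_)] = gaps
        corrections = (base + new_c) - positions

    adjusted = ts.with_positions(positions + corrections)
    diagnostics["corrections"] = corrections
    return adjusted, diagnostics
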