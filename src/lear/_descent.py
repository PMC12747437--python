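"""Numba kernel for the stochastic-descent maximization of the goal-variance
likelihood of a single locus.

The likelihood of an adjusted column ``A^α`` is a product of normal densities
over partner loci β, each evaluated at the pairwise-complete sample variance
``Var(A^α - O^β)``.  Shifting one trace's coordinate by δ changes every
partner variance through its running sums only, so a proposal is scored in
O(#partners) without touching the data matrix:

    S1' = S1 + δ,   S2' = S2 + 2 d δ + δ²,   Var' = (S2' - S1'²/n) / (n - 1)

where ``d`` is the trace's current difference to that partner.  Because the
normalization constants of the densities do not depend on ``A^α``, the
acceptance test only compares the quadratic terms ½((Var-μ)/σ)².
"""

import numpy as np
from numba import njit


@njit(cache=True)
def descent_kernel(cur, obs, valid, mu, sig, order, props, scales, tol):
    """Greedy stochastic descent on one locus column, one dimension.

    Parameters
    ----------
    cur : (N,) float64 — adjusted coordinates, modified in place (entries for
        traces never visited are left untouched).
    obs : (N, K) float64 — observed coordinates of the K usable partners.
    valid : (N, K) bool — trace co-localized with partner.
    mu, sig : (K,) — goal-variance means and uncertainties (nm²).
    order : (S, M) int64 — trace visit order per sweep.
    props : (S, M) float64 — unit-normal proposal draws.
    scales : (S,) float64 — proposal STD per sweep (annealed outside).
    tol : float — stop when the mean accepted |Δ quadratic| per visit falls
        below this.

    Returns
    -------
    neg_q : (S+1,) float64 — -Σ_b ½((Var_b-μ_b)/σ_b)² before each sweep and
        after the last one (log-likelihood up to an additive constant);
        entries past the sweep actually reached are NaN.
    sweeps_used : int
    """
    N, K = obs.shape
    nb = np.zeros(K)
    S1 = np.zeros(K)
    S2 = np.zeros(K)
    for b in range(K):
        for i in range(N):
            if valid[i, b]:
                d = cur[i] - obs[i, b]
                nb[b] += 1.0
                S1[b] += d
                S2[b] += d * d
    q = np.empty(K)
    total_q = 0.0
    for b in range(K):
        v = (S2[b] - S1[b] * S1[b] / nb[b]) / (nb[b] - 1.0)
        z = (v - mu[b]) / sig[b]
        q[b] = 0.5 * z * z
        total_q += q[b]

    n_sweeps, M = order.shape
    neg_q = np.full(n_sweeps + 1, np.nan)
    neg_q[0] = -total_q
    used = 0
    # Quiet (below-tol) sweeps only count once the proposal scale has annealed
    # to its floor: at large scales rejection-only sweeps are common even far
    # from the optimum, because proposals overshoot the acceptance window.
    floor_scale = scales[n_sweeps - 1] * 1.001
    quiet = 0
    for s in range(n_sweeps):
        acc_abs = 0.0
        scale = scales[s]
        for t in range(M):
            i = order[s, t]
            delta = props[s, t] * scale
            dq = 0.0
            for b in range(K):
                if valid[i, b]:
                    dold = cur[i] - obs[i, b]
                    s1n = S1[b] + delta
                    s2n = S2[b] + 2.0 * dold * delta + delta * delta
                    vn = (s2n - s1n * s1n / nb[b]) / (nb[b] - 1.0)
                    z = (vn - mu[b]) / sig[b]
                    dq += 0.5 * z * z - q[b]
            if dq < 0.0:  # strict improvement; ties keep the incumbent
                for b in range(K):
                    if valid[i, b]:
                        dold = cur[i] - obs[i, b]
                        S1[b] += delta
                        S2[b] += 2.0 * dold * delta + delta * delta
                        v = (S2[b] - S1[b] * S1[b] / nb[b]) / (nb[b] - 1.0)
                        z = (v - mu[b]) / sig[b]
                        q[b] = 0.5 * z * z
                cur[i] += delta
                total_q += dq
                acc_abs -= dq
        used = s + 1
        neg_q[used] = -total_q
        if acc_abs / M < tol and scale <= floor_scale:
            quiet += 1
            if quiet >= 5:
                break
        else:
            quiet = 0
    return neg_q, used
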