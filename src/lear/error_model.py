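"""Estimation of per-locus, per-dimension localization-error STDs.

The localization error of locus ``ℓ`` is the standard deviation of its
observed spots about the true positions, ``STD(ε^ℓ)``.  Two estimation
routes are provided:

* **Repeat imaging** — when the same genomic segment is imaged twice in the
  same cells, the displacement between the initial (``a``) and repeat
  (``r``) copies removes the (shared) true position and constrains the sum
  of the two error variances, while comparison against third loci
  constrains their difference::

      Var(O^a - O^r)                                  = Var(ε^a) + Var(ε^r)
      mean_β [ Var(O^a - O^β) - Var(O^r - O^β) ]      = Var(ε^a) - Var(ε^r)

  Solving the two moment equations per pair and dimension yields both
  error variances.  Repeat rounds commonly have *larger* error than the
  initial round, so the two are never pooled.

* **Worst-case bound** — without repeats, ``Var(O^α - O^β) >= Var(ε^α) +
  Var(ε^β)`` for every pair, so half the smallest displacement variance
  over genomically adjacent pairs bounds the (homogeneous) error variance
  from above.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .trace_io import TraceSet

__all__ = ["ErrorModel", "estimate_error_from_repeats", "worst_case_error_bound"]


@dataclass
class ErrorModel:
    """Per-locus, per-dimension localization-error STDs in nm.

    ``sigma`` has shape ``(L, D)``.  ``round_means`` holds the per-dimension
    mean STD across repeat pairs for the initial and the repeat imaging
    round (only for repeat-based estimates).
    """

    sigma: np.ndarray
    provenance: str  # estimated_repeats | worst_case_bound | user_supplied
    round_means: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 2:
            raise ValueError("sigma must be (L, D)")
        if not np.isfinite(self.sigma).all() or (self.sigma < 0).any():
            raise ValueError("sigma must be finite and >= 0")

    @classmethod
    def uniform(cls, n_loci: int, sigma_per_dim, provenance: str = "user_supplied") -> "ErrorModel":
        """A shared per-dimension sigma for every locus."""
        s = np.atleast_1d(np.asarray(sigma_per_dim, dtype=float))
        return cls(np.tile(s, (n_loci, 1)), provenance)

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "sigma_nm": {str(i): list(map(float, row)) for i, row in enumerate(self.sigma)},
            "round_means": {k: list(map(float, v)) for k, v in self.round_means.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ErrorModel":
        with open(path) as fh:
            payload = json.load(fh)
        keys = sorted(payload["sigma_nm"], key=int)
        sigma = np.array([payload["sigma_nm"][k] for k in keys], dtype=float)
        em = cls(sigma, payload["provenance"])
        em.round_means = {k: np.array(v) for k, v in payload.get("round_means", {}).items()}
        return em


def _pair_variance(x: np.ndarray, y: np.ndarray, min_n: int):
    """Sample variance (ddof=1) of x - y over traces where both are present."""
    d = x - y
    d = d[np.isfinite(d)]
    if d.size < max(min_n, 2):
        return None, d.size
    return float(np.var(d, ddof=1)), d.size


def estimate_error_from_repeats(ts: TraceSet, min_n: int = 50) -> ErrorModel:
    """Solve the repeat-imaging moment system for each pair and dimension.

    Negative variance solutions (possible at small samples) are clamped to
    zero with a warning.  Loci that were not repeat-imaged receive the mean
    initial-round sigma of their dimension.

    Parameters
    ----------
    ts : TraceSet with non-empty ``repeat_pairs``.
    min_n : minimum co-localized trace count per variance (default 50);
        data-poor pairs/partners are excluded.
    """
    if not ts.repeat_pairs:
        raise ValueError(
            "no repeat-imaged locus pairs; use worst_case_error_bound() or a "
            "user-supplied ErrorModel"
        )
    L, D = ts.n_loci, ts.n_dims
    roles = ts.locus_table["role"].to_numpy()
    sigma = np.full((L, D), np.nan)
    init_sigmas: list[np.ndarray] = []
    rep_sigmas: list[np.ndarray] = []

    for a, r in ts.repeat_pairs:
        pair_ok = True
        s_init = np.full(D, np.nan)
        s_rep = np.full(D, np.nan)
        for d in range(D):
            xa = ts.positions[:, a, d]
            xr = ts.positions[:, r, d]
            s_ar, n_ar = _pair_variance(xa, xr, min_n)
            if s_ar is None:
                warnings.warn(
                    f"repeat pair ({a}, {r}) skipped: only {n_ar} co-localized traces"
                )
                pair_ok = False
                break
            diffs = []
            for b in range(L):
                if b in (a, r) or roles[b] != "initial":
                    continue
                va, _ = _pair_variance(xa, ts.positions[:, b, d], min_n)
                vr, _ = _pair_variance(xr, ts.positions[:, b, d], min_n)
                if va is not None and vr is not None:
                    diffs.append(va - vr)
            delta = float(np.mean(diffs)) if diffs else 0.0
            var_init = (s_ar + delta) / 2.0
            var_rep = (s_ar - delta) / 2.0
            if var_init < 0 or var_rep < 0:
                warnings.warn(
                    f"negative error-variance solution for pair ({a}, {r}) dim {d}; clamped to 0"
                )
            s_init[d] = np.sqrt(max(var_init, 0.0))
            s_rep[d] = np.sqrt(max(var_rep, 0.0))
        if pair_ok:
            sigma[a] = s_init
            sigma[r] = s_rep
            init_sigmas.append(s_init)
            rep_sigmas.append(s_rep)

    if not init_sigmas:
        raise ValueError("no repeat pair had sufficient co-localized traces")
    mean_init = np.mean(init_sigmas, axis=0)
    mean_rep = np.mean(rep_sigmas, axis=0)
    # loci without their own estimate share the round mean of their role
    for ell in range(L):
        if np.isnan(sigma[ell]).any():
            sigma[ell] = mean_rep if roles[ell] == "repeat" else mean_init
    em = ErrorModel(sigma, "estimated_repeats")
    em.round_means = {"initial": mean_init, "repeat": mean_rep}
    return em


def worst_case_error_bound(ts: TraceSet, min_n: int = 50) -> ErrorModel:
    """Upper bound on a homogeneous localization-error STD, per dimension.

    ``sigma_max**2 = min over genomically adjacent initial pairs (α, β) of
    Var(O^α - O^β) / 2`` — valid because the displacement variance always
    contains both error variances on top of the true separation variance.
    The bound is tight only when adjacent loci nearly coincide; otherwise it
    overestimates.
    """
    init = np.flatnonzero((ts.locus_table["role"] == "initial").to_numpy())
    if init.size < 2:
        raise ValueError("need at least two initially imaged loci")
    D = ts.n_dims
    best = np.full(D, np.inf)
    for d in range(D):
        for j in range(init.size - 1):
            a, b = init[j], init[j + 1]
            v, _ = _pair_variance(ts.positions[:, a, d], ts.positions[:, b, d], min_n)
            if v is not None:
                best[d] = min(best[d], v / 2.0)
    if not np.isfinite(best).all():
        raise ValueError(
            f"no adjacent locus pair with >= {min_n} co-localized traces in every dimension"
        )
    sigma = np.tile(np.sqrt(best), (ts.n_loci, 1))
    return ErrorModel(sigma, "worst_case_bound")
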