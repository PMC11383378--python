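"""Pooled bootstrap test for a difference of means.

Given samples A (size n) and B (size m), the observed statistic is
Δµ = |mean(A) − mean(B)|. The null hypothesis that both were drawn from a
common distribution is represented by the pooled sample A ∪ B. Each replicate
draws two pseudo-samples A* and B*, each of size min(n, m), independently and
with replacement from the pool, and computes Δµ* = |mean(A*) − mean(B*)|. The
p-value is the fraction of replicates with Δµ* strictly greater than Δµ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BootstrapResult", "bootstrap_mean_test", "significance_level"]

#: Significance thresholds, strictest last.
SIG_THRESHOLDS = (0.05, 0.01, 0.0001)


@dataclass(frozen=True)
class BootstrapResult:
    """Outcome of a pooled bootstrap mean-difference test."""

    delta_mu: float
    n_boot: int
    p_value: float
    null_quantiles: dict[str, float]
    seed: int | None
    sig_level: float | None
    n: int
    m: int
    smoothed: bool = False

    @property
    def significant(self) -> bool:
        return self.sig_level is not None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value out of [0, 1]")
        if self.delta_mu < 0:
            raise ValueError("delta_mu must be nonnegative")


def significance_level(p: float) -> float | None:
    """Strictest threshold in {0.05, 0.01, 0.0001} with p strictly below it.

    Returns ``None`` when p >= 0.05.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    level = None
    for thr in SIG_THRESHOLDS:
        if p < thr:
            level = thr
    return level


def bootstrap_mean_test(
    a,
    b,
    n_boot: int = 10_000,
    seed: int | None = None,
    smoothed: bool = False,
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Pooled bootstrap test of mean(A) vs mean(B).

    Parameters
    ----------
    a, b
        Nonempty 1-d numeric samples; NaNs are dropped.
    n_boot
        Number of bootstrap replicates (default 10,000).
    seed
        Seed for the replicate draws; ignored when ``rng`` is given.
    smoothed
        If True, report the add-one smoothed p-value (k+1)/(n_boot+1) instead
        of the raw strict-exceedance fraction.
    rng
        Optional generator to draw from (for seed fan-out in pipelines).

    Notes
    -----
    The pooled sample is sorted before resampling, so the test is exactly
    symmetric in its arguments: ``bootstrap_mean_test(a, b, seed=s)`` and
    ``bootstrap_mean_test(b, a, seed=s)`` return identical p-values.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("A and B must be nonempty")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")

    delta = abs(float(a.mean()) - float(b.mean()))
    pool = np.sort(np.concatenate([a, b]))
    if pool[-1] == pool[0]:
        warnings.warn(
            "zero-variance pooled sample: every bootstrap replicate is "
            "degenerate and p = 0 by the strict-exceedance rule",
            RuntimeWarning,
            stacklevel=2,
        )
    k = min(a.size, b.size)
    if rng is None:
        rng = np.random.default_rng(seed)

    d_star = np.empty(n_boot)
    # chunk the replicate draws to bound memory for large samples
    chunk = max(1, min(n_boot, int(4e6) // max(1, 2 * k)))
    for lo in range(0, n_boot, chunk):
        hi = min(lo + chunk, n_boot)
        ia = rng.integers(0, pool.size, size=(hi - lo, k))
        ib = rng.integers(0, pool.size, size=(hi - lo, k))
        d_star[lo:hi] = np.abs(pool[ia].mean(axis=1) - pool[ib].mean(axis=1))

    exceed = int((d_star > delta).sum())
    p = (exceed + 1) / (n_boot + 1) if smoothed else exceed / n_boot
    qs = (0.5, 0.9, 0.95, 0.99)
    quantiles = {f"q{q:g}": float(v) for q, v in zip(qs, np.quantile(d_star, qs))}
    return BootstrapResult(
        delta_mu=delta,
        n_boot=int(n_boot),
        p_value=float(p),
        null_quantiles=quantiles,
        seed=seed,
        sig_level=significance_level(float(p)),
        n=int(a.size),
        m=int(b.size),
        smoothed=smoothed,
    )
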