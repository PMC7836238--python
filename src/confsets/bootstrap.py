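"""Wild t-bootstrap of the supremum statistic on the estimated boundary.

Each replicate multiplies the N standardized residual values at every
boundary point by i.i.d. Rademacher signs, studentizes by the per-point
standard deviation of the signed values, and records the supremum of the
absolute approximating field over the boundary.  The critical value k is
the (1 - alpha) nearest-rank percentile of the B suprema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["CriticalValue", "wild_t_bootstrap", "percentile"]


@dataclass(frozen=True)
class CriticalValue:
    """Bootstrap critical value and the supremum distribution behind it."""

    k: float
    alpha: float
    n_boot: int
    sup_distribution: np.ndarray = field(repr=False)
    seed: object = None


def percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank upper percentile: the ceil(q*B)-th smallest value."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty value list")
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    rank = math.ceil(q * values.size)  # 1-based
    return float(np.sort(values)[rank - 1])


def wild_t_bootstrap(
    boundary_residuals: np.ndarray,
    n_boot: int,
    alpha: float,
    rng: np.random.Generator | int | None = None,
    batch_size: int = 2000,
) -> CriticalValue:
    """Bootstrap the sup of the approximating field over boundary points.

    Parameters
    ----------
    boundary_residuals
        (N, P) standardized residual values at the P boundary points.
    n_boot
        Number of bootstrap replicates B; must allow the requested
        percentile (B >= 1/alpha).
    alpha
        Significance level in (0, 1); k is the (1 - alpha) percentile.
    rng
        Seeded generator (or seed). Replicate signs are drawn
        replicate-major so results are reproducible regardless of batching.

    Notes
    -----
    With Rademacher signs ``s`` the per-point second moment of ``s_i R_i``
    equals the second moment of ``R_i``, so the studentizer reduces to
    ``sigma*^2 = (sum_i R_i^2 - N m^2) / (N - 1)`` with ``m`` the signed
    mean -- computed without materializing the signed residuals.
    """
    r = np.asarray(boundary_residuals, dtype=np.float64)
    if r.ndim != 2:
        raise ValueError("boundary_residuals must be (n_subjects, n_points)")
    n, p = r.shape
    if p == 0:
        raise ValueError(
            "empty boundary: no interpolated boundary points; the confidence "
            "sets are degenerate (handled by compute_confidence_sets)"
        )
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_boot < 1 or n_boot < 1.0 / alpha:
        raise ValueError(
            f"n_boot={n_boot} too small for the (1-alpha) percentile at alpha={alpha}"
        )
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    sum_sq = (r**2).sum(axis=0)  # (P,), invariant under sign flips
    # all Rademacher signs drawn up front, replicate-major: the sign stream
    # is independent of the batch size used below
    all_signs = gen.integers(0, 2, size=(n_boot, n), dtype=np.int8)
    sups = np.empty(n_boot)
    for start in range(0, n_boot, batch_size):
        nb = min(batch_size, n_boot - start)
        signs = all_signs[start : start + nb].astype(np.float64) * 2.0 - 1.0
        m = signs @ r / n  # (nb, P) signed means
        var = (sum_sq - n * m**2) / (n - 1)
        np.maximum(var, 0.0, out=var)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.sqrt(n) * m / np.sqrt(var)
        sups[start : start + nb] = np.abs(g).max(axis=1)
    if not np.all(np.isfinite(sups)):
        raise FloatingPointError(
            "non-finite bootstrap suprema (zero bootstrap sd at a boundary point)"
        )
    k = percentile(sups, 1.0 - alpha)
    return CriticalValue(
        k=k, alpha=float(alpha), n_boot=int(n_boot), sup_distribution=sups, seed=rng
    )
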