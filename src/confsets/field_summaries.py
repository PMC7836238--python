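"""Pointwise estimators and small-sample constants for Cohen's d fields.

For a one-sample design with Gaussian errors, the scaled estimator
``sqrt(N) * dhat`` at a voxel follows a noncentral t distribution with N-1
degrees of freedom and noncentrality ``sqrt(N) * d``.  Two consequences
drive everything in this module:

* **Bias.**  ``E[dhat] = C_N * d`` with ``C_N > 1``, so the plug-in estimate
  overshoots the true effect; :func:`bias_factor` provides the exact
  gamma-function constant and its classical ``(1 - 3/(4N-5))^{-1}``
  approximation, used to bias-correct thresholds downstream.
* **Skew and variance growth.**  ``Var(dhat)`` grows with ``d`` and the
  distribution is right-skewed for ``d > 0``; the arcsinh-based
  variance-stabilizing transformation ``x -> alpha* * arcsinh(beta* * x)``
  with the constants from :func:`vst_constants` removes both to first order.

The sample variance uses divisor N-1 throughout, which is what makes the
noncentral-t characterization (and ``dhat = t / sqrt(N)``) exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .grid import DomainGrid, SubjectStack

__all__ = [
    "FieldSummary",
    "SmallSampleConstants",
    "summarize",
    "bias_factor",
    "vst_constants",
    "t_to_cohens_d",
]


def _check_n(n_subjects: int) -> int:
    n = int(n_subjects)
    if n < 4:
        raise ValueError(f"need n_subjects >= 4, got {n}")
    return n


@dataclass(frozen=True)
class FieldSummary:
    """Pointwise mean, standard deviation and Cohen's d estimate fields."""

    grid: DomainGrid
    mean: np.ndarray = field(repr=False)
    sd: np.ndarray = field(repr=False)
    cohens_d: np.ndarray = field(repr=False)
    n_subjects: int = 0


@dataclass(frozen=True)
class SmallSampleConstants:
    """Noncentral-t bias and variance-stabilization constants for sample size N.

    ``c_n_exact`` and ``c_n_approx`` are the exact and approximate bias
    factors C_N; ``alpha_star``, ``beta_star`` and ``b_star`` parametrize the
    arcsinh variance-stabilizing transformation, with ``alpha_star * b_star
    == 1`` by construction.
    """

    n_subjects: int
    c_n_exact: float
    c_n_approx: float
    alpha_star: float
    beta_star: float
    b_star: float


def summarize(stack: SubjectStack, degenerate: str = "exclude") -> FieldSummary:
    """Compute the pointwise mean, sd (divisor N-1) and Cohen's d fields.

    Parameters
    ----------
    stack
        Subject-level fields.
    degenerate
        What to do with in-mask voxels where the sample sd is zero (all
        subjects identical): ``"exclude"`` drops them from the mask with a
        warning, ``"error"`` raises.

    Returns
    -------
    FieldSummary
        Summary fields; ``cohens_d = mean / sd`` on the (possibly reduced)
        mask and NaN elsewhere.
    """
    if degenerate not in ("exclude", "error"):
        raise ValueError(f"degenerate must be 'exclude' or 'error', got {degenerate!r}")
    grid = stack.grid
    mean = stack.data.mean(axis=0)
    sd = stack.data.std(axis=0, ddof=1)

    bad = (sd == 0) & grid.mask
    mask = grid.mask
    if bad.any():
        if degenerate == "error":
            raise ValueError(
                f"{int(bad.sum())} in-mask voxel(s) have zero sample variance"
            )
        warnings.warn(
            f"excluding {int(bad.sum())} zero-variance voxel(s) from the mask",
            RuntimeWarning,
            stacklevel=2,
        )
        mask = mask & ~bad
        if not mask.any():
            raise ValueError("all in-mask voxels are degenerate (zero variance)")
        grid = DomainGrid(grid.shape, mask)

    cohens_d = np.full(grid.shape, np.nan)
    cohens_d[mask] = mean[mask] / sd[mask]
    return FieldSummary(
        grid=grid, mean=mean, sd=sd, cohens_d=cohens_d, n_subjects=stack.n_subjects
    )


def bias_factor(n_subjects: int, exact: bool = True) -> float:
    """Bias factor C_N of the Cohen's d estimator, ``E[dhat] = C_N d``.

    The exact value is ``sqrt((N-1)/2) * Gamma((N-2)/2) / Gamma((N-1)/2)``,
    evaluated via log-gamma differences so it is stable for large N; the
    approximation is ``(1 - 3/(4N-5))^{-1}``.
    """
    n = _check_n(n_subjects)
    if exact:
        log_c = 0.5 * np.log((n - 1) / 2.0) + gammaln((n - 2) / 2.0) - gammaln((n - 1) / 2.0)
        return float(np.exp(log_c))
    return float(1.0 / (1.0 - 3.0 / (4.0 * n - 5.0)))


def vst_constants(n_subjects: int) -> SmallSampleConstants:
    """Constants of the arcsinh variance-stabilizing transformation.

    With ``P = 8N^2 - 17N + 11`` and ``Q = (N-3)(4N-5)^2``:

    * ``alpha_star = (N P / Q)^{-1/2}`` and ``b_star = (N P / Q)^{+1/2}``
      (reciprocal powers of the same expression, so their product is 1);
    * ``beta_star = (N P / ((N-1)(4N-5)^2))^{1/2}``, chosen so that
      ``x -> alpha* arcsinh(beta* x)`` has derivative
      ``1 / sqrt(N Var(dhat))`` with ``Var(dhat) = a + b x^2``,
      ``a = (N-1)/(N(N-3))`` the exact central-t variance of dhat and
      ``b = 1/(N alpha*^2)`` the approximate slope in d^2.

    Asymptotically ``alpha* -> sqrt(2)``, ``beta* -> 1/sqrt(2)`` and the
    transformation tends to ``sqrt(2) arcsinh(x / sqrt(2))``, the classical
    stabilizer for an estimator with variance ``(1 + x^2/2)/N``.
    """
    n = _check_n(n_subjects)
    poly = 8.0 * n**2 - 17.0 * n + 11.0
    ratio = n * poly / ((n - 3.0) * (4.0 * n - 5.0) ** 2)
    alpha_star = ratio**-0.5
    b_star = ratio**0.5
    beta_star = (n * poly / ((n - 1.0) * (4.0 * n - 5.0) ** 2)) ** 0.5
    return SmallSampleConstants(
        n_subjects=n,
        c_n_exact=bias_factor(n, exact=True),
        c_n_approx=bias_factor(n, exact=False),
        alpha_star=float(alpha_star),
        beta_star=float(beta_star),
        b_star=float(b_star),
    )


def t_to_cohens_d(t_field: np.ndarray, n_subjects: int) -> np.ndarray:
    """Convert a one-sample t-statistic field to Cohen's d: ``dhat = t/sqrt(N)``."""
    n = _check_n(n_subjects)
    t = np.asarray(t_field, dtype=np.float64)
    return t / np.sqrt(n)
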