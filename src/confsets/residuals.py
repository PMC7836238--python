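"""Delta-method Cohen's d residuals and their standardizations.

The naive standardized residuals ``(Y_i - Ybar)/sd`` reproduce the spatial
correlation of the *error* field, which is not the correlation of the
limiting field of the Cohen's d estimator once d != 0.  A first-order Taylor
expansion of (mean, variance) -> mean/sd yields corrected residuals

    R_i = (Y_i - Ybar)/sd - (Ybar / (2 sd)) * ((Y_i - Ybar)^2/sd^2 - m),

whose empirical covariance matches the limiting field.  The centering
constant ``m`` is the empirical mean of ``(Y_i - Ybar)^2 / sd^2`` so that
``sum_i R_i(s) = 0`` exactly for every N and either variance divisor.

Three standardizations feed the wild t-bootstrap:

* ``limiting`` - divide by ``sqrt(1 + dhat^2/2)``, the limiting sd;
* ``sample_sd`` - divide by the pointwise sample sd of the R_i;
* ``vst`` - multiply by the arcsinh-transform derivative
  ``alpha* beta* / sqrt(1 + beta*^2 dhat^2)`` (residuals on the
  variance-stabilized scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .field_summaries import FieldSummary, SmallSampleConstants
from .grid import DomainGrid, SubjectStack

__all__ = [
    "ResidualSet",
    "cohens_d_residuals",
    "standardize_limiting",
    "standardize_sample_sd",
    "vst_residuals",
]


@dataclass(frozen=True)
class ResidualSet:
    """N standardized residual fields ready for the wild t-bootstrap.

    ``flavor`` is one of ``"limiting"``, ``"sample_sd"``, ``"vst"``;
    ``sd_r`` (the pointwise sample sd of the raw residuals) is present only
    for the ``sample_sd`` flavor, where it also enters the CS band width.
    """

    grid: DomainGrid
    residuals: np.ndarray = field(repr=False)
    flavor: str = "limiting"
    n_subjects: int = 0
    sd_r: np.ndarray | None = field(default=None, repr=False)


def cohens_d_residuals(stack: SubjectStack, summary: FieldSummary) -> np.ndarray:
    """Raw delta-method Cohen's d residuals R_i, shape (N, *grid.shape).

    Pointwise mean over subjects is exactly zero. Values are NaN outside the
    summary mask.
    """
    if stack.data.shape[1:] != summary.grid.shape:
        raise ValueError("stack and summary are on different grids")
    mask = summary.grid.mask
    eps = stack.data[:, mask] - summary.mean[mask]          # (N, V)
    z = eps / summary.sd[mask]
    z2 = z**2
    centered_sq = z2 - z2.mean(axis=0)                      # exact mean-zero centering
    r = z - (summary.cohens_d[mask] / 2.0) * centered_sq
    if not np.all(np.isfinite(r)):
        i, j = np.argwhere(~np.isfinite(r))[0]
        raise FloatingPointError(
            f"non-finite Cohen's d residual (subject {i}, masked voxel {j})"
        )
    out = np.full(stack.data.shape, np.nan)
    out[:, mask] = r
    return out


def standardize_limiting(raw: np.ndarray, summary: FieldSummary) -> ResidualSet:
    """Standardize raw residuals by the limiting sd ``sqrt(1 + dhat^2/2)``."""
    grid = summary.grid
    mask = grid.mask
    out = np.full(raw.shape, np.nan)
    out[:, mask] = raw[:, mask] / np.sqrt(1.0 + summary.cohens_d[mask] ** 2 / 2.0)
    return ResidualSet(
        grid=grid, residuals=out, flavor="limiting", n_subjects=summary.n_subjects
    )


def standardize_sample_sd(raw: np.ndarray, grid: DomainGrid) -> ResidualSet:
    """Standardize raw residuals by their pointwise sample sd (divisor N).

    By construction the pointwise second moment of the output is 1. Voxels
    where the residual sd is exactly zero are degenerate and raise.
    """
    mask = grid.mask
    r = raw[:, mask]
    n = r.shape[0]
    sd_r_m = np.sqrt((r**2).sum(axis=0) / n)
    if np.any(sd_r_m == 0):
        raise ValueError("zero residual sd at an in-mask voxel (degenerate)")
    out = np.full(raw.shape, np.nan)
    out[:, mask] = r / sd_r_m
    sd_r = np.full(grid.shape, np.nan)
    sd_r[mask] = sd_r_m
    return ResidualSet(
        grid=grid, residuals=out, flavor="sample_sd", n_subjects=n, sd_r=sd_r
    )


def vst_residuals(
    stack: SubjectStack, summary: FieldSummary, constants: SmallSampleConstants
) -> ResidualSet:
    """Residuals on the variance-stabilized (arcsinh) scale.

    Equal to the raw residuals times the derivative of
    ``x -> alpha* arcsinh(beta* x)`` at ``dhat``.
    """
    raw = cohens_d_residuals(stack, summary)
    a, b = constants.alpha_star, constants.beta_star
    mask = summary.grid.mask
    factor = a * b / np.sqrt(1.0 + b**2 * summary.cohens_d[mask] ** 2)
    out = np.full(raw.shape, np.nan)
    out[:, mask] = raw[:, mask] * factor
    return ResidualSet(
        grid=summary.grid, residuals=out, flavor="vst", n_subjects=summary.n_subjects
    )


def _bold_standardized_residuals(stack: SubjectStack, summary: FieldSummary) -> np.ndarray:
    """Plain standardized residuals (Y_i - Ybar)/sd.

    Internal reference only: their bootstrap covariance reproduces the error
    correlation rho(s,t), not the covariance of the limiting Cohen's d field,
    so they are deliberately not offered as a user-facing flavor.
    """
    mask = summary.grid.mask
    out = np.full(stack.data.shape, np.nan)
    out[:, mask] = (stack.data[:, mask] - summary.mean[mask]) / summary.sd[mask]
    return out
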