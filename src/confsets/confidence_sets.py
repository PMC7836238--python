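"""Assembly of upper/lower confidence sets for Cohen's d excursion sets.

Given N subject maps, a Cohen's d threshold c and a level 1 - alpha, the
three algorithms produce nested boolean masks

    upper  ⊆  point estimate  ⊆  lower

such that, with probability ~ 1 - alpha over repeated experiments, the
upper set lies inside the true excursion set {d >= c} and the true set lies
inside the lower set.  All three bias-correct the threshold by the
noncentral-t factor (1 - 3/(4N-5))^{-1}; they differ in the variance used
for the band (limiting 1 + dhat^2/2, sample residual sd, or none after the
variance-stabilizing arcsinh transform) and in the residuals fed to the
wild t-bootstrap that calibrates the critical value k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boundary import corrected_threshold, estimate_boundary, residuals_on_boundary
from .bootstrap import CriticalValue, wild_t_bootstrap
from .field_summaries import (
    FieldSummary,
    SmallSampleConstants,
    summarize,
    vst_constants,
)
from .grid import DomainGrid, SubjectStack
from .residuals import (
    cohens_d_residuals,
    standardize_limiting,
    standardize_sample_sd,
    vst_residuals,
)

__all__ = [
    "ConfidenceSets",
    "construct_algorithm1",
    "construct_algorithm2",
    "construct_algorithm3",
    "vst_threshold",
    "compute_confidence_sets",
]


@dataclass(frozen=True)
class ConfidenceSets:
    """Upper/lower/point-estimate masks plus the calibration that made them.

    ``upper_decision`` / ``lower_decision`` are the continuous fields whose
    nonnegativity defines the masks; they support the sub-voxel
    (interpolated) coverage assessment.  ``degenerate`` is True when the
    estimated boundary was empty so no critical value could be bootstrapped
    (both CSs then equal the point estimate).
    """

    grid: DomainGrid
    upper: np.ndarray = field(repr=False)
    lower: np.ndarray = field(repr=False)
    point_estimate: np.ndarray = field(repr=False)
    critical: CriticalValue | None
    c: float
    alpha: float
    algorithm: int
    upper_decision: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    lower_decision: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    summary: FieldSummary | None = field(repr=False, default=None)
    degenerate: bool = False

    @property
    def k(self) -> float | None:
        return None if self.critical is None else self.critical.k


def _masks(
    grid: DomainGrid, f_up: np.ndarray, f_low: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    mask = grid.mask
    upper = np.zeros(grid.shape, dtype=bool)
    lower = np.zeros(grid.shape, dtype=bool)
    upper[mask] = f_up[mask] >= 0
    lower[mask] = f_low[mask] >= 0
    return upper, lower


def _band_decisions(
    summary: FieldSummary, half_width: np.ndarray, k: float, c: float
) -> tuple[np.ndarray, np.ndarray]:
    tau = corrected_threshold(c, summary.n_subjects)
    band = (k / np.sqrt(summary.n_subjects)) * half_width
    f_up = summary.cohens_d - tau - band
    f_low = summary.cohens_d - tau + band
    return f_up, f_low


def construct_algorithm1(
    summary: FieldSummary, k: float, c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Masks with band half-width ``(k/sqrt(N)) sqrt(1 + dhat^2/2)``."""
    if k < 0:
        raise ValueError("critical value k must be nonnegative")
    f_up, f_low = _band_decisions(
        summary, np.sqrt(1.0 + summary.cohens_d**2 / 2.0), k, c
    )
    return _masks(summary.grid, f_up, f_low)


def construct_algorithm2(
    summary: FieldSummary, sd_r: np.ndarray | None, k: float, c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Masks with band half-width ``(k/sqrt(N)) sd_R(s)`` (residual sample sd)."""
    if k < 0:
        raise ValueError("critical value k must be nonnegative")
    if sd_r is None:
        raise ValueError(
            "algorithm 2 needs the residual sample sd field (sample_sd flavor)"
        )
    f_up, f_low = _band_decisions(summary, np.asarray(sd_r), k, c)
    return _masks(summary.grid, f_up, f_low)


def vst_threshold(c: float, constants: SmallSampleConstants) -> float:
    """Transformed, bias-corrected, skew-offset threshold on the arcsinh scale.

    T(c, N) = alpha* arcsinh(beta* c~) - offset, where c~ is the
    bias-corrected threshold and the offset is the second-order (skewness)
    mean correction of the stabilized estimator,

        offset = b*^2 c~ / (2N) * [ (N-1)/(N-3)
                  + N c^2 (8N^2 - 17N + 11) / (16 (N-3)(N-2)^2) ]^{-1/2}.
    """
    n = constants.n_subjects
    c_tilde = corrected_threshold(c, n)
    poly = 8.0 * n**2 - 17.0 * n + 11.0
    bracket = (n - 1.0) / (n - 3.0) + n * c**2 * poly / (
        16.0 * (n - 3.0) * (n - 2.0) ** 2
    )
    offset = constants.b_star**2 * c_tilde / (2.0 * n) * bracket**-0.5
    return float(
        constants.alpha_star * np.arcsinh(constants.beta_star * c_tilde) - offset
    )


def construct_algorithm3(
    summary: FieldSummary, constants: SmallSampleConstants, k: float, c: float
) -> tuple[np.ndarray, np.ndarray]:
    """Masks thresholding the arcsinh-stabilized field at T(c,N) -+ k/sqrt(N)."""
    if k < 0:
        raise ValueError("critical value k must be nonnegative")
    g = constants.alpha_star * np.arcsinh(constants.beta_star * summary.cohens_d)
    t = vst_threshold(c, constants)
    band = k / np.sqrt(summary.n_subjects)
    return _masks(summary.grid, g - t - band, g - t + band)


def compute_confidence_sets(
    stack: SubjectStack,
    c: float,
    alpha: float = 0.05,
    algorithm: int = 3,
    n_boot: int = 5000,
    seed: np.random.Generator | int | None = None,
) -> ConfidenceSets:
    """End-to-end confidence sets for {d >= c} from a subject stack.

    Orchestrates: summary fields -> algorithm-specific residual
    standardization -> interpolated plug-in boundary -> wild t-bootstrap
    critical value -> set construction.  If the estimated boundary is empty
    (dhat never approaches the corrected threshold inside the mask), no
    critical value can be bootstrapped; the sets collapse to the point
    estimate and are flagged degenerate, with a warning.
    """
    if algorithm not in (1, 2, 3):
        raise ValueError(f"algorithm must be 1, 2 or 3, got {algorithm}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if c < 0:
        raise ValueError(f"threshold c must be nonnegative, got {c}")

    summary = summarize(stack)
    grid = summary.grid
    n = summary.n_subjects
    tau = corrected_threshold(c, n)
    point = np.zeros(grid.shape, dtype=bool)
    point[grid.mask] = summary.cohens_d[grid.mask] >= tau

    constants = vst_constants(n)
    raw = cohens_d_residuals(stack, summary)
    sd_r = None
    if algorithm == 1:
        rset = standardize_limiting(raw, summary)
    elif algorithm == 2:
        rset = standardize_sample_sd(raw, grid)
        sd_r = rset.sd_r
    else:
        rset = vst_residuals(stack, summary, constants)

    bnd = estimate_boundary(summary, c, algorithm)
    if bnd.n_points == 0:
        warnings.warn(
            "degenerate confidence sets: estimated boundary is outside the mask; "
            "returning the point-estimate set for both CSs",
            RuntimeWarning,
            stacklevel=2,
        )
        nanfield = np.full(grid.shape, np.nan)
        return ConfidenceSets(
            grid=grid,
            upper=point.copy(),
            lower=point.copy(),
            point_estimate=point,
            critical=None,
            c=float(c),
            alpha=float(alpha),
            algorithm=algorithm,
            upper_decision=nanfield,
            lower_decision=nanfield.copy(),
            summary=summary,
            degenerate=True,
        )

    boundary_res = residuals_on_boundary(rset, bnd)
    critical = wild_t_bootstrap(boundary_res, n_boot=n_boot, alpha=alpha, rng=seed)
    k = critical.k

    if algorithm == 1:
        f_up, f_low = _band_decisions(
            summary, np.sqrt(1.0 + summary.cohens_d**2 / 2.0), k, c
        )
    elif algorithm == 2:
        f_up, f_low = _band_decisions(summary, sd_r, k, c)
    else:
        g = constants.alpha_star * np.arcsinh(constants.beta_star * summary.cohens_d)
        t = vst_threshold(c, constants)
        band = k / np.sqrt(n)
        f_up, f_low = g - t - band, g - t + band
    upper, lower = _masks(grid, f_up, f_low)

    return ConfidenceSets(
        grid=grid,
        upper=upper,
        lower=lower,
        point_estimate=point,
        critical=critical,
        c=float(c),
        alpha=float(alpha),
        algorithm=algorithm,
        upper_decision=f_up,
        lower_decision=f_low,
        summary=summary,
        degenerate=False,
    )
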