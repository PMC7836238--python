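"""Synthetic signals, smoothed Gaussian noise, and coverage experiments.

The generators emulate a standard group-fMRI simulation design: a smooth
deterministic mean field (linear ramp, smoothed circular or spherical
phantoms of magnitude 1) plus subject-specific noise obtained by smoothing
white noise with a 3-voxel-FWHM Gaussian kernel, re-standardized so the
pointwise sd is exactly the requested sd field (spatially constant 1, or
increasing linearly from 0.5 to 1.5 along the last axis).  With the
homogeneous field the true Cohen's d equals the mean signal itself.

Axis convention: the ramp runs along axis 0 ("x"); the heterogeneous sd
gradient runs along the last axis ("y" in 2-D, "z" in 3-D), so the two are
orthogonal as in the reference design.

Coverage of a confidence-set pair is assessed against the *true* excursion
set on the lattice and, sub-voxel, at linearly interpolated points of the
true boundary (where the noise-free d field crosses c): a trial covers iff
upper ⊆ A_c ⊆ lower voxelwise and, at every interpolated true-boundary
point, the upper decision field is not positive and the lower decision
field is not negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .boundary import find_crossings
from .confidence_sets import ConfidenceSets, compute_confidence_sets
from .grid import DomainGrid, SubjectStack

__all__ = [
    "SignalSpec",
    "NoiseSpec",
    "SimConfig",
    "TruthSet",
    "make_signal",
    "make_noise",
    "make_truth",
    "assess_coverage_trial",
    "upper_cs_sensitivity",
    "run_experiment",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

SIGNAL_KINDS = ("ramp2d", "circle2d", "sphere3d_small", "sphere3d_large", "multi_sphere3d")

# default geometry for the four-phantom 3-D signal, as fractions of the grid
# shape: centers spread symmetrically, radii of varying size (in voxels for a
# 100^3 grid, scaled with the grid otherwise)
_MULTI_CENTERS = ((0.3, 0.3, 0.3), (0.3, 0.7, 0.7), (0.7, 0.3, 0.7), (0.7, 0.7, 0.3))
_MULTI_RADII = (0.05, 0.08, 0.10, 0.12)


@dataclass(frozen=True)
class SignalSpec:
    """Deterministic mean-field specification."""

    kind: str
    shape: tuple[int, ...]
    magnitude: float = 1.0
    smoothing_fwhm: float = 3.0
    radius: float | None = None
    centers: tuple[tuple[float, ...], ...] | None = None
    radii: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in SIGNAL_KINDS:
            raise ValueError(f"unknown signal kind {self.kind!r}; one of {SIGNAL_KINDS}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))


@dataclass(frozen=True)
class NoiseSpec:
    """Smoothed-Gaussian noise specification.

    ``sd`` is ``"homogeneous"`` (pointwise sd 1) or ``"linear"`` (sd rising
    linearly from ``sd_range[0]`` to ``sd_range[1]`` along the last axis).
    """

    smoothing_fwhm: float = 3.0
    sd: str = "homogeneous"
    sd_range: tuple[float, float] = (0.5, 1.5)

    def __post_init__(self) -> None:
        if self.sd not in ("homogeneous", "linear"):
            raise ValueError(f"sd must be 'homogeneous' or 'linear', got {self.sd!r}")

    def sd_field(self, shape: Sequence[int]) -> np.ndarray:
        shape = tuple(shape)
        if self.sd == "homogeneous":
            return np.ones(shape)
        lo, hi = self.sd_range
        n_last = shape[-1]
        ramp = np.linspace(lo, hi, n_last)
        out = np.broadcast_to(ramp, shape).copy()
        return out


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo experiment configuration (defaults = full study scale)."""

    n_trials: int = 3000
    n_boot: int = 5000
    sample_sizes: tuple[int, ...] = (30, 60, 120, 240, 480)
    levels: tuple[float, ...] = (0.80, 0.90, 0.95)
    c: float = 0.8
    algorithms: tuple[int, ...] = (1, 2, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_sizes", tuple(int(n) for n in np.atleast_1d(self.sample_sizes)))
        object.__setattr__(self, "levels", tuple(float(v) for v in np.atleast_1d(self.levels)))
        object.__setattr__(self, "algorithms", tuple(int(a) for a in np.atleast_1d(self.algorithms)))
        if self.n_trials < 1 or self.n_boot < 1:
            raise ValueError("n_trials and n_boot must be positive")
        if not all(0.0 < lv < 1.0 for lv in self.levels):
            raise ValueError("levels must lie in (0, 1)")


@dataclass(frozen=True)
class TruthSet:
    """Noise-free d field, its excursion set, and the interpolated true boundary."""

    grid: DomainGrid
    d: np.ndarray = field(repr=False)
    a_c: np.ndarray = field(repr=False)
    c: float = 0.8
    boundary_a: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    boundary_b: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    boundary_w: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _kernel1d(fwhm: float) -> np.ndarray:
    """Normalized 1-D Gaussian kernel, truncated at 4 sigma."""
    sigma = fwhm * FWHM_TO_SIGMA
    radius = max(1, int(round(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def _smooth(arr: np.ndarray, fwhm: float, axes: Sequence[int]) -> np.ndarray:
    """Separable truncated-Gaussian smoothing with zero padding outside."""
    k = _kernel1d(fwhm)
    out = arr
    for ax in axes:
        out = convolve1d(out, k, axis=ax, mode="constant", cval=0.0)
    return out


def smoothed_noise_sd(shape: Sequence[int], fwhm: float) -> np.ndarray:
    """Exact pointwise sd of zero-padded-smoothed unit white noise.

    Separable: the variance field is the outer product over axes of the
    convolution of a ones-vector with the squared 1-D kernel, which handles
    edge truncation exactly.
    """
    k2 = _kernel1d(fwhm) ** 2
    var = np.ones(())
    factors = []
    for n in shape:
        factors.append(convolve1d(np.ones(n), k2, mode="constant", cval=0.0))
    var = factors[0]
    for f in factors[1:]:
        var = np.multiply.outer(var, f)
    return np.sqrt(var)


def _ball_indicator(shape: tuple[int, ...], center: Sequence[float], radius: float) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape], indexing="ij")
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return (dist2 <= radius**2).astype(np.float64)


def make_signal(spec: SignalSpec) -> np.ndarray:
    """Deterministic mean field mu(s) for the given specification."""
    shape = spec.shape
    if spec.kind == "ramp2d":
        if len(shape) != 2:
            raise ValueError("ramp2d needs a 2-D shape")
        # linear 0 -> magnitude along axis 0, inclusive endpoints; no smoothing
        ramp = np.linspace(0.0, spec.magnitude, shape[0])
        return np.broadcast_to(ramp[:, None], shape).copy()

    center = tuple((n - 1) / 2.0 for n in shape)
    if spec.kind == "circle2d":
        if len(shape) != 2:
            raise ValueError("circle2d needs a 2-D shape")
        radius = 30.0 if spec.radius is None else spec.radius
        if radius >= min(shape) / 2.0 + 1:
            raise ValueError("circle radius exceeds the grid")
        disk = spec.magnitude * _ball_indicator(shape, center, radius)
        return _smooth(disk, spec.smoothing_fwhm, range(2))

    if spec.kind in ("sphere3d_small", "sphere3d_large"):
        if len(shape) != 3:
            raise ValueError(f"{spec.kind} needs a 3-D shape")
        radius = (5.0 if spec.kind == "sphere3d_small" else 30.0) if spec.radius is None else spec.radius
        if radius >= min(shape) / 2.0 + 1:
            raise ValueError("sphere radius exceeds the grid")
        ball = _ball_indicator(shape, center, radius)
        sm = _smooth(ball, spec.smoothing_fwhm, range(3))
        # imagewise rescaling to a maximum intensity of `magnitude`
        return spec.magnitude * sm / sm.max()

    # multi_sphere3d: each phantom smoothed and rescaled to peak `magnitude`
    # on its own, then summed; overlap regions clipped back to `magnitude` so
    # every phantom center sits exactly at the nominal peak.
    if len(shape) != 3:
        raise ValueError("multi_sphere3d needs a 3-D shape")
    centers = spec.centers
    radii = spec.radii
    if centers is None:
        centers = tuple(tuple(f * (n - 1) for f, n in zip(fr, shape)) for fr in _MULTI_CENTERS)
    if radii is None:
        radii = tuple(r * min(shape) for r in _MULTI_RADII)
    if len(centers) != len(radii):
        raise ValueError("centers and radii must have equal length")
    total = np.zeros(shape)
    for ctr, rad in zip(centers, radii):
        if rad < 1:
            raise ValueError("sphere radius below one voxel")
        sm = _smooth(_ball_indicator(shape, ctr, rad), spec.smoothing_fwhm, range(3))
        total += sm / sm.max()
    return spec.magnitude * np.minimum(total, 1.0)


def make_noise(
    grid: DomainGrid,
    noise: NoiseSpec,
    n_subjects: int,
    rng: np.random.Generator | int | None = None,
    signal: np.ndarray | None = None,
) -> SubjectStack:
    """Draw a subject stack of smoothed, standardized Gaussian noise.

    Per subject: white standard-normal noise -> zero-padded Gaussian
    smoothing -> division by the exact pointwise sd of the smoothed noise
    (unit-variance standardization) -> multiplication by the sd field.  If
    ``signal`` is given it is added to every subject field.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    shape = grid.shape
    white = gen.standard_normal((int(n_subjects), *shape))
    sm = _smooth(white, noise.smoothing_fwhm, range(1, len(shape) + 1))
    sm /= smoothed_noise_sd(shape, noise.smoothing_fwhm)
    sm *= noise.sd_field(shape)
    if signal is not None:
        sm += np.asarray(signal)
    return SubjectStack(grid=grid, data=sm)


def make_truth(signal: np.ndarray, noise: NoiseSpec, c: float, grid: DomainGrid | None = None) -> TruthSet:
    """True d field, excursion set and interpolated true boundary at level c."""
    signal = np.asarray(signal, dtype=np.float64)
    if grid is None:
        grid = DomainGrid(signal.shape)
    d = signal / noise.sd_field(signal.shape)
    a_c = np.zeros(grid.shape, dtype=bool)
    a_c[grid.mask] = d[grid.mask] >= c
    ba, bb, bw = find_crossings(d, c, grid.mask)
    return TruthSet(grid=grid, d=d, a_c=a_c, c=float(c), boundary_a=ba, boundary_b=bb, boundary_w=bw)


def assess_coverage_trial(cs: ConfidenceSets, truth: TruthSet) -> bool:
    """True iff the CS pair brackets the true excursion set.

    Checks voxelwise nesting (upper ⊆ A_c and A_c ⊆ lower) and, at every
    linearly interpolated point of the *true* boundary, that the upper
    decision field is <= 0 and the lower decision field is >= 0.
    """
    if cs.grid.shape != truth.grid.shape:
        raise ValueError("confidence sets and truth are on different grids")
    if np.any(cs.upper & ~truth.a_c):
        return False
    if np.any(truth.a_c & ~cs.lower):
        return False
    if truth.boundary_a.size == 0 or cs.degenerate:
        return True
    w = truth.boundary_w
    f_up = cs.upper_decision.ravel()
    f_low = cs.lower_decision.ravel()
    up_p = (1.0 - w) * f_up[truth.boundary_a] + w * f_up[truth.boundary_b]
    low_p = (1.0 - w) * f_low[truth.boundary_a] + w * f_low[truth.boundary_b]
    if np.any(up_p > 0):
        return False
    if np.any(low_p < 0):
        return False
    return True


def upper_cs_sensitivity(cs: ConfidenceSets, truth: TruthSet) -> float:
    """Fraction of true suprathreshold voxels captured by the upper CS."""
    n_true = int(truth.a_c.sum())
    if n_true == 0:
        raise ValueError("sensitivity undefined: true excursion set is empty")
    return float((cs.upper & truth.a_c).sum() / n_true)


def _trial_rng(seed: int, n: int, trial: int) -> np.random.Generator:
    """Deterministic per-trial data generator.

    Depends only on (seed, N, trial) so different algorithms and levels see
    identical simulated samples.
    """
    return np.random.default_rng(np.random.SeedSequence([seed, n, trial, 0]))


def run_experiment(
    config: SimConfig,
    signal: SignalSpec,
    noise: NoiseSpec,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Monte-Carlo coverage/sensitivity experiment.

    For every (sample size, level, algorithm) cell, ``n_trials`` independent
    samples are drawn from the signal-plus-noise model, confidence sets are
    computed with the wild t-bootstrap (``n_boot`` replicates), and coverage
    and upper-CS sensitivity are aggregated.  Fully seed-deterministic: the
    same ``config.seed`` reproduces the table, and all algorithms/levels of
    a trial share the same simulated sample.
    """
    mu = make_signal(signal)
    grid = DomainGrid(mu.shape, mask)
    truth = make_truth(mu, noise, config.c, grid)
    have_truth = bool(truth.a_c.any())

    rows = []
    for n in config.sample_sizes:
        cover = {(lv, alg): 0 for lv in config.levels for alg in config.algorithms}
        sens = {(lv, alg): [] for lv in config.levels for alg in config.algorithms}
        for trial in range(config.n_trials):
            data_rng = _trial_rng(config.seed, n, trial)
            stack = make_noise(grid, noise, n, data_rng, signal=mu)
            for alg in config.algorithms:
                for i_lv, lv in enumerate(config.levels):
                    boot_rng = np.random.default_rng(
                        np.random.SeedSequence([config.seed, n, trial, 1, alg, i_lv])
                    )
                    cs = compute_confidence_sets(
                        stack,
                        c=config.c,
                        alpha=1.0 - lv,
                        algorithm=alg,
                        n_boot=config.n_boot,
                        seed=boot_rng,
                    )
                    if assess_coverage_trial(cs, truth):
                        cover[(lv, alg)] += 1
                    if have_truth:
                        sens[(lv, alg)].append(upper_cs_sensitivity(cs, truth))
        for alg in config.algorithms:
            for lv in config.levels:
                p = cover[(lv, alg)] / config.n_trials
                rows.append(
                    {
                        "signal": signal.kind,
                        "noise": noise.sd,
                        "algorithm": alg,
                        "N": n,
                        "level": lv,
                        "trials": config.n_trials,
                        "B": config.n_boot,
                        "coverage": p,
                        "coverage_se": math.sqrt(p * (1.0 - p) / config.n_trials),
                        "sensitivity": float(np.mean(sens[(lv, alg)])) if have_truth else math.nan,
                        "seed": config.seed,
                    }
                )
    return pd.DataFrame(rows)
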