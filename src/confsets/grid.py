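"""Domain grid and subject-stack containers.

Fields live on a 2-D or 3-D rectangular voxel lattice; a boolean mask marks
the in-domain voxels. All estimators downstream restrict themselves to the
mask. Arrays are C-ordered and the subject index is always axis 0 of a stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DomainGrid", "SubjectStack"]


@dataclass(frozen=True)
class DomainGrid:
    """A 2-D or 3-D voxel lattice with an in-domain mask.

    Parameters
    ----------
    shape
        Voxel counts per axis (length 2 or 3).
    mask
        Boolean array of ``shape`` marking in-domain voxels. ``None`` means
        the full grid.
    """

    shape: tuple[int, ...]
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (2, 3):
            raise ValueError(f"grid must be 2-D or 3-D, got shape {shape}")
        if any(n < 1 for n in shape):
            raise ValueError(f"grid axes must be positive, got {shape}")
        mask = self.mask
        if mask is None:
            mask = np.ones(shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != shape:
                raise ValueError(
                    f"mask shape {mask.shape} does not match grid shape {shape}"
                )
        if not mask.any():
            raise ValueError("mask is empty: no in-domain voxels")
        object.__setattr__(self, "mask", mask)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def check_field(self, arr: np.ndarray, name: str = "field") -> np.ndarray:
        """Validate that ``arr`` is a per-voxel field on this grid."""
        arr = np.asarray(arr)
        if arr.shape != self.shape:
            raise ValueError(
                f"{name} shape {arr.shape} does not match grid shape {self.shape}"
            )
        return arr

    def same_as(self, other: "DomainGrid") -> bool:
        return self.shape == other.shape and np.array_equal(self.mask, other.mask)


@dataclass(frozen=True)
class SubjectStack:
    """N aligned subject-level scalar fields over a masked grid.

    ``data`` has shape ``(n_subjects, *grid.shape)``; subject fields must be
    finite on the mask and N >= 4 so that the small-sample constants
    (denominators N-3 and 4N-5) and the variance estimate are well defined.
    """

    grid: DomainGrid
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != self.grid.ndim + 1:
            raise ValueError(
                f"data must be (n_subjects, *grid.shape); got ndim {data.ndim}"
            )
        if data.shape[1:] != self.grid.shape:
            raise ValueError(
                f"data field shape {data.shape[1:]} does not match grid "
                f"shape {self.grid.shape}"
            )
        if data.shape[0] < 4:
            raise ValueError(
                f"need at least 4 subjects, got {data.shape[0]}"
            )
        if not np.all(np.isfinite(data[:, self.grid.mask])):
            raise ValueError("subject fields contain non-finite values on the mask")
        object.__setattr__(self, "data", data)

    @property
    def n_subjects(self) -> int:
        return int(self.data.shape[0])
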