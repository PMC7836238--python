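"""NIfTI input/output and result sidecars.

Subject stacks are read from a single 4-D NIfTI volume (subject index on the
fourth axis) or from an ordered list of per-subject 3-D volumes, together
with a 3-D mask on the same grid.  Confidence-set masks are written as
uint8 0/1 volumes with the reference affine, the Cohen's d map as 32-bit
float, and the run parameters (c, alpha, algorithm, k, B, seed) to a JSON
sidecar.  No resampling is performed: grids and affines must match.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .confidence_sets import ConfidenceSets
from .grid import DomainGrid, SubjectStack

__all__ = ["read_subject_stack", "write_confidence_sets"]


def _load(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    return nib.load(str(path))


def read_subject_stack(
    input_path: str | Path | Sequence[str | Path],
    mask_path: str | Path | None = None,
) -> tuple[SubjectStack, nib.Nifti1Image]:
    """Load a subject stack (and reference image) from NIfTI files.

    Parameters
    ----------
    input_path
        A 4-D NIfTI path, or a sequence of 3-D NIfTI paths stacked in the
        given order.
    mask_path
        Optional 3-D binary mask on the same grid and affine; defaults to
        the full grid.

    Returns
    -------
    (stack, reference)
        The masked subject stack and the first input image (affine/header
        reference for writing outputs).
    """
    if isinstance(input_path, (str, Path)):
        img = _load(input_path)
        data = np.asarray(img.dataobj, dtype=np.float64)
        if data.ndim != 4:
            raise ValueError(
                f"expected a 4-D volume (got {data.ndim}-D); pass a list of "
                "files for per-subject 3-D volumes"
            )
        stack_data = np.moveaxis(data, -1, 0)
        ref = img
    else:
        paths = list(input_path)
        if not paths:
            raise ValueError("empty input file list")
        imgs = [_load(p) for p in paths]
        ref = imgs[0]
        vols = []
        for p, im in zip(paths, imgs):
            arr = np.asarray(im.dataobj, dtype=np.float64)
            if arr.ndim != 3:
                raise ValueError(f"{p}: expected a 3-D volume, got {arr.ndim}-D")
            if arr.shape != imgs[0].shape or not np.allclose(im.affine, ref.affine):
                raise ValueError(f"{p}: grid/affine mismatch with {paths[0]}")
            vols.append(arr)
        stack_data = np.stack(vols, axis=0)

    shape = stack_data.shape[1:]
    mask = None
    if mask_path is not None:
        mimg = _load(mask_path)
        marr = np.asarray(mimg.dataobj)
        if marr.shape != shape:
            raise ValueError(
                f"mask shape {marr.shape} does not match data grid {shape}"
            )
        if not np.allclose(mimg.affine, ref.affine):
            raise ValueError("mask affine does not match the data affine")
        mask = marr > 0
    grid = DomainGrid(shape, mask)
    return SubjectStack(grid=grid, data=stack_data), ref


def write_confidence_sets(
    cs: ConfidenceSets,
    reference: nib.Nifti1Image | None,
    outdir: str | Path,
    prefix: str = "cs",
) -> dict[str, Path]:
    """Write CS masks, the Cohen's d map and a JSON parameter sidecar.

    Returns a mapping from artifact name to written path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if reference is None else reference.affine

    written: dict[str, Path] = {}
    for name, arr in (
        ("upper", cs.upper),
        ("lower", cs.lower),
        ("point_estimate", cs.point_estimate),
    ):
        img = nib.Nifti1Image(arr.astype(np.uint8), affine)
        path = outdir / f"{prefix}_{name}.nii.gz"
        nib.save(img, str(path))
        written[name] = path
    if cs.summary is not None:
        dimg = nib.Nifti1Image(cs.summary.cohens_d.astype(np.float32), affine)
        path = outdir / f"{prefix}_cohens_d.nii.gz"
        nib.save(dimg, str(path))
        written["cohens_d"] = path

    sidecar = {
        "c": cs.c,
        "alpha": cs.alpha,
        "algorithm": cs.algorithm,
        "k": cs.k,
        "n_boot": None if cs.critical is None else cs.critical.n_boot,
        "seed": None if cs.critical is None else _jsonable(cs.critical.seed),
        "degenerate": cs.degenerate,
        "n_upper_voxels": int(cs.upper.sum()),
        "n_lower_voxels": int(cs.lower.sum()),
        "n_point_estimate_voxels": int(cs.point_estimate.sum()),
    }
    spath = outdir / f"{prefix}_params.json"
    spath.write_text(json.dumps(sidecar, indent=2))
    written["sidecar"] = spath
    return written


def _jsonable(seed: object) -> object:
    if seed is None or isinstance(seed, (int, str)):
        return seed
    return repr(seed)
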