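"""Readers and writers for the formats the tool touches.

Volumes travel as NIfTI-1 (4-D, float32 on disk, float64 in memory);
gradient tables as the two-file bval/bvec dialect (whitespace separated,
3xN or Nx3 auto-detected); directions, peaks, ground truth and summaries as
plain tabular text with '#' comment headers; run provenance as YAML.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .geometry import DirectionSet
from .simulate import BTable

__all__ = [
    "FormatError",
    "read_dwi",
    "write_dwi",
    "read_btable",
    "write_btable",
    "write_fodf",
    "read_fodf",
    "write_table",
    "read_table",
    "write_provenance",
]


class FormatError(ValueError):
    """Raised when an on-disk file does not match the expected layout."""


def read_btable(bval_path, bvec_path, n_volumes: int | None = None) -> BTable:
    """Read a bval/bvec pair; bvec orientation (3xN vs Nx3) is auto-detected."""
    bvals = np.atleast_1d(np.loadtxt(bval_path))
    bvecs = np.atleast_2d(np.loadtxt(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        warnings.warn("3x3 bvec table: assuming one row per volume")
    if bvecs.shape != (bvals.size, 3):
        raise FormatError("bvec shape does not match the number of b-values")
    if n_volumes is not None and bvals.size != n_volumes:
        raise FormatError(
            f"b-table has {bvals.size} rows but the volume has {n_volumes}"
        )
    dwi = bvals > 0
    norms = np.linalg.norm(bvecs[dwi], axis=1)
    if np.any(norms == 0):
        raise FormatError("zero gradient vector on a diffusion-weighted row")
    if np.any(np.abs(norms - 1.0) > 1e-3):
        warnings.warn("non-unit gradients at b > 0; renormalising")
    bvecs = bvecs.copy()
    bvecs[dwi] /= norms[:, None]
    return BTable(bvals, bvecs)


def write_btable(btable: BTable, bval_path, bvec_path) -> None:
    """Write a bval/bvec pair (one row of b-values, three rows of components)."""
    np.savetxt(bval_path, btable.bvals[None, :], fmt="%.17g")
    np.savetxt(bvec_path, btable.bvecs.T, fmt="%.17g")


def read_dwi(nifti_path, bval_path, bvec_path) -> tuple[np.ndarray, BTable]:
    """Load a 4-D diffusion volume and its aligned b-table."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise FormatError("expected a 4-D diffusion volume")
    btable = read_btable(bval_path, bvec_path, n_volumes=data.shape[3])
    return data, btable


def write_dwi(signals: np.ndarray, btable: BTable, out_prefix) -> dict[str, Path]:
    """Write voxel signals as a 4-D NIfTI plus the bval/bvec pair.

    A flat (n_voxels, n_rows) signal stack is stored as an (n_voxels, 1, 1,
    n_rows) volume.
    """
    out_prefix = Path(out_prefix)
    signals = np.asarray(signals, dtype=np.float32)
    if signals.ndim == 2:
        vol = signals.reshape(signals.shape[0], 1, 1, signals.shape[1])
    elif signals.ndim == 4:
        vol = signals
    else:
        raise ValueError("signals must be (n_voxels, n_rows) or 4-D")
    paths = {
        "nifti": out_prefix.with_suffix(".nii.gz"),
        "bval": out_prefix.parent / (out_prefix.name + ".bval"),
        "bvec": out_prefix.parent / (out_prefix.name + ".bvec"),
    }
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(paths["nifti"]))
    write_btable(btable, paths["bval"], paths["bvec"])
    return paths


def write_table(frame: pd.DataFrame, path, comment: str | None = None) -> None:
    """Tab-separated table with an optional '#' comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_fodf(results, out_prefix) -> dict[str, Path]:
    """Write a fitted decomposition: fODF volume, f0 and total-fraction maps,
    peaks table, and the direction table.

    The fODF volume has the axis fractions (unit-sum scale) as its last
    dimension; voxels are laid out along the first axis when the input was a
    flat voxel stack.
    """
    out_prefix = Path(out_prefix)
    dirs = results.directions
    n = len(dirs)
    fodf = np.asarray(results.normalized_fractions.todense(), dtype=np.float32)
    v = fodf.shape[0]
    paths = {
        "fodf": out_prefix.parent / (out_prefix.name + "_fodf.nii.gz"),
        "f0": out_prefix.parent / (out_prefix.name + "_f0.nii.gz"),
        "total": out_prefix.parent / (out_prefix.name + "_total_fraction.nii.gz"),
        "peaks": out_prefix.parent / (out_prefix.name + "_peaks.txt"),
        "directions": out_prefix.parent / (out_prefix.name + "_directions.txt"),
    }
    affine = np.eye(4)
    nib.save(nib.Nifti1Image(fodf.reshape(v, 1, 1, n), affine), str(paths["fodf"]))
    nib.save(
        nib.Nifti1Image(
            np.asarray(results.normalized_f0, dtype=np.float32).reshape(v, 1, 1), affine
        ),
        str(paths["f0"]),
    )
    nib.save(
        nib.Nifti1Image(
            np.asarray(results.total_fiber_fraction, dtype=np.float32).reshape(v, 1, 1),
            affine,
        ),
        str(paths["total"]),
    )
    write_table(results.peaks_table(), paths["peaks"], comment="ranked fODF peaks")
    dirs.save(paths["directions"])
    return paths


def read_fodf(out_prefix) -> tuple[np.ndarray, np.ndarray, np.ndarray, DirectionSet]:
    """Read back a written decomposition: (fodf, f0, total fraction, directions)."""
    out_prefix = Path(out_prefix)
    fodf = np.asarray(
        nib.load(str(out_prefix.parent / (out_prefix.name + "_fodf.nii.gz"))).dataobj,
        dtype=np.float64,
    )
    f0 = np.asarray(
        nib.load(str(out_prefix.parent / (out_prefix.name + "_f0.nii.gz"))).dataobj,
        dtype=np.float64,
    )
    total = np.asarray(
        nib.load(
            str(out_prefix.parent / (out_prefix.name + "_total_fraction.nii.gz"))
        ).dataobj,
        dtype=np.float64,
    )
    dirs = DirectionSet.load(out_prefix.parent / (out_prefix.name + "_directions.txt"))
    return fodf, f0, total, dirs


def write_provenance(config: dict, path) -> None:
    """Echo the run configuration (with package version) next to the outputs."""
    from . import __version__

    payload = {"diffdecomp_version": __version__, **config}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
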