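"""Diffusion-ODF reconstruction and the single-fiber component basis.

The diffusion ODF (dODF) is reconstructed with the generalized q-sampling
(GQI) analytic transform: the value along a unit direction ``u`` is a linear
functional of the signals,

    psi_d(u) = sum_rows S_row * sinc( L * sqrt(6 D b_row) * <g_row, u> )

with ``sinc(x) = sin(x)/x``, ``D`` the free-water diffusivity at body
temperature and ``L`` the diffusion sampling-length ratio (default 1.25).
Because the kernel depends only on b-value and gradient direction, the same
transform serves shell, grid, and multi-shell schemes.

The fiber model needs one *characteristic* dODF — the diffusion profile of a
coherent single-fiber population, taken from the most anisotropic voxel
available.  Component dODFs are built by re-centering that profile at each of
the 321 axes: the characteristic is collapsed onto an axial profile p(theta)
(value versus angle from its peak axis, smoothed with a Gaussian radial-basis
kernel of SD ``sigma_deg = 9``) and each component is p evaluated at the
angles to its assigned axis, normalised to unit sum.  The decomposition
operates on zero-mean, unit-norm versions of these columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .geometry import DirectionSet, axis_angle_matrix

__all__ = [
    "WATER_DIFFUSIVITY",
    "ODF",
    "ComponentBasis",
    "DegenerateCharacteristicError",
    "gqi_kernel",
    "reconstruct_dodf",
    "reconstruct_dodfs",
    "anisotropy_score",
    "select_characteristic",
    "build_component",
    "build_basis",
]

#: free-water diffusivity at body temperature, mm^2/s (GQI kernel constant)
WATER_DIFFUSIVITY = 2.51e-3

#: default diffusion sampling-length ratio of the GQI transform
DEFAULT_RATIO = 1.25

#: default angular smoothing (degrees) of the component profile
DEFAULT_SIGMA_DEG = 9.0


class DegenerateCharacteristicError(ValueError):
    """Raised when the characteristic dODF has no discernible peak."""


@dataclass(frozen=True)
class ODF:
    """A nonnegative density over the reduced direction set.

    ``kind`` tags the role: 'diffusion' (dODF), 'fiber' (fODF), or
    'component' (single-fiber component dODF, unit sum).
    """

    values: np.ndarray
    kind: str = "diffusion"

    def __post_init__(self):
        values = np.ascontiguousarray(self.values, dtype=float).ravel()
        if self.kind not in ("diffusion", "fiber", "component"):
            raise ValueError(f"unknown ODF kind {self.kind!r}")
        scale = float(np.abs(values).max()) if values.size else 0.0
        if scale and values.min() < -1e-8 * scale:
            raise ValueError("ODF values must be nonnegative")
        if self.kind == "component" and abs(values.sum() - 1.0) > 1e-9:
            raise ValueError("component ODFs must sum to 1")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


def gqi_kernel(btable, dirs: DirectionSet, ratio: float = DEFAULT_RATIO) -> np.ndarray:
    """GQI reconstruction matrix of shape (n_directions, n_rows).

    ``dODF = kernel @ signal``; rows with b = 0 contribute a constant offset.
    """
    q = np.sqrt(6.0 * WATER_DIFFUSIVITY * btable.bvals)[:, None] * btable.bvecs
    arg = ratio * (dirs.vectors @ q.T)  # (n_dirs, n_rows)
    return np.sinc(arg / np.pi)


def reconstruct_dodf(signal, btable, dirs: DirectionSet, ratio: float = DEFAULT_RATIO) -> ODF:
    """Reconstruct one voxel's diffusion ODF from its signals."""
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size != btable.n_rows:
        raise ValueError("signal length does not match the b-table")
    return ODF(gqi_kernel(btable, dirs, ratio) @ signal, kind="diffusion")


def reconstruct_dodfs(signals, btable, dirs: DirectionSet, ratio: float = DEFAULT_RATIO) -> np.ndarray:
    """Vectorised reconstruction: (n_voxels, n_rows) signals -> (n_voxels, n_dirs)."""
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if signals.shape[1] != btable.n_rows:
        raise ValueError("signal rows do not match the b-table")
    return signals @ gqi_kernel(btable, dirs, ratio).T


def anisotropy_score(odf) -> float:
    """ODF-native anisotropy: (max - min) / mean. Zero for a constant ODF."""
    v = np.asarray(getattr(odf, "values", odf), dtype=float)
    m = v.mean()
    if m == 0:
        return 0.0
    return float((v.max() - v.min()) / m)


def select_characteristic(dodfs) -> tuple[ODF, int]:
    """Pick the dODF with the highest anisotropy score (ties: lowest index).

    ``dodfs`` is a sequence of ODFs or an (n_voxels, n_dirs) array.
    """
    if isinstance(dodfs, np.ndarray) and dodfs.ndim == 2:
        values = dodfs
    else:
        values = np.array([np.asarray(getattr(o, "values", o), dtype=float) for o in dodfs])
    if values.size == 0:
        raise ValueError("need at least one dODF")
    scores = np.array([anisotropy_score(row) for row in values])
    idx = int(np.argmax(scores))
    return ODF(values[idx], kind="diffusion"), idx


def _axial_profile(values: np.ndarray, dirs: DirectionSet, sigma_deg: float):
    """Collapse a single-fiber dODF onto an angle profile p(theta).

    Returns (theta_grid, p) where p is the Gaussian-RBF (Nadaraya-Watson)
    smoothed dODF value as a function of the axis angle from the peak axis,
    tabulated on a fine grid over [0, 90] degrees.
    """
    peak_axis = dirs.vectors[int(np.argmax(values))]
    theta = axis_angle_matrix(dirs.vectors, peak_axis[None, :]).ravel()
    grid = np.linspace(0.0, 90.0, 901)
    w = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / sigma_deg) ** 2)
    p = (w @ values) / w.sum(axis=1)
    return grid, p


def build_component(
    characteristic,
    target_axis: np.ndarray,
    dirs: DirectionSet,
    sigma_deg: float = DEFAULT_SIGMA_DEG,
) -> ODF:
    """Re-center the characteristic single-fiber profile at ``target_axis``.

    The returned component dODF sums to one.  Raises
    :class:`DegenerateCharacteristicError` when the characteristic has no
    discernible peak (max/mean < 1 + 1e-6).
    """
    values = np.asarray(getattr(characteristic, "values", characteristic), dtype=float)
    if values.shape != (len(dirs),):
        raise ValueError("characteristic length does not match the direction set")
    if values.max() / values.mean() < 1.0 + 1e-6:
        raise DegenerateCharacteristicError("characteristic dODF has no peak")
    grid, p = _axial_profile(values, dirs, sigma_deg)
    target_axis = np.asarray(target_axis, dtype=float)
    target_axis = target_axis / np.linalg.norm(target_axis)
    theta = axis_angle_matrix(dirs.vectors, target_axis[None, :]).ravel()
    comp = np.interp(theta, grid, p)
    return ODF(comp / comp.sum(), kind="component")


@dataclass(frozen=True)
class ComponentBasis:
    """The 321 component dODFs and their normalised forms.

    ``components`` holds the raw unit-sum columns (one per axis of the
    reduced direction set); ``normalized`` the zero-mean, unit-norm columns
    used for correlation in the decomposition.
    """

    components: np.ndarray
    normalized: np.ndarray
    directions: DirectionSet
    sigma_deg: float

    def __post_init__(self):
        n = len(self.directions)
        if self.components.shape != (n, n) or self.normalized.shape != (n, n):
            raise ValueError("basis matrices must be (n_dirs, n_dirs)")

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def fiber_axes(self) -> np.ndarray:
        return self.directions.vectors

    @cached_property
    def gram(self) -> np.ndarray:
        """Gram matrix of the normalised columns (diagonal = 1)."""
        return self.normalized.T @ self.normalized

    def save(self, path) -> None:
        """Write the raw component matrix as plain tabular text (one column per axis)."""
        header = (
            f"component dODF matrix, {self.n_components} columns, "
            f"sigma_deg={self.sigma_deg}"
        )
        np.savetxt(path, self.components, fmt="%.17g", header=header, comments="# ")

    @classmethod
    def load(cls, path, directions: DirectionSet, sigma_deg: float = DEFAULT_SIGMA_DEG):
        """Rebuild a basis from a saved component matrix."""
        comps = np.loadtxt(path, comments="#")
        centered = comps - comps.mean(axis=0, keepdims=True)
        normalized = centered / np.linalg.norm(centered, axis=0, keepdims=True)
        return cls(
            components=comps,
            normalized=normalized,
            directions=directions,
            sigma_deg=sigma_deg,
        )


def build_basis(
    characteristic,
    dirs: DirectionSet,
    sigma_deg: float = DEFAULT_SIGMA_DEG,
) -> ComponentBasis:
    """Build the full component basis by re-centering the characteristic at every axis."""
    values = np.asarray(getattr(characteristic, "values", characteristic), dtype=float)
    if values.shape != (len(dirs),):
        raise ValueError("characteristic length does not match the direction set")
    if values.max() / values.mean() < 1.0 + 1e-6:
        raise DegenerateCharacteristicError("characteristic dODF has no peak")
    grid, p = _axial_profile(values, dirs, sigma_deg)
    theta = axis_angle_matrix(dirs.vectors, dirs.vectors)
    comps = np.interp(theta, grid, p)
    comps = comps / comps.sum(axis=0, keepdims=True)
    centered = comps - comps.mean(axis=0, keepdims=True)
    normalized = centered / np.linalg.norm(centered, axis=0, keepdims=True)
    return ComponentBasis(
        components=comps, normalized=normalized, directions=dirs, sigma_deg=sigma_deg
    )
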