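"""Multi-tensor crossing-fiber signal simulator with Rician noise.

A simulated voxel mixes an isotropic compartment with one or more diffusion
tensors, each representing a coherent fiber population:

    S(b, v) = S(0) * [ f0 * exp(-b v' D0 v) + sum_i f_i * exp(-b v' D_i v) ]

where ``b`` is the diffusion weighting (s/mm^2), ``v`` the unit gradient
direction, ``D0 = d_iso * I`` the isotropic tensor and ``D_i`` axially
symmetric tensors with prescribed fractional anisotropy (FA) and mean
diffusivity (MD).  Magnitude noise is Rician: each clean value S is replaced
by ``sqrt((S + n1)^2 + n2^2)`` with independent Gaussian ``n1, n2``.

The study-level generator sweeps crossing-fiber voxels over grids of volume
fraction, crossing angle and FA.  The two stock configurations mirror a
160-direction b=1500 s/mm^2 shell at b0 SNR 40 (MD 1.0e-3 mm^2/s) and a
55-direction shell at b0 SNR 20 (MD 0.5e-3 mm^2/s); in both the isotropic
fraction is 0.2, the first fiber fraction runs from 0.50 to 0.90 of the
total fiber volume in 40 multiplier steps of 0.01, and crossing angles run
from 18 degrees upward in 40 steps of 1.8 degrees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "BTable",
    "Fiber",
    "VoxelModel",
    "SimulationConfig",
    "SimulationDataset",
    "shell_scheme",
    "grid_scheme",
    "fractional_anisotropy",
    "make_axisymmetric_tensor",
    "crossing_voxel",
    "simulate_signal",
    "add_rician_noise",
    "generate_dataset",
    "simulation1_config",
    "simulation2_config",
]

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class BTable:
    """Per-acquisition diffusion weightings and gradient directions.

    ``bvals`` are in s/mm^2; ``bvecs`` are unit vectors for every b > 0 row
    (the gradient of a b0 row is ignored and may be zero).  At least one b0
    row is required so noise levels can be anchored to the unweighted signal.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.ascontiguousarray(self.bvals, dtype=float).ravel()
        bvecs = np.ascontiguousarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape != (bvals.size, 3):
            raise ValueError("bvecs must be an (n, 3) array matching bvals")
        if np.any(bvals < 0):
            raise ValueError("b-values must be >= 0")
        dwi = bvals > 0
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("gradients must be unit norm where b > 0")
        if not np.any(~dwi):
            raise ValueError("b-table needs at least one b0 row")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_rows(self) -> int:
        return self.bvals.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > 0


def shell_scheme(n_dirs: int, b_value: float, n_b0: int = 1) -> BTable:
    """Single-shell scheme with near-uniform directions on the hemisphere.

    Directions follow a spherical Fibonacci lattice restricted to z > 0,
    which spreads ``n_dirs`` points nearly uniformly (a deterministic stand-in
    for electrostatic-repulsion direction tables).  ``n_b0`` unweighted rows
    are prepended.
    """
    if n_dirs < 1 or n_b0 < 1:
        raise ValueError("need at least one direction and one b0 row")
    i = np.arange(n_dirs)
    z = (i + 0.5) / n_dirs
    phi = i * _GOLDEN_ANGLE
    r = np.sqrt(1.0 - z * z)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b_value))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return BTable(bvals, bvecs)


def grid_scheme(b_max: float, radius: int = 3) -> BTable:
    """Grid (DSI-like) scheme: q-space lattice points in a half ball.

    Integer lattice points q with ``0 < |q|^2 <= radius^2`` are kept, one per
    antipodal pair (first nonzero coordinate positive); the b-value scales as
    ``b_max * |q|^2 / radius^2``.  A single b0 row represents the origin.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    pts = []
    rng = range(-radius, radius + 1)
    for q in itertools.product(rng, rng, rng):
        n2 = q[0] ** 2 + q[1] ** 2 + q[2] ** 2
        if 0 < n2 <= radius * radius:
            nz = next(c for c in q if c != 0)
            if nz > 0:
                pts.append((q, n2))
    bvals = [0.0]
    bvecs = [(0.0, 0.0, 0.0)]
    for q, n2 in sorted(pts):
        bvals.append(float(b_max) * n2 / (radius * radius))
        bvecs.append(tuple(c / np.sqrt(n2) for c in q))
    return BTable(np.array(bvals), np.array(bvecs))


def fractional_anisotropy(eigenvalues: Sequence[float]) -> float:
    """Standard FA of a diffusion tensor from its three eigenvalues."""
    l = np.asarray(eigenvalues, dtype=float)
    if l.shape != (3,):
        raise ValueError("need exactly three eigenvalues")
    num = (l[0] - l[1]) ** 2 + (l[1] - l[2]) ** 2 + (l[2] - l[0]) ** 2
    den = 2.0 * float(l @ l)
    if den == 0:
        return 0.0
    return float(np.sqrt(num / den))


def make_axisymmetric_tensor(fa: float, md: float, axis: np.ndarray) -> np.ndarray:
    """Axially symmetric tensor with given FA, mean diffusivity and principal axis.

    Eigenvalues are ``(md + 2d, md - d, md - d)``; the offset ``d`` is solved
    numerically so the FA formula evaluates exactly to ``fa`` while the mean
    diffusivity stays ``md``.
    """
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must be in [0, 1)")
    if md <= 0:
        raise ValueError("mean diffusivity must be positive")
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    if fa == 0.0:
        return md * np.eye(3)

    def gap(d: float) -> float:
        return fractional_anisotropy((md + 2 * d, md - d, md - d)) - fa

    d = brentq(gap, 0.0, md, xtol=1e-16, rtol=1e-15)
    lam1, lam2 = md + 2 * d, md - d
    return lam2 * np.eye(3) + (lam1 - lam2) * np.outer(axis, axis)


@dataclass(frozen=True)
class Fiber:
    """One fiber population: volume fraction, axis, and diffusion tensor."""

    fraction: float
    axis: np.ndarray
    tensor: np.ndarray

    def __post_init__(self):
        axis = np.asarray(self.axis, dtype=float)
        tensor = np.asarray(self.tensor, dtype=float)
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fiber fraction must be in [0, 1]")
        if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
            raise ValueError("fiber axis must be unit norm")
        if tensor.shape != (3, 3) or np.abs(tensor - tensor.T).max() > 1e-12:
            raise ValueError("tensor must be 3x3 symmetric")
        w, v = np.linalg.eigh(tensor)
        if w[0] < -1e-15:
            raise ValueError("tensor must be positive semidefinite")
        if w[2] - w[1] > 1e-12 and abs(float(v[:, 2] @ axis)) < 1.0 - 1e-9:
            raise ValueError("fiber axis must be the tensor's principal eigenvector")
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "tensor", tensor)


@dataclass(frozen=True)
class VoxelModel:
    """Ground-truth voxel: isotropic background plus fiber tensors."""

    s0: float
    f0: float
    fibers: tuple[Fiber, ...]
    iso_diffusivity: float

    def __post_init__(self):
        object.__setattr__(self, "fibers", tuple(self.fibers))
        total = self.f0 + sum(f.fraction for f in self.fibers)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("volume fractions must sum to 1")
        if self.s0 <= 0 or self.f0 < 0 or self.iso_diffusivity <= 0:
            raise ValueError("invalid baseline, f0, or isotropic diffusivity")

    @property
    def axes(self) -> np.ndarray:
        return np.array([f.axis for f in self.fibers])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([f.fraction for f in self.fibers])


def crossing_voxel(
    f0: float,
    f1: float,
    angle_deg: float,
    fa: float,
    md: float,
    s0: float = 1.0,
    iso_diffusivity: float | None = None,
) -> VoxelModel:
    """Two-fiber crossing voxel: fiber 1 along +x, fiber 2 in the x-y plane.

    ``f2 = 1 - f0 - f1`` fills the remaining volume; both fibers share the
    same FA and mean diffusivity.  A single-fiber voxel is obtained with
    ``f1 = 1 - f0`` (the second fiber drops out).
    """
    f2 = 1.0 - f0 - f1
    if f2 < -1e-12:
        raise ValueError("f0 + f1 exceeds 1")
    f2 = max(f2, 0.0)
    a = np.radians(angle_deg)
    ax1 = np.array([1.0, 0.0, 0.0])
    ax2 = np.array([np.cos(a), np.sin(a), 0.0])
    fibers = [Fiber(f1, ax1, make_axisymmetric_tensor(fa, md, ax1))]
    if f2 > 0:
        fibers.append(Fiber(f2, ax2, make_axisymmetric_tensor(fa, md, ax2)))
    return VoxelModel(
        s0=s0,
        f0=f0,
        fibers=tuple(fibers),
        iso_diffusivity=md if iso_diffusivity is None else iso_diffusivity,
    )


def simulate_signal(model: VoxelModel, btable: BTable) -> np.ndarray:
    """Noise-free diffusion signal of a voxel model, one value per b-table row."""
    b = btable.bvals
    v = btable.bvecs
    atten = model.f0 * np.exp(-b * model.iso_diffusivity * np.einsum("ij,ij->i", v, v))
    for fib in model.fibers:
        atten = atten + fib.fraction * np.exp(-b * np.einsum("ij,jk,ik->i", v, fib.tensor, v))
    return model.s0 * atten


def add_rician_noise(signal: np.ndarray, sigma: float, seed=None) -> np.ndarray:
    """Rician-corrupted magnitude signal: sqrt((S + n1)^2 + n2^2).

    ``seed`` may be an integer or a ``numpy.random.Generator``; ``sigma = 0``
    returns the input unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameter grids for a crossing-fiber simulation study.

    ``f1_grid`` holds absolute first-fiber fractions, ``angle_grid_deg``
    crossing angles, ``fa_values`` the FA shared by both fibers.  The Rician
    noise SD is anchored to the unweighted signal: ``sigma = s0 / b0_snr``
    (set ``b0_snr = inf`` for noise-free data).
    """

    btable: BTable
    f0: float
    f1_grid: tuple[float, ...]
    angle_grid_deg: tuple[float, ...]
    fa_values: tuple[float, ...]
    mean_diffusivity: float
    b0_snr: float
    trials: int
    seed: int = 0
    s0: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "f1_grid", tuple(float(x) for x in self.f1_grid))
        object.__setattr__(self, "angle_grid_deg", tuple(float(x) for x in self.angle_grid_deg))
        object.__setattr__(self, "fa_values", tuple(float(x) for x in self.fa_values))
        if not (self.f1_grid and self.angle_grid_deg and self.fa_values):
            raise ValueError("parameter grids must be nonempty")
        if self.trials < 1:
            raise ValueError("trials must be >= 1")
        if not self.b0_snr > 0:
            raise ValueError("b0_snr must be positive")
        if any(f1 + self.f0 > 1 + 1e-12 for f1 in self.f1_grid):
            raise ValueError("f1 + f0 must not exceed 1")

    @property
    def sigma(self) -> float:
        return 0.0 if np.isinf(self.b0_snr) else self.s0 / self.b0_snr

    @property
    def n_records(self) -> int:
        return len(self.f1_grid) * len(self.angle_grid_deg) * len(self.fa_values) * self.trials


@dataclass
class SimulationDataset:
    """Generated study: noisy signals plus a ground-truth table.

    ``truth`` has one row per signal with columns f0, f1, f2, angle_deg, fa,
    trial and the two fiber axes (ax1_*, ax2_*).
    """

    config: SimulationConfig
    signals: np.ndarray
    truth: pd.DataFrame

    @property
    def truth_axes(self) -> np.ndarray:
        """(n_records, 2, 3) array of the two ground-truth fiber axes."""
        a1 = self.truth[["ax1_x", "ax1_y", "ax1_z"]].to_numpy()
        a2 = self.truth[["ax2_x", "ax2_y", "ax2_z"]].to_numpy()
        return np.stack([a1, a2], axis=1)


def generate_dataset(cfg: SimulationConfig) -> SimulationDataset:
    """Simulate every (f1, angle, FA, trial) combination of a configuration.

    Records are ordered with f1 slowest, then angle, FA, and trial fastest.
    Noise is reproducible from ``cfg.seed``.
    """
    bt = cfg.btable
    b, v = bt.bvals, bt.bvecs
    nf1, nang, nfa = len(cfg.f1_grid), len(cfg.angle_grid_deg), len(cfg.fa_values)
    md = cfg.mean_diffusivity

    e0 = np.exp(-b * md)  # isotropic attenuation (D0 = md * I)
    ax1 = np.array([1.0, 0.0, 0.0])
    e1 = np.empty((nfa, bt.n_rows))
    e2 = np.empty((nfa, nang, bt.n_rows))
    for i_fa, fa in enumerate(cfg.fa_values):
        d1 = make_axisymmetric_tensor(fa, md, ax1)
        e1[i_fa] = np.exp(-b * np.einsum("ij,jk,ik->i", v, d1, v))
        for i_a, ang in enumerate(cfg.angle_grid_deg):
            r = np.radians(ang)
            ax2 = np.array([np.cos(r), np.sin(r), 0.0])
            d2 = make_axisymmetric_tensor(fa, md, ax2)
            e2[i_fa, i_a] = np.exp(-b * np.einsum("ij,jk,ik->i", v, d2, v))

    f1 = np.asarray(cfg.f1_grid)
    f2 = 1.0 - cfg.f0 - f1
    # clean signals, shape (nf1, nang, nfa, n_meas)
    clean = cfg.s0 * (
        cfg.f0 * e0
        + f1[:, None, None, None] * e1[None, None, :, :]
        + f2[:, None, None, None] * np.swapaxes(e2, 0, 1)[None, :, :, :]
    )
    full = np.broadcast_to(
        clean[:, :, :, None, :], (nf1, nang, nfa, cfg.trials, bt.n_rows)
    ).reshape(-1, bt.n_rows)
    rng = np.random.default_rng(cfg.seed)
    signals = add_rician_noise(full, cfg.sigma, seed=rng)

    combos = list(
        itertools.product(
            range(nf1), range(nang), range(nfa), range(cfg.trials)
        )
    )
    i_f1, i_ang, i_fa, trial = (np.array(x) for x in zip(*combos))
    ang = np.asarray(cfg.angle_grid_deg)[i_ang]
    rad = np.radians(ang)
    truth = pd.DataFrame(
        {
            "f0": cfg.f0,
            "f1": f1[i_f1],
            "f2": f2[i_f1],
            "angle_deg": ang,
            "fa": np.asarray(cfg.fa_values)[i_fa],
            "trial": trial,
            "ax1_x": 1.0,
            "ax1_y": 0.0,
            "ax1_z": 0.0,
            "ax2_x": np.cos(rad),
            "ax2_y": np.sin(rad),
            "ax2_z": 0.0,
        }
    )
    return SimulationDataset(config=cfg, signals=signals, truth=truth)


def _study_grids(f0: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """The stock f1 and crossing-angle grids (40 steps each)."""
    mult = 0.50 + 0.01 * np.arange(40)
    f1 = tuple(mult * (1.0 - f0))
    angles = tuple(18.0 + 1.8 * np.arange(40))
    return f1, angles


def simulation1_config(trials: int = 100, seed: int = 0, n_b0: int = 1) -> SimulationConfig:
    """160-direction b=1500 s/mm^2 shell, b0 SNR 40, MD 1.0e-3 mm^2/s, f0 = 0.2."""
    f1, angles = _study_grids(0.2)
    return SimulationConfig(
        btable=shell_scheme(160, 1500.0, n_b0=n_b0),
        f0=0.2,
        f1_grid=f1,
        angle_grid_deg=angles,
        fa_values=(0.4, 0.5, 0.6, 0.7),
        mean_diffusivity=1.0e-3,
        b0_snr=40.0,
        trials=trials,
        seed=seed,
    )


def simulation2_config(trials: int = 100, seed: int = 0, n_b0: int = 1) -> SimulationConfig:
    """55-direction b=1500 s/mm^2 shell, b0 SNR 20, MD 0.5e-3 mm^2/s, f0 = 0.2."""
    f1, angles = _study_grids(0.2)
    return SimulationConfig(
        btable=shell_scheme(55, 1500.0, n_b0=n_b0),
        f0=0.2,
        f1_grid=f1,
        angle_grid_deg=angles,
        fa_values=(0.4, 0.5, 0.6, 0.7),
        mean_diffusivity=0.5e-3,
        b0_snr=20.0,
        trials=trials,
        seed=seed,
    )
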