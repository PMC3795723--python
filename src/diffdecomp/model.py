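"""Model/results interface for decomposing many voxels at once.

:class:`DiffusionDecomposition` is constructed from a stack of per-voxel
diffusion signals and a b-table (or directly from dODFs), carries the
component basis and decomposition parameters, and ``fit()`` returns a
:class:`DecompositionResults` holding the sparse fODF of every voxel along
with diagnostics (iteration counts, residual norms, OLS standard errors of
the active fractions) and a ``summary()`` table.

The heavy loop is vectorised across voxels: correlations with all 321
components are maintained incrementally for the whole batch, so each
selection-decomposition step is a few array operations regardless of the
number of voxels.  The per-voxel OLS refit with negativity pruning runs on
precomputed Gram blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from .decomposition import DecompositionParams
from .geometry import DirectionSet, Peak, find_peaks, reduce_antipodal, tessellate_icosahedron
from .reconstruction import (
    ComponentBasis,
    DEFAULT_RATIO,
    ODF,
    build_basis,
    reconstruct_dodfs,
    select_characteristic,
)
from .simulate import BTable, crossing_voxel, simulate_signal

logger = logging.getLogger(__name__)

__all__ = [
    "DiffusionDecomposition",
    "DecompositionResults",
    "default_directions",
    "single_fiber_basis",
]


def default_directions(frequency: int = 8) -> DirectionSet:
    """The reduced icosahedral direction set ODFs are discretised on (321 axes)."""
    return reduce_antipodal(tessellate_icosahedron(frequency))


def single_fiber_basis(
    btable: BTable,
    dirs: DirectionSet,
    fa: float,
    md: float,
    f0: float = 0.0,
    s0: float = 1.0,
    ratio: float = DEFAULT_RATIO,
    sigma_deg: float = 9.0,
) -> ComponentBasis:
    """Component basis from a synthetic noise-free single-fiber voxel.

    Mirrors picking the most anisotropic voxel of a dataset when the ground
    truth is known: a coherent fiber of the given FA and mean diffusivity
    (plus an optional isotropic background fraction) is simulated, its dODF
    reconstructed, and the basis built from that characteristic profile.
    """
    voxel = crossing_voxel(f0=f0, f1=1.0 - f0, angle_deg=90.0, fa=fa, md=md, s0=s0)
    signal = simulate_signal(voxel, btable)
    dodfs = reconstruct_dodfs(signal[None, :], btable, dirs, ratio=ratio)
    return build_basis(dodfs[0], dirs, sigma_deg=sigma_deg)


class DiffusionDecomposition:
    """Sparse fiber-ODF model for a stack of voxels.

    Parameters
    ----------
    signals : (n_voxels, n_rows) array
        Diffusion signals, one row per voxel, aligned with ``btable``.
    btable : BTable
        Acquisition b-values and gradient directions.
    directions : DirectionSet, optional
        Reduced axis set (default: 321 axes of the frequency-8 tessellation).
    basis : ComponentBasis, optional
        Precomputed component basis.  When omitted, the characteristic dODF
        is selected from the data (highest-anisotropy voxel) at fit time.
    params : DecompositionParams, optional
    ratio : float
        GQI sampling-length ratio.
    """

    def __init__(
        self,
        signals,
        btable: BTable,
        *,
        directions: DirectionSet | None = None,
        basis: ComponentBasis | None = None,
        params: DecompositionParams | None = None,
        ratio: float = DEFAULT_RATIO,
    ):
        self.signals = np.atleast_2d(np.asarray(signals, dtype=float))
        if self.signals.shape[1] != btable.n_rows:
            raise ValueError("signal columns do not match the b-table")
        self.btable = btable
        self.directions = (
            directions
            if directions is not None
            else (basis.directions if basis is not None else default_directions())
        )
        self.basis = basis
        self.params = params or DecompositionParams()
        self.ratio = float(ratio)

    @classmethod
    def from_simulation(cls, dataset, **kwargs) -> "DiffusionDecomposition":
        """Model over a :class:`~diffdecomp.simulate.SimulationDataset`."""
        return cls(dataset.signals, dataset.config.btable, **kwargs)

    @property
    def n_voxels(self) -> int:
        return self.signals.shape[0]

    def fit(self, chunk_size: int = 8192) -> "DecompositionResults":
        """Reconstruct dODFs, resolve the basis, and decompose every voxel."""
        dirs = self.directions
        dodfs = reconstruct_dodfs(self.signals, self.btable, dirs, ratio=self.ratio)
        basis = self.basis
        characteristic_index = None
        if basis is None:
            _, characteristic_index = select_characteristic(dodfs)
            basis = build_basis(dodfs[characteristic_index], dirs)
            logger.info("characteristic dODF from voxel %d", characteristic_index)
        logger.info(
            "decomposing %d voxels (epsilon=%g, m=%d, ratio=%g)",
            self.n_voxels,
            self.params.epsilon,
            self.params.m,
            self.ratio,
        )
        spin = self.signals[:, self.btable.b0_mask].mean(axis=1)
        return _fit_dodfs(
            dodfs, basis, self.params, spin_scales=spin, model=self,
            characteristic_index=characteristic_index, chunk_size=chunk_size,
        )


def _batch_selection(dodfs: np.ndarray, basis: ComponentBasis, params: DecompositionParams):
    """Vectorised selection-decomposition for a batch of dODFs.

    Returns (stamps, n_iterations) where ``stamps[v, i]`` is the iteration at
    which component i first entered voxel v's active set (-1 when never).
    """
    V, n = dodfs.shape
    N = basis.normalized
    G = basis.gram
    centered = dodfs - dodfs.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    scale = np.maximum(np.abs(dodfs).max(axis=1), 1.0)
    live = norms > 1e-12 * scale
    W = np.zeros_like(dodfs)
    W[live] = centered[live] / norms[live, None]
    C = W @ N  # (V, n) correlations, updated incrementally
    stamps = np.full((V, n), -1, dtype=np.int32)
    counts = np.zeros(V, dtype=np.int32)
    iters = np.zeros(V, dtype=np.int32)
    rows = np.flatnonzero(live)
    first = True
    for step in range(params.max_iterations):
        if rows.size == 0:
            break
        Cr = C[rows]
        k = np.argmax(Cr, axis=1)
        cmax = Cr[np.arange(rows.size), k]
        go = (cmax > 0) & (counts[rows] < params.m)
        rows = rows[go]
        if rows.size == 0:
            break
        k = k[go]
        if first and params.adaptive_first and basis.n_components > 1:
            Gk = G[k]  # (r, n)
            denom = 1.0 - Gk
            with np.errstate(divide="ignore", invalid="ignore"):
                steps = (C[rows, k][:, None] - C[rows]) / denom
            steps[denom <= 1e-12] = np.inf
            steps[np.arange(rows.size), k] = np.inf
            eps = np.maximum(steps.min(axis=1), 0.0)
        else:
            Gk = G[k]
            eps = np.full(rows.size, params.epsilon)
        first = False
        C[rows] -= eps[:, None] * Gk
        new = stamps[rows, k] < 0
        stamps[rows[new], k[new]] = iters[rows[new]]
        counts[rows[new]] += 1
        iters[rows] += 1
    else:
        import warnings

        warnings.warn(
            "selection-decomposition hit the iteration cap for some voxels",
            RuntimeWarning,
        )
    return stamps, iters


def _fit_dodfs(
    dodfs: np.ndarray,
    basis: ComponentBasis,
    params: DecompositionParams,
    spin_scales: np.ndarray | None = None,
    model: DiffusionDecomposition | None = None,
    characteristic_index: int | None = None,
    chunk_size: int = 8192,
) -> "DecompositionResults":
    """Decompose a (n_voxels, n_dirs) stack of dODFs into sparse fODFs."""
    V, n = dodfs.shape
    if spin_scales is None:
        spin_scales = np.ones(V)
    # Gram blocks of the raw design [iso | components] for fast subset OLS
    iso = np.full(n, 1.0 / n)
    M = np.concatenate([iso[:, None], basis.components], axis=1)  # (n, n+1)
    GM = M.T @ M

    f0 = np.zeros(V)
    resid = np.zeros(V)
    n_iter = np.zeros(V, dtype=np.int32)
    rows_idx: list[np.ndarray] = []
    rows_val: list[np.ndarray] = []
    rows_err: list[np.ndarray] = []
    active_sets: list[tuple[int, ...]] = []
    indptr = [0]

    for start in range(0, V, chunk_size):
        stop = min(start + chunk_size, V)
        block = dodfs[start:stop]
        stamps, iters = _batch_selection(block, basis, params)
        n_iter[start:stop] = iters
        MtY = M.T @ block.T  # (n+1, chunk)
        yty = np.einsum("ij,ij->i", block, block)
        for v in range(block.shape[0]):
            sel = np.flatnonzero(stamps[v] >= 0)
            order = sel[np.argsort(stamps[v, sel])]
            g_f0, frac_idx, frac_val, err, rn = _prune_ols(
                GM, MtY[:, v], yty[v], order
            )
            scale = 1.0
            total = g_f0 + frac_val.sum()
            if total > 0:
                scale = spin_scales[start + v] / total
            f0[start + v] = g_f0 * scale
            resid[start + v] = rn
            keep = frac_val != 0
            kept_idx = frac_idx[keep]
            kept_val = frac_val[keep] * scale
            kept_err = err[keep] * scale
            srt = np.argsort(kept_idx)
            rows_idx.append(kept_idx[srt])
            rows_val.append(kept_val[srt])
            rows_err.append(kept_err[srt])
            kept = set(int(i) for i in kept_idx)
            active_sets.append(tuple(int(i) for i in order if int(i) in kept))
            indptr.append(indptr[-1] + int(keep.sum()))

    data = np.concatenate(rows_val) if rows_val else np.empty(0)
    errs = np.concatenate(rows_err) if rows_err else np.empty(0)
    indices = np.concatenate(rows_idx) if rows_idx else np.empty(0, dtype=int)
    fractions = sparse.csr_matrix((data, indices, np.array(indptr)), shape=(V, n))
    stderr = sparse.csr_matrix((errs, indices.copy(), np.array(indptr)), shape=(V, n))
    return DecompositionResults(
        model=model,
        basis=basis,
        params=params,
        f0=f0,
        fractions=fractions,
        fraction_stderr=stderr,
        spin_scales=np.asarray(spin_scales, dtype=float),
        n_iterations=n_iter,
        residual_norms=resid,
        active_sets=active_sets,
        characteristic_index=characteristic_index,
    )


def _prune_ols(GM: np.ndarray, Mty: np.ndarray, yty: float, order: np.ndarray):
    """Subset OLS with negativity pruning on precomputed Gram blocks.

    ``order`` lists selected component indices (0-based into the basis); the
    design indexes ``GM``/``Mty`` with 0 = isotropic regressor and i+1 =
    component i.  Returns (f0, component indices, fractions, standard errors,
    residual norm).
    """
    A = [int(i) + 1 for i in order]
    pin_f0 = False
    while True:
        idx = ([] if pin_f0 else [0]) + A
        if not idx:
            coef = np.empty(0)
            rss = yty
            cov = np.empty((0, 0))
            break
        Gs = GM[np.ix_(idx, idx)]
        bs = Mty[idx]
        try:
            coef = np.linalg.solve(Gs, bs)
        except np.linalg.LinAlgError:
            coef, _, _, _ = np.linalg.lstsq(Gs, bs, rcond=None)
        fib = coef if pin_f0 else coef[1:]
        if A and fib.size and fib.min() < 0:
            A.pop(int(np.argmin(fib)))
            continue
        if not pin_f0 and coef.size and coef[0] < 0:
            pin_f0 = True
            continue
        rss = max(yty - float(coef @ bs), 0.0)
        # OLS standard errors from sigma^2 (X'X)^-1; dof = n_obs - n_params
        n_obs = GM.shape[0] - 1  # ODF length equals component count
        dof = max(n_obs - len(idx), 1)
        s2 = rss / dof
        try:
            cov = s2 * np.linalg.inv(Gs)
        except np.linalg.LinAlgError:
            cov = np.full((len(idx), len(idx)), np.nan)
        break
    f0 = 0.0 if pin_f0 or not coef.size else float(coef[0])
    fib = coef if pin_f0 else coef[1:]
    off = 0 if pin_f0 else 1
    err = np.sqrt(np.maximum(np.diag(cov)[off:], 0.0)) if cov.size else np.empty(0)
    frac_idx = np.array([i - 1 for i in A], dtype=int)
    return f0, frac_idx, np.asarray(fib, dtype=float), err, float(np.sqrt(rss))


@dataclass
class DecompositionResults:
    """Fitted sparse fODFs for a stack of voxels.

    ``fractions`` is a CSR matrix (n_voxels x n_axes) of spin-scaled fiber
    volume fractions; ``f0`` the matching isotropic fractions.  Normalised
    (unit-sum) versions divide by ``spin_scales``.
    """

    model: DiffusionDecomposition | None
    basis: ComponentBasis
    params: DecompositionParams
    f0: np.ndarray
    fractions: sparse.csr_matrix
    fraction_stderr: sparse.csr_matrix
    spin_scales: np.ndarray
    n_iterations: np.ndarray
    residual_norms: np.ndarray
    active_sets: list[tuple[int, ...]]
    characteristic_index: int | None = None

    @property
    def n_voxels(self) -> int:
        return self.fractions.shape[0]

    @property
    def directions(self) -> DirectionSet:
        return self.basis.directions

    @property
    def normalized_fractions(self) -> sparse.csr_matrix:
        inv = sparse.diags(1.0 / self.spin_scales)
        return (inv @ self.fractions).tocsr()

    @property
    def normalized_f0(self) -> np.ndarray:
        return self.f0 / self.spin_scales

    @property
    def total_fiber_fraction(self) -> np.ndarray:
        """Per-voxel sum of fiber volume fractions (isotropic excluded), unit-sum scale."""
        return np.asarray(self.normalized_fractions.sum(axis=1)).ravel()

    @property
    def n_fibers(self) -> np.ndarray:
        return np.diff(self.fractions.indptr)

    def voxel_fodf(self, v: int) -> ODF:
        return ODF(
            np.asarray(self.normalized_fractions[v].todense()).ravel(), kind="fiber"
        )

    def peaks(self, min_fraction: float = 0.0) -> list[list[Peak]]:
        """Ranked fODF peaks per voxel (unit-sum fraction scale)."""
        dirs = self.directions
        out = []
        nf = self.normalized_fractions
        for v in range(self.n_voxels):
            row = np.asarray(nf[v].todense()).ravel()
            out.append(find_peaks(row, dirs, min_fraction=min_fraction))
        return out

    def peaks_table(self, min_fraction: float = 0.0) -> pd.DataFrame:
        """Long-format peak table: voxel, rank, axis coordinates, fraction."""
        records = []
        for v, pk in enumerate(self.peaks(min_fraction=min_fraction)):
            for rank, p in enumerate(pk):
                records.append(
                    {
                        "voxel": v,
                        "rank": rank,
                        "axis_index": p.index,
                        "x": p.orientation[0],
                        "y": p.orientation[1],
                        "z": p.orientation[2],
                        "fraction": p.value,
                    }
                )
        return pd.DataFrame(
            records, columns=["voxel", "rank", "axis_index", "x", "y", "z", "fraction"]
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Diffusion decomposition results",
            "=" * 34,
            f"voxels:                {self.n_voxels}",
            f"axes (components):     {self.basis.n_components}",
            f"epsilon:               {self.params.epsilon}",
            f"max active set (m):    {self.params.m}",
            f"adaptive first step:   {self.params.adaptive_first}",
            f"characteristic voxel:  {self.characteristic_index}",
            f"mean iterations:       {self.n_iterations.mean():.1f}",
            f"mean active-set size:  {self.n_fibers.mean():.2f}",
            f"mean isotropic f0:     {self.normalized_f0.mean():.4f}",
            f"mean total fiber frac: {self.total_fiber_fraction.mean():.4f}",
            f"mean residual norm:    {self.residual_norms.mean():.3e}",
        ]
        return "\n".join(lines)
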