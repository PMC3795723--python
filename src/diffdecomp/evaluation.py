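"""Accuracy metrics for resolved fiber orientations and volume fractions.

Covers the simulation-study protocol (two-peak angular error against a
two-fiber ground truth), the sensitivity/specificity matching protocol
(closest-reference angular error with a 45-degree penalty when nothing is
resolved — the expected error of a random orientation), fraction-recovery
correlation per FA level, the total fiber volume fraction map, and a
standard log-linear diffusion-tensor FA fit for comparison maps.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .geometry import axis_angle_matrix

__all__ = [
    "RANDOM_ORIENTATION_PENALTY_DEG",
    "two_peak_angular_error",
    "matched_angular_error",
    "fraction_recovery_correlation",
    "fiber_fraction_estimates",
    "total_fiber_fraction_map",
    "quantitative_anisotropy",
    "tensor_fa",
    "angular_error_report",
]

#: expected angular error of a fiber resolved at a random orientation
RANDOM_ORIENTATION_PENALTY_DEG = 45.0


def _as_axes(axes) -> np.ndarray:
    axes = np.asarray(axes, dtype=float)
    if axes.size == 0:
        return axes.reshape(0, 3)
    return np.atleast_2d(axes)


def two_peak_angular_error(resolved, truth) -> float:
    """Mean deviation of the two most prominent resolved fibers from a crossing.

    ``resolved`` is a prominence-ranked list of axes (may be empty or hold a
    single axis, which then counts as two fibers at the same orientation;
    extra axes beyond the top two are discarded).  ``truth`` holds exactly
    two ground-truth axes.  Resolved and truth fibers are paired so the
    total deviation is minimal; no resolved fiber at all scores the
    random-orientation penalty.
    """
    truth = _as_axes(truth)
    if truth.shape != (2, 3):
        raise ValueError("truth must hold exactly two axes")
    resolved = _as_axes(resolved)
    if resolved.shape[0] == 0:
        return RANDOM_ORIENTATION_PENALTY_DEG
    if resolved.shape[0] == 1:
        resolved = np.vstack([resolved, resolved])
    top2 = resolved[:2]
    ang = axis_angle_matrix(top2, truth)
    direct = ang[0, 0] + ang[1, 1]
    crossed = ang[0, 1] + ang[1, 0]
    return float(min(direct, crossed) / 2.0)


def matched_angular_error(
    query_fibers, reference_fibers, penalty: float = RANDOM_ORIENTATION_PENALTY_DEG
) -> np.ndarray:
    """Per-query-fiber angular error against the closest reference fiber.

    Sensitivity mode queries the full-scheme fibers against the
    reduced-scheme fibers; specificity mode the converse.  An empty
    reference assigns the penalty to every query fiber.
    """
    query = _as_axes(query_fibers)
    reference = _as_axes(reference_fibers)
    if query.shape[0] == 0:
        return np.empty(0)
    if reference.shape[0] == 0:
        return np.full(query.shape[0], float(penalty))
    return np.minimum(axis_angle_matrix(query, reference).min(axis=1), float(penalty))


def fiber_fraction_estimates(fractions, directions, truth_axes) -> np.ndarray:
    """Per-voxel estimated volume fraction of each ground-truth fiber.

    Every nonzero fODF component is assigned to the nearer of the voxel's
    two true axes (by axis angle) and the fractions are summed per fiber.
    ``fractions`` is an (n_voxels, n_axes) sparse or dense matrix on the
    unit-sum scale; ``truth_axes`` is (n_voxels, 2, 3).
    """
    truth_axes = np.asarray(truth_axes, dtype=float)
    V = truth_axes.shape[0]
    mat = sparse.csr_matrix(fractions)
    if mat.shape[0] != V:
        raise ValueError("fractions and truth_axes disagree on voxel count")
    axes = directions.vectors
    est = np.zeros((V, 2))
    indptr, indices, data = mat.indptr, mat.indices, mat.data
    for v in range(V):
        lo, hi = indptr[v], indptr[v + 1]
        if lo == hi:
            continue
        comp_axes = axes[indices[lo:hi]]
        ang = axis_angle_matrix(comp_axes, truth_axes[v])  # (k, 2)
        nearer = np.argmin(ang, axis=1)
        np.add.at(est[v], nearer, data[lo:hi])
    return est


def fraction_recovery_correlation(estimates, truths, group_by_fa=None):
    """Pearson correlation between estimated and true fiber volume fractions.

    Both fibers of every voxel are pooled as separate observations.  With
    ``group_by_fa`` (a per-observation FA array) a dict of per-FA
    correlations is returned, else a single float.  Constant input raises.
    """
    est = np.asarray(estimates, dtype=float).ravel()
    tru = np.asarray(truths, dtype=float).ravel()
    if est.shape != tru.shape:
        raise ValueError("estimates and truths must have equal length")

    def _r(e, t):
        if np.ptp(e) == 0 or np.ptp(t) == 0:
            raise ValueError("correlation undefined for constant input")
        return float(stats.pearsonr(e, t).statistic)

    if group_by_fa is None:
        return _r(est, tru)
    fa = np.asarray(group_by_fa, dtype=float).ravel()
    if fa.shape != est.shape:
        raise ValueError("group_by_fa must match the observations")
    return {float(v): _r(est[fa == v], tru[fa == v]) for v in np.unique(fa)}


def total_fiber_fraction_map(results, normalize: bool = False) -> np.ndarray:
    """Per-voxel sum of fiber volume fractions, isotropic background excluded.

    ``results`` may be a fitted :class:`~diffdecomp.model.DecompositionResults`
    or an (n_voxels, n_axes) fraction matrix.  ``normalize`` rescales the map
    so its maximum is one.
    """
    if hasattr(results, "total_fiber_fraction"):
        out = np.asarray(results.total_fiber_fraction, dtype=float).copy()
    else:
        mat = sparse.csr_matrix(results)
        out = np.asarray(mat.sum(axis=1)).ravel()
    if normalize and out.max() > 0:
        out /= out.max()
    return out


def quantitative_anisotropy(odf) -> float:
    """QA-like score: peak value minus the isotropic floor of a dODF."""
    v = np.asarray(getattr(odf, "values", odf), dtype=float)
    return float(v.max() - v.min())


def tensor_fa(signal, btable) -> float:
    """Fractional anisotropy from a log-linear least-squares tensor fit.

    Requires at least six diffusion-weighted rows spanning gradient space.
    The design regresses log-signal on the six tensor elements plus an
    intercept (log baseline); FA is clipped to [0, 1].
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.size != btable.n_rows:
        raise ValueError("signal length does not match the b-table")
    if np.any(signal <= 0):
        raise ValueError("log-linear fit needs strictly positive signals")
    b = btable.bvals
    g = btable.bvecs
    design = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    if np.count_nonzero(btable.dwi_mask) < 6 or np.linalg.matrix_rank(design) < 7:
        raise ValueError("gradient design is rank deficient for a tensor fit")
    coef, _, _, _ = np.linalg.lstsq(design, np.log(signal), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = coef[1:]
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    lam = np.linalg.eigvalsh(D)
    num = (lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[2] - lam[0]) ** 2
    den = 2.0 * float(lam @ lam)
    if den == 0:
        return 0.0
    return float(np.clip(np.sqrt(num / den), 0.0, 1.0))


def angular_error_report(
    peaks_per_voxel, truth: pd.DataFrame, min_fraction: float = 0.0
) -> pd.DataFrame:
    """Per-voxel two-peak angular error joined onto the ground-truth table.

    ``peaks_per_voxel`` is a list of ranked peak lists (as produced by
    ``DecompositionResults.peaks``); ``truth`` must carry the ax1_*/ax2_*
    columns of a simulated dataset.  Deviations are in [0, 90] and the
    no-fiber penalty is exactly 45.
    """
    a1 = truth[["ax1_x", "ax1_y", "ax1_z"]].to_numpy()
    a2 = truth[["ax2_x", "ax2_y", "ax2_z"]].to_numpy()
    errors = np.empty(len(peaks_per_voxel))
    n_peaks = np.empty(len(peaks_per_voxel), dtype=int)
    for v, pk in enumerate(peaks_per_voxel):
        axes = [p.orientation for p in pk if p.value >= min_fraction]
        n_peaks[v] = len(axes)
        errors[v] = two_peak_angular_error(axes, np.vstack([a1[v], a2[v]]))
    out = truth.copy()
    out["n_peaks"] = n_peaks
    out["angular_error_deg"] = errors
    return out
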