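"""Sparse fODF estimation: nonnegative forward-stagewise selection and OLS refit.

The fiber ODF is modelled as a nonnegative, sparse combination of the
component dODFs plus an isotropic background.  Working in the normalised
space (every vector shifted to zero mean and scaled to unit norm, which
removes the isotropic term), the algorithm repeats two moves:

* selection  — pick the component most positively correlated with the
  current working vector, ``k = argmax_i <Psi_i, Psi_d>``;
* decomposition — peel a small volume off the working vector,
  ``Psi_d <- Psi_d - eps * Psi_k``.

The recursion stops when the best correlation drops to zero or the set of
distinct selected components reaches ``m`` (default 10).  The very first
step may use an adaptive fraction — the smallest step along the winner
after which some other component ties it, the least-angle-regression step —
which skips the long run of repeated selections of the dominant component.

Volume fractions are then estimated by ordinary least squares of the *raw*
dODF on the isotropic regressor plus the selected raw components, pruning
negative fiber fractions one at a time (most negative first) and pinning a
negative isotropic fraction to zero, refitting until all fractions are
nonnegative.  Fractions are finally rescaled so their sum matches the spin
density proxy (the voxel's b0 signal); the unit-sum version is kept for
evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .reconstruction import ComponentBasis, ODF, reconstruct_dodf

__all__ = [
    "DecompositionParams",
    "DecompositionResult",
    "DegenerateODFError",
    "normalize_dodf",
    "select_component",
    "adaptive_first_fraction",
    "selection_decomposition",
    "estimate_fractions",
    "diffusion_decomposition",
]

_DEGENERATE_TOL = 1e-12


class DegenerateODFError(ValueError):
    """Raised when a constant (purely isotropic) dODF cannot be normalised."""


@dataclass(frozen=True)
class DecompositionParams:
    """Tunable knobs of the decomposition recursion.

    epsilon : decomposition fraction peeled off per step (default 0.05)
    m : maximum number of distinct components in the active set (default 10)
    adaptive_first : use the least-angle step for the first decomposition
    max_iterations : safety cap on selection-decomposition steps
    """

    epsilon: float = 0.05
    m: int = 10
    adaptive_first: bool = True
    max_iterations: int = 10_000

    def __post_init__(self):
        if not 0.0 < self.epsilon <= 1.0:
            raise ValueError("epsilon must be in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class DecompositionResult:
    """Sparse fODF of one voxel.

    ``f0`` and ``fractions`` are scaled so that ``f0 + fractions.sum()``
    equals the spin-density proxy (``spin_scale``; 1 when decomposing a bare
    dODF).  ``normalized_f0``/``normalized_fractions`` give the unit-sum
    version used for evaluation.
    """

    f0: float
    fractions: np.ndarray
    active_set: tuple[int, ...]
    n_iterations: int
    spin_scale: float
    residual_norm: float = float("nan")

    @property
    def normalized_fractions(self) -> np.ndarray:
        return self.fractions / self.spin_scale

    @property
    def normalized_f0(self) -> float:
        return self.f0 / self.spin_scale

    @property
    def total_fiber_fraction(self) -> float:
        """Sum of the fiber volume fractions, isotropic background excluded."""
        return float(self.normalized_fractions.sum())

    @property
    def fodf(self) -> ODF:
        return ODF(self.normalized_fractions, kind="fiber")


def normalize_dodf(dodf) -> np.ndarray:
    """Shift to zero mean and scale to unit Euclidean norm.

    Raises :class:`DegenerateODFError` for a constant vector (pure isotropy),
    for which the decomposition short-circuits to an isotropic-only result.
    """
    v = np.asarray(getattr(dodf, "values", dodf), dtype=float)
    centered = v - v.mean()
    norm = np.linalg.norm(centered)
    scale = float(np.abs(v).max())
    if norm <= _DEGENERATE_TOL * max(scale, 1.0):
        raise DegenerateODFError("constant dODF has no normalised form")
    return centered / norm


def select_component(psi_d: np.ndarray, basis: ComponentBasis) -> int | None:
    """Most positively correlated component, or None when all correlations <= 0."""
    c = basis.normalized.T @ np.asarray(psi_d, dtype=float)
    k = int(np.argmax(c))
    return k if c[k] > 0 else None


def adaptive_first_fraction(psi_d: np.ndarray, basis: ComponentBasis, k: int) -> float:
    """Least-angle step: smallest fraction after which another component ties k.

    Solving ``c_k - eps = c_i - eps * G_ik`` for each competitor gives
    ``eps_i = (c_k - c_i) / (1 - G_ik)``; the adaptive fraction is the
    minimum over all components that are not collinear with k.
    """
    if basis.n_components < 2:
        raise ValueError("adaptive fraction needs at least two components")
    c = basis.normalized.T @ np.asarray(psi_d, dtype=float)
    g = basis.gram[:, k]
    denom = 1.0 - g
    ok = np.ones(basis.n_components, dtype=bool)
    ok[k] = False
    ok &= denom > 1e-12
    if not np.any(ok):
        raise ValueError("no competitor component is distinguishable from k")
    eps = (c[k] - c[ok]) / denom[ok]
    return float(max(eps.min(), 0.0))


def selection_decomposition(
    dodf, basis: ComponentBasis, params: DecompositionParams | None = None
) -> tuple[tuple[int, ...], np.ndarray, int]:
    """Run the selection-decomposition recursion on one dODF.

    Returns the ordered active set (order of first selection), the final
    working vector, and the number of iterations.  A degenerate (constant)
    dODF yields an empty active set.
    """
    params = params or DecompositionParams()
    try:
        w = normalize_dodf(dodf)
    except DegenerateODFError:
        n = basis.n_components
        return (), np.zeros(n), 0
    c = basis.normalized.T @ w
    active: list[int] = []
    n_iter = 0
    first = True
    while n_iter < params.max_iterations:
        k = int(np.argmax(c))
        if c[k] <= 0 or len(active) >= params.m:
            break
        if first and params.adaptive_first and basis.n_components > 1:
            eps = adaptive_first_fraction(w, basis, k)
        else:
            eps = params.epsilon
        first = False
        w = w - eps * basis.normalized[:, k]
        c = c - eps * basis.gram[:, k]
        if k not in active:
            active.append(k)
        n_iter += 1
    else:
        warnings.warn(
            "selection-decomposition hit the iteration cap; result may be truncated",
            RuntimeWarning,
        )
    return tuple(active), w, n_iter


def _ols(cols: list[np.ndarray], y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares coefficients and residual norm for a small design."""
    if not cols:
        return np.empty(0), float(np.linalg.norm(y))
    X = np.column_stack(cols)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return coef, float(np.linalg.norm(y - X @ coef))


def estimate_fractions(
    dodf, basis: ComponentBasis, active, return_residual: bool = False
):
    """OLS volume fractions with iterative negativity pruning.

    Fits the raw dODF on the uniform isotropic regressor plus the raw
    components of the active set; while any fiber fraction is negative the
    most negative one is removed and the fit repeated; a negative isotropic
    fraction is pinned to zero (and fiber pruning re-checked) until stable.
    Components outside the final active set get fraction zero.
    """
    y = np.asarray(getattr(dodf, "values", dodf), dtype=float)
    n = basis.n_components
    iso = np.full(n, 1.0 / n)
    A = [int(i) for i in active]
    pin_f0 = False
    while True:
        cols = ([] if pin_f0 else [iso]) + [basis.components[:, j] for j in A]
        coef, resid = _ols(cols, y)
        f0 = 0.0 if pin_f0 else (float(coef[0]) if coef.size else 0.0)
        fib = coef if pin_f0 else coef[1:]
        if A and fib.size and fib.min() < 0:
            A.pop(int(np.argmin(fib)))
            continue
        if not pin_f0 and f0 < 0:
            pin_f0 = True
            continue
        break
    fractions = np.zeros(n)
    if A:
        fractions[A] = fib
    if return_residual:
        return f0, fractions, resid
    return f0, fractions


def diffusion_decomposition(
    data,
    basis: ComponentBasis,
    params: DecompositionParams | None = None,
    btable=None,
    ratio: float | None = None,
) -> DecompositionResult:
    """Full per-voxel pipeline: (signal or dODF) -> sparse fODF.

    When ``btable`` is given, ``data`` is a signal vector: the dODF is
    reconstructed first and the mean b0 signal becomes the spin-density
    proxy to which the fractions are scaled.  Otherwise ``data`` is a dODF
    and the scale is 1.
    """
    params = params or DecompositionParams()
    if btable is not None:
        signal = np.asarray(data, dtype=float).ravel()
        kwargs = {} if ratio is None else {"ratio": ratio}
        dodf = reconstruct_dodf(signal, btable, basis.directions, **kwargs)
        spin = float(signal[btable.b0_mask].mean())
    else:
        dodf = data
        spin = 1.0
    active, _, n_iter = selection_decomposition(dodf, basis, params)
    f0, fractions, resid = estimate_fractions(dodf, basis, active, return_residual=True)
    total = f0 + fractions.sum()
    if total > 0:
        scale = spin / total
        f0 *= scale
        fractions = fractions * scale
    final_active = tuple(i for i in active if fractions[i] != 0)
    return DecompositionResult(
        f0=f0,
        fractions=fractions,
        active_set=final_active,
        n_iterations=n_iter,
        spin_scale=spin,
        residual_norm=resid,
    )
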