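"""Single-tissue constrained spherical deconvolution and the split-half
gold-standard consistency procedure.

The reference FODs that stand in for a full multi-tissue reconstruction are
obtained by deconvolving a measured axially-symmetric single-fiber response
from the multi-shell signal, under a non-negativity constraint enforced on
a symmetrized sphere grid.  On the sphere, convolution with a zonal kernel
is diagonal in the SH basis: a signal generated by an FOD ``f`` satisfies
``s_lm(b) = sqrt(4*pi/(2l+1)) * r_l(b) * f_lm`` where ``r_l(b)`` are the
per-shell zonal SH coefficients of the response.

Non-negativity on the constraint grid is enforced exactly: the quadratic
program ``min ||M c - s||^2  s.t.  B c >= 0`` is reduced, through a
Cholesky factor of the normal matrix, to a least-distance problem and
solved with the Lawson-Hanson NNLS transformation.  Voxels whose solve
fails (numerically infeasible) fall back to their isotropic part and are
counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import nnls

from .dti_masks import fit_tensor
from .metrics_eval import MetricsReport, evaluate
from .sh_core import (
    PeakParams,
    SHCoefficientField,
    build_sh_basis,
    make_symmetric_grid,
    n_coeffs_for_lmax,
    sh_degrees,
)
from .synthetic_cohort import GradientScheme

__all__ = [
    "ResponseFunction",
    "estimate_response",
    "csd_fit",
    "split_half_consistency",
    "split_measurements",
]

DEFAULT_CSD_LMAX = 8
CONSTRAINT_GRID_POINTS = 724  # grid where non-negativity is enforced exactly
MAX_CSD_ITER = 50


@dataclass
class ResponseFunction:
    """Per-shell zonal (m=0) even-order SH coefficients of the normalized
    single-fiber signal, axially symmetric about +z.

    ``zonal[b]`` has one entry per even order l = 0, 2, ..., lmax.
    """

    zonal: dict[float, np.ndarray]
    lmax: int

    def __post_init__(self):
        for b, z in self.zonal.items():
            if len(z) != self.lmax // 2 + 1:
                raise ValueError(f"shell {b}: expected {self.lmax // 2 + 1} zonal coefficients")
            if z[0] <= 0:
                raise ValueError(f"shell {b}: order-0 zonal coefficient must be positive")


def _zonal_design(cos_theta: np.ndarray, lmax: int) -> np.ndarray:
    """Matrix of Y_l0(theta) for even l, evaluated at cos(theta)."""
    d = np.stack(
        [np.sqrt(np.maximum(0.0, 1 - cos_theta**2)), np.zeros_like(cos_theta), cos_theta],
        axis=-1,
    )
    B = build_sh_basis(d, lmax)
    ls, ms = sh_degrees(lmax)
    return B[:, ms == 0]


def estimate_response(
    dwi: np.ndarray,
    scheme: GradientScheme,
    single_fiber_mask: np.ndarray,
    lmax: int = DEFAULT_CSD_LMAX,
    min_voxels: int = 20,
) -> ResponseFunction:
    """Estimate the single-fiber response from known single-fiber voxels.

    Each voxel's signal is reoriented so its tensor principal eigenvector
    maps to +z (equivalently, expressed as a function of the angle between
    the gradient and the fiber); a zonal SH fit per shell pools all voxels.
    Signals are normalized by the voxelwise mean b=0 signal.
    """
    mask = np.asarray(single_fiber_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty single-fiber mask")
    if mask.sum() < min_voxels:
        raise ValueError(f"need >= {min_voxels} single-fiber voxels, got {int(mask.sum())}")
    dwi = np.asarray(dwi, dtype=float)
    fit = fit_tensor(dwi, scheme)
    evals, evecs = np.linalg.eigh(fit.tensors[mask])
    e1 = evecs[..., -1]  # principal eigenvector, (n, 3)
    b0 = dwi[mask][:, scheme.b0_mask].mean(axis=1)
    s = dwi[mask] / np.maximum(b0, 1e-12)[:, None]
    zonal = {}
    for b in scheme.shells():
        idx = scheme.shell_indices(b)
        cos_t = np.clip(e1 @ scheme.bvecs[idx].T, -1.0, 1.0)  # (n, n_dirs)
        Z = _zonal_design(cos_t.ravel(), lmax)
        vals = s[:, idx].ravel()
        coef, *_ = np.linalg.lstsq(Z, vals, rcond=None)
        zonal[b] = coef
    return ResponseFunction(zonal=zonal, lmax=lmax)


def _convolution_design(scheme: GradientScheme, response: ResponseFunction, lmax: int) -> np.ndarray:
    """Forward matrix mapping FOD SH coefficients to normalized signals."""
    ls, _ = sh_degrees(lmax)
    M = np.zeros((len(scheme), n_coeffs_for_lmax(lmax)))
    # only diffusion-weighted rows enter the deconvolution (b=0 volumes are
    # used for normalization, the usual single-tissue convention); zero rows
    # give b=0 measurements no weight in the fit
    for b in scheme.shells():
        idx = scheme.shell_indices(b)
        Y = build_sh_basis(scheme.bvecs[idx], lmax)
        factors = np.sqrt(4 * np.pi / (2 * ls + 1)) * response.zonal[b][ls // 2]
        M[idx] = Y * factors
    return M


def _solve_ldp(G: np.ndarray, h: np.ndarray) -> np.ndarray | None:
    """Least-distance program: min ||x|| s.t. G x >= h (Lawson-Hanson).

    Returns None if numerically infeasible.
    """
    m, n = G.shape
    E = np.vstack([G.T, h[None, :]])  # (n+1, m)
    f = np.zeros(n + 1)
    f[-1] = 1.0
    u, _ = nnls(E, f)
    r = E @ u - f
    if abs(r[-1]) < 1e-12:
        return None
    return -r[:n] / r[-1]


def csd_fit(
    dwi: np.ndarray,
    scheme: GradientScheme,
    response: ResponseFunction,
    lmax: int = DEFAULT_CSD_LMAX,
    mask: np.ndarray | None = None,
    constraint_points: int = CONSTRAINT_GRID_POINTS,
    lambda_reg: float = 1.0,
    max_iter: int = MAX_CSD_ITER,
) -> tuple[SHCoefficientField, int]:
    """Constrained spherical deconvolution of a DWI volume.

    Per voxel solves ``min ||M c - s||^2 + reg  s.t.  B c >= 0`` on the
    constraint grid, where ``reg`` is a light Laplace-Beltrami damping term
    scaled by ``lambda_reg`` that stabilizes orders the measurements barely
    constrain.  Returns the FOD field (zeros outside ``mask``) and the
    number of voxels that failed and fell back to their isotropic part.
    """
    dwi = np.asarray(dwi, dtype=float)
    grid_shape = dwi.shape[:-1]
    ncoef = n_coeffs_for_lmax(lmax)
    if len(scheme) < ncoef:
        raise ValueError(f"{len(scheme)} measurements cannot support lmax={lmax}")
    mask = np.ones(grid_shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
    M = _convolution_design(scheme, response, lmax)
    cgrid = make_symmetric_grid(constraint_points)
    B = build_sh_basis(cgrid.directions, lmax)  # (g, c)
    ls, _ = sh_degrees(lmax)
    # light high-order damping; scale relative to the data term
    lb_scale = lambda_reg * 1e-4 * np.trace(M.T @ M) / ncoef
    Q = M.T @ M + lb_scale * np.diag((ls * (ls + 1.0) / (lmax * (lmax + 1.0))) ** 2)
    L = np.linalg.cholesky(Q)
    # constraint matrix in the whitened variable d = L^T c
    A = solve_triangular(L, B.T, lower=True).T  # = B L^{-T}
    b0 = dwi[..., scheme.b0_mask].mean(axis=-1)
    S = dwi / np.maximum(b0, 1e-12)[..., None]
    svox = S[mask]  # (n, m)
    rhs_all = svox @ M  # (n, c)
    w_all = solve_triangular(L, rhs_all.T, lower=True).T  # (n, c)
    coeffs = np.zeros_like(rhs_all)
    n_failed = 0
    for v in range(svox.shape[0]):
        w = w_all[v]
        e = _solve_ldp(A, -(A @ w))
        if e is None:
            n_failed += 1
            c = np.zeros(ncoef)
            c[0] = max(rhs_all[v][0] / Q[0, 0], 0.0)
        else:
            c = solve_triangular(L.T, e + w, lower=False)
        coeffs[v] = c
    out = np.zeros(grid_shape + (ncoef,))
    out[mask] = coeffs
    return SHCoefficientField(lmax=lmax, coefficients=out), n_failed


def split_measurements(scheme: GradientScheme, randomized: bool = False, seed: int | None = None):
    """Partition the non-b0 measurements into two interleaved halves.

    Deterministic by default: within each shell, measurements sorted by
    index alternate between the halves; b=0 volumes are shared by both.
    """
    b0_idx = np.nonzero(scheme.b0_mask)[0]
    half_a, half_b = [], []
    order_rng = np.random.default_rng(seed) if randomized else None
    for b in scheme.shells():
        idx = np.sort(scheme.shell_indices(b))
        if order_rng is not None:
            idx = order_rng.permutation(idx)
        half_a += list(idx[0::2])
        half_b += list(idx[1::2])
    a = np.concatenate([b0_idx, np.sort(half_a)]).astype(int)
    b = np.concatenate([b0_idx, np.sort(half_b)]).astype(int)
    return a, b


def _subscheme(scheme: GradientScheme, idx: np.ndarray) -> GradientScheme:
    return GradientScheme(scheme.bvals[idx], scheme.bvecs[idx], scheme.shell_tol)


def split_half_consistency(
    dwi: np.ndarray,
    scheme: GradientScheme,
    response: ResponseFunction,
    wm_mask: np.ndarray,
    lmax: int = DEFAULT_CSD_LMAX,
    peak_params: PeakParams = PeakParams(),
    randomized: bool = False,
    seed: int | None = None,
) -> MetricsReport:
    """Gold-standard consistency: CSD on two disjoint measurement halves,
    compared with the AR/AE/AFD metric suite."""
    n_dw = int((~scheme.b0_mask).sum())
    if n_dw < 2 * n_coeffs_for_lmax(lmax):
        raise ValueError(
            f"{n_dw} DW measurements cannot support two lmax={lmax} reconstructions"
        )
    ia, ib = split_measurements(scheme, randomized=randomized, seed=seed)
    fod_a, _ = csd_fit(dwi[..., ia], _subscheme(scheme, ia), response, lmax=lmax, mask=wm_mask)
    fod_b, _ = csd_fit(dwi[..., ib], _subscheme(scheme, ib), response, lmax=lmax, mask=wm_mask)
    return evaluate(fod_a, fod_b, wm_mask, peak_params)
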