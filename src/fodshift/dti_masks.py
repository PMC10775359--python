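"""Diffusion-tensor fitting, FA/MD maps, white-matter mask rules, and the
arctan growth analysis of mean WM FA versus age.

The tensor is fit by log-linear least squares on the b <= 1000 s/mm^2
measurements (the Gaussian-diffusion regime).  Two mask rules are provided,
named after the cohorts whose pipelines they emulate:

* ``dhcp``: tissue mask OR (FA > 0.3)
* ``bcp``:  tissue mask OR (FA > 0.4) OR (FA > 0.15 AND MD > 0.0011 mm^2/s)

with strict inequalities throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .synthetic_cohort import AgeModel, GradientScheme

__all__ = [
    "MaskRule",
    "TensorFitResult",
    "ArctanFit",
    "fit_tensor",
    "compute_fa_md",
    "build_wm_mask",
    "mean_wm_fa",
    "fit_arctan_growth",
]

B_MAX_TENSOR = 1000.0  # s/mm^2; shells used for the tensor fit
_MIN_SIGNAL = 1e-10


@dataclass(frozen=True)
class MaskRule:
    """WM-mask thresholds; strict '>' comparisons."""

    name: str  # "dhcp" | "bcp"
    fa_dhcp: float = 0.3
    fa_bcp: float = 0.4
    fa_low: float = 0.15
    md_low: float = 0.0011  # mm^2/s

    def __post_init__(self):
        if self.name not in ("dhcp", "bcp"):
            raise ValueError("rule name must be 'dhcp' or 'bcp'")
        if min(self.fa_dhcp, self.fa_bcp, self.fa_low, self.md_low) <= 0:
            raise ValueError("thresholds must be strictly positive")


@dataclass
class TensorFitResult:
    """Per-voxel symmetric tensors (mm^2/s) with fit bookkeeping."""

    tensors: np.ndarray  # (..., 3, 3)
    log_s0: np.ndarray  # (...,)
    n_clamped: int  # non-positive signals clamped before the log


def _tensor_design(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    g = bvecs
    return np.column_stack(
        [
            np.ones(len(bvals)),
            -bvals * g[:, 0] ** 2,
            -bvals * g[:, 1] ** 2,
            -bvals * g[:, 2] ** 2,
            -2 * bvals * g[:, 0] * g[:, 1],
            -2 * bvals * g[:, 0] * g[:, 2],
            -2 * bvals * g[:, 1] * g[:, 2],
        ]
    )


def fit_tensor(dwi: np.ndarray, scheme: GradientScheme, b_max: float = B_MAX_TENSOR) -> TensorFitResult:
    """Log-linear least-squares tensor fit.

    Requires at least six distinct-direction diffusion-weighted measurements
    plus one b=0; raises on a rank-deficient (e.g. coplanar) direction set.
    Non-positive signals are clamped to a tiny value and counted.
    """
    dwi = np.asarray(dwi, dtype=float)
    use = scheme.bvals <= b_max + scheme.shell_tol
    bvals = scheme.bvals[use]
    bvecs = scheme.bvecs[use]
    dw = bvals > scheme.shell_tol
    if dw.sum() < 6 or (~dw).sum() < 1:
        raise ValueError("tensor fit needs >= 6 DW measurements and >= 1 b=0")
    W = _tensor_design(bvals, bvecs)
    if np.linalg.matrix_rank(W) < 7:
        raise ValueError("gradient directions are degenerate (rank-deficient design)")
    S = dwi[..., use]
    n_clamped = int(np.sum(S <= 0))
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} non-positive signals before log", stacklevel=2)
        S = np.maximum(S, _MIN_SIGNAL)
    y = np.log(S)
    coef, *_ = np.linalg.lstsq(W, y.reshape(-1, W.shape[0]).T, rcond=None)
    coef = coef.T.reshape(y.shape[:-1] + (7,))
    D = np.empty(y.shape[:-1] + (3, 3))
    D[..., 0, 0] = coef[..., 1]
    D[..., 1, 1] = coef[..., 2]
    D[..., 2, 2] = coef[..., 3]
    D[..., 0, 1] = D[..., 1, 0] = coef[..., 4]
    D[..., 0, 2] = D[..., 2, 0] = coef[..., 5]
    D[..., 1, 2] = D[..., 2, 1] = coef[..., 6]
    return TensorFitResult(tensors=D, log_s0=coef[..., 0], n_clamped=n_clamped)


def compute_fa_md(tensors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """FA and MD from tensor eigenvalues (clipped at zero for the metrics).

    The all-zero tensor maps to FA = 0, MD = 0 by convention.
    """
    tensors = np.asarray(tensors, dtype=float)
    evals = np.linalg.eigvalsh(tensors)
    evals = np.clip(evals, 0.0, None)
    md = evals.mean(axis=-1)
    num = np.sqrt(((evals - md[..., None]) ** 2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0), md


def build_wm_mask(fa_map, md_map, tissue_mask, rule: MaskRule) -> np.ndarray:
    """Apply a cohort mask rule; all maps must share one grid."""
    fa = np.asarray(fa_map)
    md = np.asarray(md_map)
    tissue = np.asarray(tissue_mask, dtype=bool)
    if not (fa.shape == md.shape == tissue.shape):
        raise ValueError("FA, MD and tissue mask shapes differ")
    if rule.name == "dhcp":
        return tissue | (fa > rule.fa_dhcp)
    return tissue | (fa > rule.fa_bcp) | ((fa > rule.fa_low) & (md > rule.md_low))


def mean_wm_fa(fa_map, wm_mask) -> float:
    """Arithmetic mean FA over mask voxels."""
    mask = np.asarray(wm_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty WM mask")
    return float(np.asarray(fa_map)[mask].mean())


@dataclass
class ArctanFit:
    """Fitted growth curve with diagnostics."""

    model: AgeModel
    residual_rms: float
    degenerate: bool  # near-flat data: b (or a) pinned at its lower bound
    n_points: int


def _arctan(t, a, b, t0, d):
    return a * np.arctan(b * (t - t0)) + d


def fit_arctan_growth(ages, mean_fas, n_starts: int = 12) -> ArctanFit:
    """Nonlinear least squares of FA(t) = a*arctan(b*(t - t0)) + d.

    Multi-start initialization over a grid of slopes and inflection ages;
    the best converged start (lowest residual RMS) wins.  Near-constant data
    drives b toward zero and is flagged as degenerate rather than an error.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(mean_fas, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("ages and mean_fas must be 1-D arrays of equal length")
    if len(t) < 8:
        raise ValueError("need at least 8 (age, FA) points")
    span = np.ptp(t) if np.ptp(t) > 0 else 1.0
    b_grid = [4.0 / span, 0.4 / span, 0.04 / span]
    t0_grid = np.quantile(t, [0.2, 0.5, 0.8])
    amp0 = max(np.ptp(y) / np.pi * 2, 1e-3)
    lo = [1e-6, 1e-6, t.min() - 2 * span, -1.0]
    hi = [2.0, 1e3, t.max() + 2 * span, 2.0]
    best = None
    for b0 in b_grid:
        for t00 in t0_grid:
            p0 = [amp0, b0, t00, float(np.median(y))]
            try:
                popt, _ = curve_fit(_arctan, t, y, p0=p0, bounds=(lo, hi), maxfev=20000)
            except (RuntimeError, ValueError):
                continue
            rms = float(np.sqrt(np.mean((_arctan(t, *popt) - y) ** 2)))
            if best is None or rms < best[0]:
                best = (rms, popt)
    if best is None:
        raise RuntimeError("arctan growth fit failed to converge from any start")
    rms, popt = best
    a, b, t0, d = (float(v) for v in popt)
    degenerate = (a * b * span) < 1e-3 or b <= 2e-6 or a <= 2e-6
    return ArctanFit(
        model=AgeModel(a=max(a, 1e-6), b=max(b, 1e-6), t0=t0, d=d),
        residual_rms=rms,
        degenerate=degenerate,
        n_points=len(t),
    )
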