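"""Method-of-Moments (MoM) signal harmonization across acquisition sites.

Spherical moments — the per-voxel mean and variance of the signal over the
six selected gradient directions — are rotation-invariant features of the
diffusion signal.  MoM aligns a target site to a reference site with a
per-voxel linear map ``f(S) = alpha * S + beta`` chosen so the target's
moments match the reference's::

    alpha = sqrt(var_ref / var_src),   beta = mean_ref - alpha * mean_src

Moment images are voxelwise medians across subjects, optionally smoothed
with a Gaussian filter.  Because ``alpha > 0``, the within-voxel ranking of
the six direction signals — the directional content — is preserved exactly.

Variance uses the population (1/n) convention.  All subjects must share the
template grid; no registration is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "MomentMaps",
    "HarmonizationField",
    "compute_moment_maps",
    "derive_mapping",
    "apply_mapping",
    "moment_discrepancy",
]

DEFAULT_SMOOTHING_SIGMA = 1.0  # voxels
ALPHA_BOUNDS = (0.1, 10.0)
DEFAULT_VAR_FLOOR = 1e-6


@dataclass
class MomentMaps:
    """Median-across-subjects mean/variance images of the six-direction signal."""

    mean_map: np.ndarray
    var_map: np.ndarray
    n_subjects: int
    smoothing_sigma: float

    def __post_init__(self):
        if self.mean_map.shape != self.var_map.shape:
            raise ValueError("mean and variance maps must share a grid")
        if np.any(self.var_map < 0):
            raise ValueError("variance map must be non-negative")


@dataclass
class HarmonizationField:
    """Per-voxel (alpha, beta) of the linear harmonization map."""

    alpha: np.ndarray
    beta: np.ndarray
    n_floored: int  # voxels whose source variance hit the floor
    n_clipped: int  # voxels whose alpha was clipped to bounds

    def __post_init__(self):
        if self.alpha.shape != self.beta.shape:
            raise ValueError("alpha and beta must share a grid")
        if not np.all(np.isfinite(self.alpha)) or not np.all(np.isfinite(self.beta)):
            raise ValueError("harmonization field must be finite")
        if np.any(self.alpha <= 0):
            raise ValueError("alpha must be positive after clipping")


def _subject_moments(dwi: np.ndarray, six_indices) -> tuple[np.ndarray, np.ndarray]:
    six = np.asarray(dwi, dtype=float)[..., list(six_indices)]
    if six.shape[-1] != 6:
        raise ValueError("expected exactly six direction indices")
    mean = six.mean(axis=-1)
    var = six.var(axis=-1)  # population (1/n) convention
    return mean, var


def compute_moment_maps(
    subjects,
    six_indices,
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA,
) -> MomentMaps:
    """Voxelwise median across subjects of the six-direction mean/variance,
    Gaussian-smoothed with ``smoothing_sigma`` voxels (0 disables).

    ``subjects`` is a list of SubjectPhantom (or any objects with ``.dwi``).
    """
    if len(subjects) == 0:
        raise ValueError("need at least one subject")
    grids = {s.dwi.shape[:-1] for s in subjects}
    if len(grids) != 1:
        raise ValueError("subjects are on mismatched grids")
    means, variances = zip(*(_subject_moments(s.dwi, six_indices) for s in subjects))
    mean_map = np.median(np.stack(means), axis=0)
    var_map = np.median(np.stack(variances), axis=0)
    if smoothing_sigma > 0:
        mean_map = gaussian_filter(mean_map, smoothing_sigma)
        var_map = gaussian_filter(var_map, smoothing_sigma)
    return MomentMaps(
        mean_map=mean_map,
        var_map=np.maximum(var_map, 0.0),
        n_subjects=len(subjects),
        smoothing_sigma=smoothing_sigma,
    )


def derive_mapping(
    source: MomentMaps,
    reference: MomentMaps,
    var_floor: float = DEFAULT_VAR_FLOOR,
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS,
) -> HarmonizationField:
    """Per-voxel (alpha, beta) aligning source moments to reference moments.

    Where the source variance is at least ``var_floor`` the mapped moments
    reproduce the reference exactly; degenerate voxels are floored and alpha
    clipped to ``alpha_bounds``, with counts reported.
    """
    if source.mean_map.shape != reference.mean_map.shape:
        raise ValueError("source and reference maps must share a grid")
    if var_floor <= 0:
        raise ValueError("var_floor must be positive")
    floored = source.var_map < var_floor
    alpha = np.sqrt(reference.var_map / np.maximum(source.var_map, var_floor))
    clipped = (alpha < alpha_bounds[0]) | (alpha > alpha_bounds[1])
    alpha = np.clip(alpha, *alpha_bounds)
    beta = reference.mean_map - alpha * source.mean_map
    return HarmonizationField(
        alpha=alpha,
        beta=beta,
        n_floored=int(floored.sum()),
        n_clipped=int(clipped.sum()),
    )


def apply_mapping(dwi_six: np.ndarray, field: HarmonizationField) -> np.ndarray:
    """Apply ``S' = alpha*S + beta`` voxelwise; all six directions share the
    voxel's pair.  The output is floored at zero (signals are magnitudes)."""
    dwi_six = np.asarray(dwi_six, dtype=float)
    if dwi_six.shape[:-1] != field.alpha.shape:
        raise ValueError("volume and harmonization field grids do not match")
    out = field.alpha[..., None] * dwi_six + field.beta[..., None]
    return np.maximum(out, 0.0)


def moment_discrepancy(dwi_six: np.ndarray, reference: MomentMaps) -> dict:
    """QC: RMS mismatch between a volume's per-voxel moments and a reference."""
    mean, var = _subject_moments(dwi_six, range(dwi_six.shape[-1]))
    return {
        "mean_rms": float(np.sqrt(np.mean((mean - reference.mean_map) ** 2))),
        "var_rms": float(np.sqrt(np.mean((var - reference.var_map) ** 2))),
    }
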