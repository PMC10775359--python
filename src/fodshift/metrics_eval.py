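"""FOD evaluation metrics: agreement rate, angular error, AFD error.

Agreement Rate (AR) is the percentage of white-matter voxels in which the
predicted FOD has the same number of peaks as the ground truth, stratified
by the ground-truth fiber count k in {1, 2, 3}.  Angular Error (AE) is the
mean angle (degrees, antipodally identified) over matched ground-truth /
predicted peak pairs pooled across the voxels of a stratum; peaks are
matched greedily by smallest angle under a 45 degree cap, so AE is only
computed among fibers with a matched prediction.  AFD error is the mean
absolute difference of total apparent fiber density, the sphere integral of
the FOD, which depends only on the order-0 coefficient:
``AFD = c00 * 2 * sqrt(pi)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .sh_core import PeakParams, PeakSet, SHCoefficientField, extract_peaks_field, make_symmetric_grid

__all__ = [
    "MetricsReport",
    "angular_error",
    "match_peaks",
    "peak_counts",
    "agreement_rate",
    "angular_error_field",
    "afd_error",
    "evaluate",
]

_STRATA = (1, 2, 3)
_MATCH_CAP_DEG = 45.0


@dataclass
class MetricsReport:
    """AR/AE per fiber-count stratum plus AFD error and bookkeeping counts.

    Empty strata are reported as ``None`` (missing), never as 0.
    """

    ar_by_k: dict[int, float | None]
    ae_by_k: dict[int, float | None]
    afd_error: float
    n_voxels_by_k: dict[int, int]
    n_matched_pairs_by_k: dict[int, int]
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ar_by_k": {str(k): v for k, v in self.ar_by_k.items()},
            "ae_by_k": {str(k): v for k, v in self.ae_by_k.items()},
            "afd_error": self.afd_error,
            "n_voxels_by_k": {str(k): v for k, v in self.n_voxels_by_k.items()},
            "n_matched_pairs_by_k": {str(k): v for k, v in self.n_matched_pairs_by_k.items()},
            "extras": self.extras,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(
            ar_by_k={int(k): v for k, v in d["ar_by_k"].items()},
            ae_by_k={int(k): v for k, v in d["ae_by_k"].items()},
            afd_error=d["afd_error"],
            n_voxels_by_k={int(k): v for k, v in d["n_voxels_by_k"].items()},
            n_matched_pairs_by_k={int(k): v for k, v in d["n_matched_pairs_by_k"].items()},
            extras=d.get("extras", {}),
        )


def angular_error(u, v) -> float:
    """Angle in degrees between two directions with antipodal identification.

    Range [0, 90]; ``angular_error(u, -u) == 0``.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("angular_error requires non-zero vectors")
    c = abs(float(u @ v) / (nu * nv))
    return float(np.degrees(np.arccos(min(1.0, c))))


def match_peaks(gt: PeakSet, pred: PeakSet, cap_deg: float = _MATCH_CAP_DEG) -> list[tuple[int, int]]:
    """Minimum-angle matching of ground-truth and predicted peaks.

    Solves the optimal one-to-one assignment that first maximizes the
    number of pairs within the ``cap_deg`` angular cap and, among those,
    minimizes the total matched angle; each peak is used at most once.
    Deterministic, with ties resolved by (gt index, pred index) order.
    """
    if gt.count == 0 or pred.count == 0:
        return []
    ang = np.empty((gt.count, pred.count))
    for i in range(gt.count):
        for j in range(pred.count):
            ang[i, j] = angular_error(gt.directions[i], pred.directions[j])
    # pairs beyond the cap carry a prohibitive cost, so the assignment
    # maximizes in-cap pairs first and total angle second
    cost = np.where(ang <= cap_deg, ang, 1e6)
    rows, cols = linear_sum_assignment(cost)
    return sorted((int(i), int(j)) for i, j in zip(rows, cols) if ang[i, j] <= cap_deg)


def _coeff_matrix(fod, wm_mask) -> np.ndarray:
    """Masked (n_voxels, n_coeffs) view of a coefficient field or array."""
    coeffs = fod.coefficients if isinstance(fod, SHCoefficientField) else np.asarray(fod)
    mask = np.asarray(wm_mask, dtype=bool)
    if coeffs.shape[:-1] != mask.shape:
        raise ValueError("FOD field and mask grids do not match")
    return coeffs[mask]


def peak_counts(peaks: list[PeakSet]) -> np.ndarray:
    return np.array([p.count for p in peaks], dtype=int)


def _extract_both(gt_field, pred_field, wm_mask, peak_params: PeakParams):
    grid = make_symmetric_grid(peak_params.grid_points)
    gt_peaks = extract_peaks_field(_coeff_matrix(gt_field, wm_mask), grid, peak_params)
    pred_peaks = extract_peaks_field(_coeff_matrix(pred_field, wm_mask), grid, peak_params)
    return gt_peaks, pred_peaks


def agreement_rate(gt_field, pred_field, wm_mask, k: int, peak_params: PeakParams = PeakParams()) -> float | None:
    """Percent of GT k-fiber WM voxels whose prediction also has k peaks."""
    gt_peaks, pred_peaks = _extract_both(gt_field, pred_field, wm_mask, peak_params)
    return _agreement_from_counts(peak_counts(gt_peaks), peak_counts(pred_peaks), k)


def _agreement_from_counts(gt_counts: np.ndarray, pred_counts: np.ndarray, k: int) -> float | None:
    sel = gt_counts == k
    if not np.any(sel):
        return None
    return float(100.0 * np.mean(pred_counts[sel] == k))


def angular_error_field(gt_field, pred_field, wm_mask, k: int, peak_params: PeakParams = PeakParams()) -> float | None:
    """Mean matched-pair angle (degrees) over GT k-fiber WM voxels."""
    gt_peaks, pred_peaks = _extract_both(gt_field, pred_field, wm_mask, peak_params)
    angles = _matched_angles(gt_peaks, pred_peaks, k)
    return float(np.mean(angles)) if angles else None


def _matched_angles(gt_peaks, pred_peaks, k: int) -> list[float]:
    angles = []
    for g, p in zip(gt_peaks, pred_peaks):
        if g.count != k:
            continue
        for gi, pj in match_peaks(g, p):
            angles.append(angular_error(g.directions[gi], p.directions[pj]))
    return angles


def total_afd(fod, wm_mask) -> np.ndarray:
    """Per-voxel total apparent fiber density (sphere integral of the FOD)."""
    c = _coeff_matrix(fod, wm_mask)
    return c[:, 0] * 2.0 * np.sqrt(np.pi)


def afd_error(gt_field, pred_field, wm_mask) -> float:
    """Mean absolute total-AFD difference over WM voxels."""
    return float(np.mean(np.abs(total_afd(pred_field, wm_mask) - total_afd(gt_field, wm_mask))))


def evaluate(
    gt_field,
    pred_field,
    wm_mask,
    peak_params: PeakParams = PeakParams(),
    include_three_fiber: bool = True,
) -> MetricsReport:
    """Full AR/AE/AFD report between a ground-truth and a predicted FOD field.

    Three-fiber rows are always computed; ``include_three_fiber=False`` only
    flags them as excluded from headline comparisons in ``extras``.
    """
    mask = np.asarray(wm_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty WM mask")
    gt_peaks, pred_peaks = _extract_both(gt_field, pred_field, wm_mask, peak_params)
    gt_counts = peak_counts(gt_peaks)
    pred_counts = peak_counts(pred_peaks)
    ar, ae, nvox, npairs = {}, {}, {}, {}
    for k in _STRATA:
        ar[k] = _agreement_from_counts(gt_counts, pred_counts, k)
        angles = _matched_angles(gt_peaks, pred_peaks, k)
        ae[k] = float(np.mean(angles)) if angles else None
        nvox[k] = int(np.sum(gt_counts == k))
        npairs[k] = len(angles)
    report = MetricsReport(
        ar_by_k=ar,
        ae_by_k=ae,
        afd_error=afd_error(gt_field, pred_field, wm_mask),
        n_voxels_by_k=nvox,
        n_matched_pairs_by_k=npairs,
        extras={
            "n_wm_voxels": int(mask.sum()),
            "n_voxels_k0": int(np.sum(gt_counts == 0)),
            "three_fiber_excluded_from_headline": not include_three_fiber,
        },
    )
    return report
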