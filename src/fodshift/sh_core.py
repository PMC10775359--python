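"""Real even-order spherical harmonics and FOD peak extraction.

Basis convention
----------------
Real, symmetric (even ``l`` only), orthonormal over the sphere, ordered
l-major with ``m`` running from ``-l`` to ``+l`` (the ordering used by
MRtrix).  For a unit direction with polar angle ``theta`` and azimuth
``phi``::

    Y_{l,m}(u) = sqrt(2) * N_{l,|m|} * P_l^{|m|}(cos theta) * sin(|m| phi)   m < 0
    Y_{l,0}(u) =           N_{l,0}   * P_l(cos theta)                        m = 0
    Y_{l,m}(u) = sqrt(2) * N_{l,m}  * P_l^{m}(cos theta)  * cos(m phi)       m > 0

with ``N_{l,m} = sqrt((2l+1)/(4 pi) * (l-m)!/(l+m)!)`` and ``P_l^m``
including the Condon-Shortley phase (scipy's ``lpmv``).  Only even orders
appear, so every field is antipodally symmetric by construction.  A vector
of coefficients up to even order ``lmax`` has ``(lmax+1)(lmax+2)/2``
entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gammaln

BASIS_CONVENTION = "real-symmetric-orthonormal-lm"

__all__ = [
    "BASIS_CONVENTION",
    "UnitDirectionSet",
    "SHCoefficientField",
    "PeakSet",
    "PeakParams",
    "n_coeffs_for_lmax",
    "lmax_for_n_coeffs",
    "sh_degrees",
    "build_sh_basis",
    "project_to_sh",
    "evaluate_sh",
    "make_symmetric_grid",
    "extract_peaks",
    "extract_peaks_field",
]


def n_coeffs_for_lmax(lmax: int) -> int:
    """Number of real even-order SH coefficients up to ``lmax``."""
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError(f"lmax must be a non-negative even integer, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def lmax_for_n_coeffs(n: int) -> int:
    """Inverse of :func:`n_coeffs_for_lmax`; rejects lengths that fit no even lmax."""
    lmax = 0
    while n_coeffs_for_lmax(lmax) < n:
        lmax += 2
    if n_coeffs_for_lmax(lmax) != n:
        raise ValueError(f"{n} is not a valid even-order SH coefficient count")
    return lmax


def sh_degrees(lmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays ``(l, m)`` for every coefficient index up to even ``lmax``."""
    ls, ms = [], []
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def _as_unit_directions(directions, atol: float = 1e-10) -> np.ndarray:
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    if d.ndim != 2 or d.shape[1] != 3 or d.shape[0] < 1:
        raise ValueError("directions must be an (n, 3) array with n >= 1")
    norms = np.linalg.norm(d, axis=1)
    if not np.allclose(norms, 1.0, atol=atol):
        raise ValueError("directions must be unit vectors")
    return d


@dataclass(frozen=True)
class UnitDirectionSet:
    """A set of unit 3-vectors (gradient directions or a sphere grid)."""

    directions: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "directions", _as_unit_directions(self.directions))

    def __len__(self) -> int:
        return self.directions.shape[0]


@dataclass
class SHCoefficientField:
    """Per-voxel even-order SH coefficient vectors on a 3D grid.

    ``coefficients`` has shape ``grid_shape + (n_coeffs,)``.
    """

    lmax: int
    coefficients: np.ndarray
    basis_convention: str = BASIS_CONVENTION

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients)
        if self.coefficients.shape[-1] != n_coeffs_for_lmax(self.lmax):
            raise ValueError(
                f"coefficient vectors of length {self.coefficients.shape[-1]} "
                f"do not match lmax={self.lmax}"
            )

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.coefficients.shape[:-1]

    @property
    def n_coeffs(self) -> int:
        return self.coefficients.shape[-1]


@dataclass
class PeakSet:
    """FOD peaks: unit directions (antipodally identified) with amplitudes,
    sorted by descending amplitude."""

    directions: np.ndarray  # (k, 3)
    amplitudes: np.ndarray  # (k,)

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float).reshape(-1, 3)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float).reshape(-1)
        if self.directions.shape[0] != self.amplitudes.shape[0]:
            raise ValueError("directions and amplitudes must have the same length")

    @property
    def count(self) -> int:
        return self.directions.shape[0]

    def __len__(self) -> int:
        return self.count


def _cart_to_sph(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polar angle (from +z) and azimuth of unit vectors."""
    theta = np.arccos(np.clip(d[..., 2], -1.0, 1.0))
    phi = np.arctan2(d[..., 1], d[..., 0])
    return theta, phi


def _legendre_table(lmax: int, x: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Associated Legendre P_l^m(x) for all 0 <= m <= l <= lmax.

    Stable upward recurrence in l per m, Condon-Shortley phase included
    (matches scipy.special.lpmv).
    """
    P: dict[tuple[int, int], np.ndarray] = {}
    sx = np.sqrt(np.maximum(0.0, 1.0 - x * x))
    pmm = np.ones_like(x)
    for m in range(0, lmax + 1):
        if m > 0:
            pmm = pmm * (-(2 * m - 1)) * sx
        P[(m, m)] = pmm
        if m < lmax:
            P[(m + 1, m)] = x * (2 * m + 1) * pmm
        for l in range(m + 2, lmax + 1):
            P[(l, m)] = ((2 * l - 1) * x * P[(l - 1, m)] - (l + m - 1) * P[(l - 2, m)]) / (l - m)
    return P


def build_sh_basis(directions, lmax: int) -> np.ndarray:
    """Design matrix of the real even-order SH basis, shape (n_dirs, n_coeffs)."""
    if isinstance(directions, UnitDirectionSet):
        d = directions.directions
    else:
        d = _as_unit_directions(directions)
    ncoef = n_coeffs_for_lmax(lmax)
    theta, phi = _cart_to_sph(d)
    x = np.cos(theta)
    P = _legendre_table(lmax, x)
    cosm = {m: np.cos(m * phi) for m in range(1, lmax + 1)}
    sinm = {m: np.sin(m * phi) for m in range(1, lmax + 1)}
    B = np.empty(d.shape[:-1] + (ncoef,), dtype=float)
    j = 0
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            am = abs(m)
            norm = np.exp(
                0.5
                * (
                    np.log(2 * l + 1.0)
                    - np.log(4 * np.pi)
                    + gammaln(l - am + 1)
                    - gammaln(l + am + 1)
                )
            )
            if m < 0:
                B[..., j] = np.sqrt(2.0) * norm * P[(l, am)] * sinm[am]
            elif m == 0:
                B[..., j] = norm * P[(l, 0)]
            else:
                B[..., j] = np.sqrt(2.0) * norm * P[(l, am)] * cosm[am]
            j += 1
    return B


def project_to_sh(values, directions, lmax: int, ridge: float = 0.0) -> np.ndarray:
    """Least-squares SH fit of per-direction values (optionally ridge-regularized).

    ``values`` may carry leading batch axes; the direction axis is last.
    """
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    B = build_sh_basis(directions, lmax)
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != B.shape[0]:
        raise ValueError("number of values must match number of directions")
    n_dirs, n_coef = B.shape
    if ridge == 0.0 and n_dirs < n_coef:
        raise ValueError(
            f"underdetermined SH fit: {n_dirs} directions for {n_coef} "
            f"coefficients at lmax={lmax}; add directions or use ridge > 0"
        )
    A = B.T @ B
    if ridge > 0.0:
        A = A + ridge * np.eye(n_coef)
    rhs = values @ B  # (..., n_coef)
    coeffs = np.linalg.solve(A, rhs[..., None])[..., 0]
    return coeffs


def evaluate_sh(coeffs, directions) -> np.ndarray:
    """Evaluate SH coefficient vectors at directions.

    ``coeffs`` may carry leading batch axes (coefficient axis last); the
    result has shape ``batch + (n_directions,)``.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    lmax = lmax_for_n_coeffs(coeffs.shape[-1])
    B = build_sh_basis(directions, lmax)
    return coeffs @ B.T


# ---------------------------------------------------------------------------
# peak extraction


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic well-spread points on the upper hemisphere (z >= 0)."""
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    z = (i + 0.5) / n  # in (0, 1): strictly upper hemisphere
    r = np.sqrt(1 - z**2)
    phi = 2 * np.pi * i / golden
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclass(frozen=True)
class _SphereGrid:
    """Antipodally symmetric grid with a precomputed neighbor graph."""

    directions: np.ndarray  # (n, 3)
    neighbors: np.ndarray  # (n, k) indices of nearest neighbors

    def __len__(self) -> int:
        return self.directions.shape[0]


_GRID_CACHE: dict[tuple[int, int], _SphereGrid] = {}


def make_symmetric_grid(n_points: int = 724, n_neighbors: int = 8) -> _SphereGrid:
    """Build (and cache) an antipodally symmetric sphere grid of ``n_points``.

    Neighbors are found with antipodal identification: for each point the
    nearest distinct points under the metric min(|u-v|, |u+v|).
    """
    key = (n_points, n_neighbors)
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]
    half = _fibonacci_hemisphere(n_points // 2)
    dirs = np.concatenate([half, -half], axis=0)
    tree = cKDTree(dirs)
    _, idx = tree.query(dirs, k=n_neighbors + 2)
    nbrs = np.empty((dirs.shape[0], n_neighbors), dtype=np.intp)
    for i in range(dirs.shape[0]):
        row = [j for j in idx[i] if j != i]
        nbrs[i] = row[:n_neighbors]
    grid = _SphereGrid(directions=dirs, neighbors=nbrs)
    _GRID_CACHE[key] = grid
    return grid


@dataclass(frozen=True)
class PeakParams:
    """Peak-extraction settings shared by every evaluation in a study."""

    grid_points: int = 724
    rel_threshold: float = 0.1
    min_separation_deg: float = 15.0
    max_peaks: int = 3
    refine: bool = True

    def __post_init__(self):
        if not (0.0 < self.rel_threshold < 1.0):
            raise ValueError("rel_threshold must be in (0, 1)")


def _rotation_to(z_targets: np.ndarray) -> np.ndarray:
    """Batch of rotation matrices mapping +z to each target direction."""
    u = z_targets
    # pick a helper axis not parallel to u
    helper = np.where(np.abs(u[:, 2:3]) < 0.9, [[0.0, 0.0, 1.0]], [[1.0, 0.0, 0.0]])
    a = np.cross(helper, u)
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = np.cross(u, a)
    return np.stack([a, b, u], axis=-1)  # columns: a, b, u


def _cap_template(radius_deg: float, n_ring: int = 10, n_rad: int = 4) -> np.ndarray:
    """Small cap of directions around +z used for local peak refinement."""
    pts = [np.array([0.0, 0.0, 1.0])]
    for r in np.linspace(radius_deg / n_rad, radius_deg, n_rad):
        t = np.deg2rad(r)
        for p in np.linspace(0, 2 * np.pi, n_ring, endpoint=False):
            pts.append([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])
    return np.asarray(pts)


_CAP_STAGES = (4.0, 1.5, 0.5, 0.15)  # degrees; final resolution ~0.04 deg


def _refine_peaks(coeffs: np.ndarray, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local ascent of candidate peaks by successive cap grid searches.

    ``coeffs``: (m, n_coeffs) one coefficient vector per candidate.
    ``dirs``: (m, 3) starting directions. Returns refined (dirs, amplitudes).
    """
    lmax = lmax_for_n_coeffs(coeffs.shape[-1])
    for radius in _CAP_STAGES:
        cap = _cap_template(radius)
        R = _rotation_to(dirs)  # (m, 3, 3)
        cand = np.einsum("mij,kj->mki", R, cap)  # (m, K, 3)
        B = build_sh_basis(cand.reshape(-1, 3), lmax).reshape(cand.shape[0], cap.shape[0], -1)
        amps = np.einsum("mkc,mc->mk", B, coeffs)
        best = np.argmax(amps, axis=1)
        dirs = cand[np.arange(len(dirs)), best]
    amps = np.einsum("mc,mc->m", build_sh_basis(dirs, lmax), coeffs)
    return dirs, amps


def _canonical_hemisphere(d: np.ndarray) -> np.ndarray:
    """Flip antipodal representatives into a canonical hemisphere (z>0, then
    y>0, then x>0)."""
    d = np.array(d, dtype=float)
    flip = (d[..., 2] < 0) | ((d[..., 2] == 0) & (d[..., 1] < 0)) | (
        (d[..., 2] == 0) & (d[..., 1] == 0) & (d[..., 0] < 0)
    )
    d[flip] *= -1
    return d


def _select_peaks(dirs, amps, rel_threshold, min_separation_deg, max_peaks):
    """Threshold, merge and truncate refined candidates of one voxel."""
    if len(amps) == 0:
        return PeakSet(np.empty((0, 3)), np.empty(0))
    keep = amps > 0
    dirs, amps = dirs[keep], amps[keep]
    if len(amps) == 0:
        return PeakSet(np.empty((0, 3)), np.empty(0))
    amax = amps.max()
    keep = amps >= rel_threshold * amax
    dirs, amps = dirs[keep], amps[keep]
    # sort by descending amplitude; lexicographic direction order breaks ties
    dirs = _canonical_hemisphere(dirs)
    order = np.lexsort((dirs[:, 2], dirs[:, 1], dirs[:, 0], -amps))
    dirs, amps = dirs[order], amps[order]
    cos_min = np.cos(np.deg2rad(min_separation_deg))
    sel_d, sel_a = [], []
    for d, a in zip(dirs, amps):
        if any(abs(d @ s) > cos_min for s in sel_d):
            continue  # merged into a larger peak
        sel_d.append(d)
        sel_a.append(a)
        if len(sel_d) == max_peaks:
            break
    return PeakSet(np.asarray(sel_d).reshape(-1, 3), np.asarray(sel_a))


def extract_peaks(
    fod_coeffs,
    grid: _SphereGrid | None = None,
    rel_threshold: float = 0.1,
    min_separation_deg: float = 15.0,
    max_peaks: int = 3,
    refine: bool = True,
) -> PeakSet:
    """Extract FOD peaks from one SH coefficient vector.

    Strict local maxima on the grid's neighbor graph, refined by local
    ascent, thresholded relative to the largest amplitude, merged within
    ``min_separation_deg`` (keeping the larger), at most ``max_peaks``
    returned.  A constant (isotropic) FOD has no strict local maximum and
    yields an empty PeakSet, as does a non-positive FOD.
    """
    params = PeakParams(
        rel_threshold=rel_threshold,
        min_separation_deg=min_separation_deg,
        max_peaks=max_peaks,
        refine=refine,
    )
    peaks = extract_peaks_field(np.asarray(fod_coeffs)[None, :], grid=grid, params=params)
    return peaks[0]


def extract_peaks_field(
    coeffs: np.ndarray,
    grid: _SphereGrid | None = None,
    params: PeakParams = PeakParams(),
) -> list[PeakSet]:
    """Vectorized peak extraction for a batch of coefficient vectors (n, n_coeffs)."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim != 2:
        raise ValueError("coeffs must be (n_voxels, n_coeffs)")
    if grid is None:
        grid = make_symmetric_grid(params.grid_points)
    lmax = lmax_for_n_coeffs(coeffs.shape[-1])
    B = build_sh_basis(grid.directions, lmax)  # (g, c)
    amps = coeffs @ B.T  # (n, g)
    nbr_amps = amps[:, grid.neighbors]  # (n, g, k)
    is_max = (amps > 0) & np.all(amps[:, :, None] > nbr_amps, axis=2)
    vox_idx, grid_idx = np.nonzero(is_max)
    if len(vox_idx) == 0:
        return [PeakSet(np.empty((0, 3)), np.empty(0)) for _ in range(coeffs.shape[0])]
    cand_dirs = grid.directions[grid_idx]
    cand_amps = amps[vox_idx, grid_idx]
    # drop clearly sub-threshold candidates before the (costly) refinement;
    # the margin of 2 covers grid-vs-refined amplitude differences
    vox_max = amps.max(axis=1)
    strong = cand_amps >= 0.5 * params.rel_threshold * vox_max[vox_idx]
    vox_idx, cand_dirs, cand_amps = vox_idx[strong], cand_dirs[strong], cand_amps[strong]
    # noisy fields can carry dozens of weak maxima; only the strongest few
    # can survive thresholding and merging, so cap refinement work per voxel
    cap = 2 * params.max_peaks
    order0 = np.lexsort((-cand_amps, vox_idx))
    vox_idx, cand_dirs, cand_amps = vox_idx[order0], cand_dirs[order0], cand_amps[order0]
    first = np.searchsorted(vox_idx, vox_idx)
    rank = np.arange(len(vox_idx)) - first
    keep_rank = rank < cap
    vox_idx, cand_dirs, cand_amps = vox_idx[keep_rank], cand_dirs[keep_rank], cand_amps[keep_rank]
    # antipodal duplicates: keep canonical-hemisphere representative only
    canon = _canonical_hemisphere(cand_dirs)
    keep = np.einsum("ij,ij->i", cand_dirs, canon) > 0.5
    vox_idx, cand_dirs, cand_amps = vox_idx[keep], canon[keep], cand_amps[keep]
    if params.refine:
        cand_dirs, cand_amps = _refine_peaks(coeffs[vox_idx], cand_dirs)
        cand_dirs = _canonical_hemisphere(cand_dirs)
    out = []
    order = np.argsort(vox_idx, kind="stable")
    vox_idx, cand_dirs, cand_amps = vox_idx[order], cand_dirs[order], cand_amps[order]
    bounds = np.searchsorted(vox_idx, np.arange(coeffs.shape[0] + 1))
    for v in range(coeffs.shape[0]):
        lo, hi = bounds[v], bounds[v + 1]
        out.append(
            _select_peaks(
                cand_dirs[lo:hi],
                cand_amps[lo:hi],
                params.rel_threshold,
                params.min_separation_deg,
                params.max_peaks,
            )
        )
    return out
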