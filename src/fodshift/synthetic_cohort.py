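"""Two-site, age-structured synthetic dMRI cohorts with known fiber geometry.

Emulates, at desk scale, a newborn cohort acquired with a dHCP-like
multi-shell scheme (b in {0, 400, 1000, 2600} s/mm^2) and a baby cohort
acquired with a BCP-like scheme (b in {0, 500, ..., 3000} s/mm^2), on one
template grid.  Each phantom voxel holds 0-3 fiber populations; the
diffusion signal follows a multi-tensor forward model; site differences are
a smooth multiplicative gain field, a smooth additive offset field and
Rician noise; white-matter microstructure matures along an arctan
FA-versus-age growth curve, with ages in postnatal months throughout
(post-menstrual weeks convert as ``(weeks - 40) / 4.345``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sh_core import build_sh_basis, n_coeffs_for_lmax, sh_degrees, SHCoefficientField
from .sh_core import _fibonacci_hemisphere  # deterministic well-spread directions

__all__ = [
    "GradientScheme",
    "AgeModel",
    "SiteProfile",
    "FiberConfig",
    "SubjectPhantom",
    "GeometrySpec",
    "dhcp_like_scheme",
    "bcp_like_scheme",
    "make_site_profile",
    "sample_fiber_geometry",
    "simulate_signal",
    "age_to_diffusivities",
    "single_tensor_fa",
    "apply_site_effects",
    "analytic_gt_fod",
    "generate_cohort",
    "weeks_postmenstrual_to_months",
]

LAMBDA_PARALLEL = 1.7e-3  # mm^2/s, axial diffusivity held fixed across ages
MD_ISO = 3.0e-3  # mm^2/s, free-water compartment for non-fiber signal
DEFAULT_S0 = 100.0
FOD_APOD_KAPPA = 0.03  # Gaussian taper exp(-kappa*l*(l+1)) of the delta kernel


def weeks_postmenstrual_to_months(weeks) -> np.ndarray:
    """Convert post-menstrual weeks to postnatal months (birth at 40 weeks)."""
    return (np.asarray(weeks, dtype=float) - 40.0) / 4.345


# ---------------------------------------------------------------------------
# gradient schemes


@dataclass(frozen=True)
class GradientScheme:
    """FSL-style gradient table: b-values (s/mm^2) and unit directions."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3); rows for b=0 may be zero vectors
    shell_tol: float = 50.0

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvals.ndim != 1 or bvecs.shape != (bvals.shape[0], 3):
            raise ValueError("bvals must be (n,) and bvecs (n, 3)")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        if not np.any(bvals <= self.shell_tol):
            raise ValueError("scheme must contain at least one b=0 measurement")
        dw = bvals > self.shell_tol
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("diffusion-weighted bvecs must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.shell_tol

    def shells(self) -> list[float]:
        """Distinct non-zero shell b-values (cluster centers)."""
        out: list[float] = []
        for b in sorted(self.bvals[~self.b0_mask]):
            if not out or abs(b - out[-1]) > self.shell_tol:
                out.append(float(b))
        return out

    def shell_indices(self, b: float) -> np.ndarray:
        """Measurement indices belonging to shell ``b`` (within tolerance)."""
        idx = np.nonzero(np.abs(self.bvals - b) <= self.shell_tol)[0]
        if len(idx) == 0:
            raise ValueError(f"scheme has no b={b} shell")
        return idx


def _shell_dirs(n: int, offset: int) -> np.ndarray:
    """Deterministic well-spread hemisphere directions, decorrelated across
    shells via an index offset into a longer Fibonacci sequence."""
    return _fibonacci_hemisphere(n + offset)[offset:]


def dhcp_like_scheme(n_b0: int = 6, n_per_shell: tuple[int, ...] = (24, 40, 48)) -> GradientScheme:
    """Multi-shell scheme with b in {0, 400, 1000, 2600} s/mm^2."""
    shells = (400.0, 1000.0, 2600.0)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for k, (b, n) in enumerate(zip(shells, n_per_shell)):
        bvals += [b] * n
        bvecs += list(_shell_dirs(n, 3 * k + 1))
    return GradientScheme(np.array(bvals), np.array(bvecs))


def bcp_like_scheme(n_b0: int = 6, n_per_shell: int = 16) -> GradientScheme:
    """Multi-shell scheme with b in {0, 500, 1000, ..., 3000} s/mm^2."""
    shells = (500.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0)
    bvals = [0.0] * n_b0
    bvecs = [np.zeros(3)] * n_b0
    for k, b in enumerate(shells):
        bvals += [b] * n_per_shell
        bvecs += list(_shell_dirs(n_per_shell, 2 * k + 2))
    return GradientScheme(np.array(bvals), np.array(bvecs))


# ---------------------------------------------------------------------------
# age model and diffusivities


@dataclass(frozen=True)
class AgeModel:
    """Arctan growth curve FA(t) = a * arctan(b * (t - t0)) + d, t in months."""

    a: float
    b: float
    t0: float
    d: float

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("arctan growth requires a > 0 and b > 0")

    def fa(self, t) -> np.ndarray:
        return self.a * np.arctan(self.b * (np.asarray(t, dtype=float) - self.t0)) + self.d

    def check_range(self, t_min: float, t_max: float) -> None:
        lo, hi = self.fa(t_min), self.fa(t_max)
        if not (0.0 < lo < 1.0 and 0.0 < hi < 1.0):
            raise ValueError(f"FA leaves (0, 1) over [{t_min}, {t_max}] months")


#: shared maturation curve: FA ~0.15 at late-preterm ages, ~0.31 by 5 years
DEFAULT_AGE_MODEL = AgeModel(a=0.07, b=0.35, t0=0.0, d=0.20)


def single_tensor_fa(lambda_par: float, lambda_perp: float) -> float:
    """FA of an axially symmetric tensor diag(l_par, l_perp, l_perp)."""
    num = lambda_par - lambda_perp
    den = np.sqrt(lambda_par**2 + 2 * lambda_perp**2)
    return float(num / den)


def age_to_diffusivities(age: float, age_model: AgeModel, lambda_par: float = LAMBDA_PARALLEL) -> tuple[float, float]:
    """Axial/radial diffusivities whose single-tensor FA matches the growth curve.

    The axial diffusivity is held fixed; the radial one solves
    ``FA(l_par, l_perp) = age_model.fa(age)`` in closed form (quadratic).
    Older age -> higher FA -> lower radial diffusivity.
    """
    fa = float(age_model.fa(age))
    if not (0.0 <= fa < 1.0):
        raise ValueError(f"target FA {fa:.3f} outside [0, 1) at age {age}")
    if fa == 0.0:
        return lambda_par, lambda_par
    # FA^2 (l_par^2 + 2 r^2) = (l_par - r)^2  ->  quadratic in r
    a = 2 * fa**2 - 1.0
    b = 2 * lambda_par
    c = lambda_par**2 * (fa**2 - 1.0)
    disc = b * b - 4 * a * c
    if a == 0.0:
        r = -c / b
    else:
        roots = [(-b + s * np.sqrt(disc)) / (2 * a) for s in (+1.0, -1.0)]
        cands = [r for r in roots if 0.0 < r <= lambda_par + 1e-15]
        if not cands:
            raise ValueError(f"no radial diffusivity for FA={fa:.3f}")
        r = min(cands)
    return lambda_par, float(r)


# ---------------------------------------------------------------------------
# fiber geometry


@dataclass
class FiberConfig:
    """Per-voxel fiber populations: up to 3 (direction, volume fraction) pairs."""

    directions: np.ndarray  # (X, Y, Z, 3, 3) unit rows where populated
    fractions: np.ndarray  # (X, Y, Z, 3), zero where unpopulated
    counts: np.ndarray  # (X, Y, Z) int, 0..3

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    @property
    def wm_mask(self) -> np.ndarray:
        return self.counts > 0


@dataclass(frozen=True)
class GeometrySpec:
    """Allocation of single/double/triple-fiber regions within the WM box."""

    shares: tuple[float, float, float] = (0.4, 0.4, 0.2)  # 1-, 2-, 3-fiber
    margin: int = 2  # background border, voxels
    crossing_angle_range: tuple[float, float] = (45.0, 90.0)
    wobble_deg: float = 6.0  # smooth within-region direction variation
    n_subregions: int = 32  # independent direction draws per fiber-count stratum

    def __post_init__(self):
        if any(s < 0 for s in self.shares) or abs(sum(self.shares) - 1.0) > 1e-9:
            raise ValueError("shares must be non-negative and sum to 1")
        if self.n_subregions < 1:
            raise ValueError("n_subregions must be >= 1")


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = axis / np.linalg.norm(axis)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _region_directions(k: int, rng, angle_range: tuple[float, float]) -> np.ndarray:
    """k base directions with pairwise separations inside ``angle_range``."""
    lo, hi = np.deg2rad(angle_range[0]), np.deg2rad(angle_range[1])
    for _ in range(200):
        d1 = _random_unit(rng)
        dirs = [d1]
        ok = True
        for _ in range(k - 1):
            placed = False
            for _ in range(100):
                ref = dirs[rng.integers(len(dirs))]
                perp = np.cross(ref, _random_unit(rng))
                if np.linalg.norm(perp) < 1e-8:
                    continue
                perp /= np.linalg.norm(perp)
                ang = rng.uniform(lo, hi)
                cand = np.cos(ang) * ref + np.sin(ang) * perp
                seps = [np.arccos(min(1.0, abs(cand @ d))) for d in dirs]
                if all(lo - 1e-9 <= s <= hi + 1e-9 for s in seps):
                    dirs.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return np.asarray(dirs)
    raise RuntimeError("could not place crossing fiber directions")


def sample_fiber_geometry(grid_shape, spec: GeometrySpec, seed) -> FiberConfig:
    """Deterministic fiber geometry: contiguous 1/2/3-fiber regions inside the
    WM box, smooth within-region direction wobble, background outside."""
    grid_shape = tuple(int(s) for s in grid_shape)
    if 2 * spec.margin >= min(grid_shape):
        raise ValueError("margin leaves no WM voxels on this grid")
    rng = np.random.default_rng(seed)
    X, Y, Z = grid_shape
    counts = np.zeros(grid_shape, dtype=int)
    dirs = np.zeros(grid_shape + (3, 3))
    fracs = np.zeros(grid_shape + (3,))
    m = spec.margin
    wm = np.zeros(grid_shape, dtype=bool)
    wm[m : X - m, m : Y - m, m : Z - m] = True
    wm_idx = np.array(np.nonzero(wm)).T  # lexicographic order
    n_wm = len(wm_idx)
    # largest-remainder allocation so counts match shares exactly when possible
    raw = np.array(spec.shares) * n_wm
    n_k = np.floor(raw).astype(int)
    for _ in range(n_wm - n_k.sum()):
        n_k[np.argmax(raw - n_k)] += 1
    # smooth wobble field shared by all fibers of a voxel
    xs = np.arange(X)[:, None, None] / max(X - 1, 1)
    ys = np.arange(Y)[None, :, None] / max(Y - 1, 1)
    zs = np.arange(Z)[None, None, :] / max(Z - 1, 1)
    phase = rng.uniform(0, 2 * np.pi)
    wobble = np.deg2rad(spec.wobble_deg) * np.sin(2 * np.pi * (xs + ys + zs) / 3 + phase)
    wobble_axis = _random_unit(rng)
    start = 0
    for k, n in zip((1, 2, 3), n_k):
        if n == 0:
            continue
        stratum = wm_idx[start : start + n]
        start += n
        # split the stratum into contiguous sub-regions, each with its own
        # base directions, so cohorts cover direction space densely
        for chunk in np.array_split(stratum, min(spec.n_subregions, n)):
            if len(chunk) == 0:
                continue
            base = _region_directions(k, rng, spec.crossing_angle_range)
            for x, y, z in chunk:
                R = _rotation_about(wobble_axis, wobble[x, y, z])
                counts[x, y, z] = k
                dirs[x, y, z, :k] = base @ R.T
                fracs[x, y, z, :k] = 1.0 / k
    return FiberConfig(directions=dirs, fractions=fracs, counts=counts)


# ---------------------------------------------------------------------------
# forward signal model


def simulate_signal(
    fiber_config: FiberConfig,
    diffusivities: tuple[float, float],
    scheme: GradientScheme,
    s0: float = DEFAULT_S0,
    md_iso: float = MD_ISO,
) -> np.ndarray:
    """Noiseless multi-tensor DWI: each fiber population is an axially
    symmetric tensor; remaining volume fraction is isotropic with ``md_iso``.

    ``S(b, g) = s0 * [ sum_i f_i exp(-b g^T D_i g) + (1 - sum f) exp(-b md_iso) ]``
    """
    lam_par, lam_perp = diffusivities
    if not (lam_par > lam_perp > 0):
        raise ValueError("require lambda_par > lambda_perp > 0")
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    b = scheme.bvals  # (n,)
    g = scheme.bvecs  # (n, 3)
    fr = fiber_config.fractions  # (..., 3)
    f_tot = fr.sum(axis=-1)  # (...,)
    signal = np.empty(fiber_config.grid_shape + (len(scheme),), dtype=float)
    iso = np.exp(-b * md_iso)  # (n,)
    signal[:] = ((1.0 - f_tot)[..., None]) * iso
    delta = lam_par - lam_perp
    for i in range(3):
        fi = fr[..., i]
        if not np.any(fi > 0):
            continue
        dot = fiber_config.directions[..., i, :] @ g.T  # (..., n)
        att = np.exp(-b * lam_perp - b * delta * dot**2)
        signal += fi[..., None] * att
    return s0 * signal


# ---------------------------------------------------------------------------
# site effects


@dataclass
class SiteProfile:
    """One acquisition site: scheme plus smooth signal shifts and noise level."""

    name: str
    scheme: GradientScheme
    gain_field: np.ndarray | None = None  # multiplicative, > 0
    offset_field: np.ndarray | None = None  # additive, signal units
    rician_sigma: float = 0.0  # noise std relative to mean b0 signal

    def __post_init__(self):
        if self.rician_sigma < 0:
            raise ValueError("rician_sigma must be non-negative")
        if self.gain_field is not None and np.any(np.asarray(self.gain_field) <= 0):
            raise ValueError("gain_field must be positive everywhere")


def _smooth_bump(grid_shape) -> np.ndarray:
    """Gaussian bump in [0, 1], centred on the volume (smooth template field)."""
    axes = [np.linspace(-1.0, 1.0, s) for s in grid_shape]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.exp(-(xx**2 + yy**2 + zz**2) / (2 * 0.45**2))


def make_site_profile(
    name: str,
    scheme: GradientScheme,
    grid_shape,
    gain_amplitude: float = 0.0,
    offset_frac: float = 0.0,
    rician_sigma: float = 0.0,
    s0: float = DEFAULT_S0,
) -> SiteProfile:
    """Site with smooth gain ``1 + gain_amplitude * bump`` and additive offset
    ``offset_frac * s0 * (0.5 + 0.5 * bump)``."""
    bump = _smooth_bump(grid_shape)
    gain = 1.0 + gain_amplitude * bump
    offset = offset_frac * s0 * (0.5 + 0.5 * bump)
    return SiteProfile(
        name=name,
        scheme=scheme,
        gain_field=gain if gain_amplitude != 0.0 else None,
        offset_field=offset if offset_frac != 0.0 else None,
        rician_sigma=rician_sigma,
    )


def apply_site_effects(clean_dwi: np.ndarray, profile: SiteProfile, seed) -> np.ndarray:
    """Observed signal ``sqrt((gain*S + offset + e1)^2 + e2^2)`` with Gaussian
    ``e ~ N(0, sigma^2)``, ``sigma = rician_sigma * mean(b0)``; deterministic
    for a fixed seed."""
    rng = np.random.default_rng(seed)
    S = np.asarray(clean_dwi, dtype=float)
    gain = 1.0 if profile.gain_field is None else np.asarray(profile.gain_field)[..., None]
    if np.any(np.asarray(gain) <= 0):
        raise ValueError("gain must be positive")
    offset = 0.0 if profile.offset_field is None else np.asarray(profile.offset_field)[..., None]
    shifted = gain * S + offset
    if profile.rician_sigma == 0.0:
        return shifted
    sigma = profile.rician_sigma * float(S[..., profile.scheme.b0_mask].mean())
    e1 = rng.normal(0.0, sigma, size=S.shape)
    e2 = rng.normal(0.0, sigma, size=S.shape)
    return np.sqrt((shifted + e1) ** 2 + e2**2)


# ---------------------------------------------------------------------------
# analytic ground-truth FODs


def _delta_taper(lmax: int, kappa: float = FOD_APOD_KAPPA) -> np.ndarray:
    ls, _ = sh_degrees(lmax)
    return np.exp(-kappa * ls * (ls + 1))


def analytic_gt_fod(fiber_config: FiberConfig, lmax: int = 8, kappa: float = FOD_APOD_KAPPA) -> SHCoefficientField:
    """Ground-truth FOD field: each fiber population contributes an apodized
    band-limited delta, scaled so the sphere integral equals its fraction.

    The order-0 taper weight is 1, so total AFD equals the total fiber
    fraction exactly.
    """
    taper = _delta_taper(lmax, kappa)
    ncoef = n_coeffs_for_lmax(lmax)
    coeffs = np.zeros(fiber_config.grid_shape + (ncoef,))
    for i in range(3):
        sel = fiber_config.counts > i
        if not np.any(sel):
            continue
        Y = build_sh_basis(fiber_config.directions[sel][:, i, :], lmax)
        coeffs[sel] += fiber_config.fractions[sel][:, i, None] * taper * Y
    return SHCoefficientField(lmax=lmax, coefficients=coeffs)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass
class SubjectPhantom:
    """One synthetic subject: observed DWI plus complete ground truth."""

    subject_id: str
    dwi: np.ndarray  # (X, Y, Z, n_meas)
    scheme: GradientScheme
    gt_fod: SHCoefficientField
    fiber_config: FiberConfig
    wm_mask: np.ndarray
    age: float  # postnatal months
    site: str
    seed: int

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.wm_mask.shape


def generate_cohort(
    n_subjects: int,
    age_range: tuple[float, float],
    site_profile: SiteProfile,
    age_model: AgeModel = DEFAULT_AGE_MODEL,
    geometry_spec: GeometrySpec = GeometrySpec(),
    seed: int = 0,
    grid_shape=(24, 24, 24),
    s0: float = DEFAULT_S0,
    fod_lmax: int = 8,
) -> list[SubjectPhantom]:
    """Generate a site cohort; fully reproducible from the master seed.

    Ages are sampled uniformly in ``age_range`` (postnatal months); each
    subject draws its own geometry, diffusivities from the maturation curve,
    and site effects from a child seed of the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    lo, hi = age_range
    if not (hi > lo):
        raise ValueError("empty age range")
    age_model.check_range(lo, hi)
    master = np.random.SeedSequence(seed)
    children = master.spawn(n_subjects)
    subjects = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        age = float(rng.uniform(lo, hi))
        geom = sample_fiber_geometry(grid_shape, geometry_spec, rng.integers(2**31 - 1))
        lam = age_to_diffusivities(age, age_model)
        clean = simulate_signal(geom, lam, site_profile.scheme, s0=s0)
        dwi = apply_site_effects(clean, site_profile, rng.integers(2**31 - 1))
        gt = analytic_gt_fod(geom, lmax=fod_lmax)
        subjects.append(
            SubjectPhantom(
                subject_id=f"{site_profile.name}-{i:03d}",
                dwi=np.asarray(dwi, dtype=np.float32),
                scheme=site_profile.scheme,
                gt_fod=gt,
                fiber_config=geom,
                wm_mask=geom.wm_mask,
                age=age,
                site=site_profile.name,
                seed=sub_seed,
            )
        )
    return subjects
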