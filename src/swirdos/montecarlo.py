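"""White Monte Carlo photon transport in a homogeneous slab.

Photons are launched as a pencil beam normally incident at the origin of a
slab (default 60 x 60 x 100 mm) and random-walked with zero absorption
("white" transport): exponential steps at mu_t = mu_s, Henyey-Greenstein
scattering, and Fresnel reflection at the top refractive boundary against
air.  Bottom and side boundaries absorb.  For every photon escaping the top
surface the total path length, exit radius, and exit weight are recorded;
absorption at any mu_a is applied afterwards by Beer-Lambert reweighting of
the recorded path lengths (see :mod:`swirdos.lut`).

Weight bookkeeping: the specular reflection at normal incidence is removed
at launch, so each photon carries weight ``1 - R_sp``.  Photons are
terminated (weight booked as residual) once their path exceeds a cutoff of
forty slab diagonals (chosen so that, at the smallest tabulated
absorption of 0.001 mm^-1, the truncated-tail contribution to any detector
ring is below ~1%); everything else either escapes the top or is absorbed
at the bottom/side boundaries, so launched weight is conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["TransportMedium", "PathRecords", "run_white_mc"]


@dataclass(frozen=True)
class TransportMedium:
    """Optical and geometric description of the slab for white transport."""

    musp: float  # reduced scattering coefficient, mm^-1
    g: float = 0.7  # scattering anisotropy
    n: float = 1.435  # refractive index (external medium is air, n=1)
    slab_xy_mm: float = 60.0  # lateral extent (square), mm
    slab_z_mm: float = 100.0  # thickness, mm

    def __post_init__(self) -> None:
        if not (0.0 <= self.g < 1.0):
            raise ValueError(f"anisotropy g must be in [0, 1), got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")
        if self.musp <= 0:
            raise ValueError(f"musp must be > 0, got {self.musp}")
        if self.slab_xy_mm <= 0 or self.slab_z_mm <= 0:
            raise ValueError("slab dimensions must be positive")

    @property
    def mus(self) -> float:
        """Scattering coefficient mu_s = mus' / (1 - g) used for step sampling."""
        return self.musp / (1.0 - self.g)


@dataclass
class PathRecords:
    """Top-exit photon records from one white-MC run plus weight ledger."""

    path_mm: np.ndarray  # total path length in medium per detected photon
    radius_mm: np.ndarray  # exit distance from source axis
    weight: np.ndarray  # statistical weight at exit
    n_launched: int
    medium: TransportMedium
    seed: int
    r_max_mm: float  # records kept only for exit radius <= r_max_mm
    # weight ledger, all normalized per launched photon:
    specular_fraction: float = 0.0
    escaped_top_fraction: float = 0.0  # includes exits beyond r_max_mm
    absorbed_boundary_fraction: float = 0.0  # bottom + side terminations
    residual_fraction: float = 0.0  # path-cutoff terminations
    extra: dict = field(default_factory=dict)

    @property
    def total_fraction(self) -> float:
        return (
            self.specular_fraction
            + self.escaped_top_fraction
            + self.absorbed_boundary_fraction
            + self.residual_fraction
        )


@njit(cache=True)
def _hg_cos(g: float, u: float) -> float:
    if g < 1e-6:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - tmp * tmp) / (2.0 * g)


@njit(cache=True)
def _fresnel_unpolarized(n_rel: float, cos_i: float) -> float:
    """Internal reflectance at the medium->air interface (n_rel = n_in/n_out)."""
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = n_rel * n_rel * sin_i2
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = (n_rel * cos_i - cos_t) / (n_rel * cos_i + cos_t)
    rp = (n_rel * cos_t - cos_i) / (n_rel * cos_t + cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def _transport_kernel(
    mus, g, n_rel, half_xy, depth, n_photons, seed, r_max, path_max
):
    np.random.seed(seed)
    r_sp = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2
    w0 = 1.0 - r_sp

    out_path = np.empty(n_photons)
    out_radius = np.empty(n_photons)
    out_weight = np.empty(n_photons)
    n_det = 0

    w_top = 0.0
    w_lost = 0.0
    w_resid = 0.0

    for _ in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        path = 0.0
        alive = True

        while alive:
            s = -np.log(np.random.random()) / mus
            while s > 0.0 and alive:
                # fast path: a step of length s cannot cross a boundary it is
                # farther than s away from along every coordinate
                ax = x if x > 0.0 else -x
                ay = y if y > 0.0 else -y
                if (
                    s < z
                    and s < depth - z
                    and s < half_xy - ax
                    and s < half_xy - ay
                ):
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    path += s
                    if path > path_max:
                        w_resid += w0
                        alive = False
                    break
                # distance to nearest boundary along current direction
                d_top = np.inf
                if uz < 0.0:
                    d_top = -z / uz
                d_exit = np.inf  # absorbing boundaries (bottom + sides)
                if uz > 0.0:
                    d = (depth - z) / uz
                    if d < d_exit:
                        d_exit = d
                if ux > 0.0:
                    d = (half_xy - x) / ux
                    if d < d_exit:
                        d_exit = d
                elif ux < 0.0:
                    d = (-half_xy - x) / ux
                    if d < d_exit:
                        d_exit = d
                if uy > 0.0:
                    d = (half_xy - y) / uy
                    if d < d_exit:
                        d_exit = d
                elif uy < 0.0:
                    d = (-half_xy - y) / uy
                    if d < d_exit:
                        d_exit = d

                d_b = d_top if d_top < d_exit else d_exit
                if s < d_b:
                    x += s * ux
                    y += s * uy
                    z += s * uz
                    path += s
                    s = 0.0
                elif d_top <= d_exit:
                    # hit the refractive top surface
                    x += d_top * ux
                    y += d_top * uy
                    z = 0.0
                    path += d_top
                    s -= d_top
                    cos_i = -uz
                    if np.random.random() < _fresnel_unpolarized(n_rel, cos_i):
                        uz = -uz
                    else:
                        w_top += w0
                        r = np.sqrt(x * x + y * y)
                        if r <= r_max:
                            out_path[n_det] = path
                            out_radius[n_det] = r
                            out_weight[n_det] = w0
                            n_det += 1
                        alive = False
                else:
                    # absorbed at bottom or side
                    w_lost += w0
                    alive = False

                if alive and path > path_max:
                    w_resid += w0
                    alive = False

            if not alive:
                break

            # Henyey-Greenstein scatter
            cos_t = _hg_cos(g, np.random.random())
            sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
            phi = 2.0 * np.pi * np.random.random()
            cos_p = np.cos(phi)
            sin_p = np.sin(phi)
            if abs(uz) > 0.99999:
                ux = sin_t * cos_p
                uy = sin_t * sin_p
                uz = cos_t if uz > 0.0 else -cos_t
            else:
                denom = np.sqrt(1.0 - uz * uz)
                ux_n = sin_t * (ux * uz * cos_p - uy * sin_p) / denom + ux * cos_t
                uy_n = sin_t * (uy * uz * cos_p + ux * sin_p) / denom + uy * cos_t
                uz_n = -sin_t * cos_p * denom + uz * cos_t
                norm = np.sqrt(ux_n * ux_n + uy_n * uy_n + uz_n * uz_n)
                ux = ux_n / norm
                uy = uy_n / norm
                uz = uz_n / norm

    return (
        out_path[:n_det],
        out_radius[:n_det],
        out_weight[:n_det],
        w_top / n_photons,
        w_lost / n_photons,
        w_resid / n_photons,
        r_sp,
    )


def run_white_mc(
    medium: TransportMedium,
    n_photons: int,
    seed: int,
    r_max_mm: float = 18.0,
    path_cutoff_diagonals: float = 40.0,
) -> PathRecords:
    """Run a zero-absorption photon random walk and collect top-exit records.

    Parameters
    ----------
    medium
        Slab optical/geometric description; step sampling uses
        ``mu_s = musp / (1 - g)``.
    n_photons
        Photons to launch (>= 1).
    seed
        Seed for the transport RNG; runs are bit-reproducible per seed.
    r_max_mm
        Records are stored only for exit radii up to this value (the weight
        ledger still counts all top exits).
    path_cutoff_diagonals
        Path-length cutoff in units of the slab diagonal; photons exceeding
        it are booked as residual weight.
    """
    if n_photons < 1:
        raise ValueError(f"n_photons must be >= 1, got {n_photons}")
    diag = np.sqrt(2 * medium.slab_xy_mm**2 + medium.slab_z_mm**2)
    path_max = path_cutoff_diagonals * diag
    path, radius, weight, f_top, f_lost, f_resid, r_sp = _transport_kernel(
        medium.mus,
        medium.g,
        medium.n,
        medium.slab_xy_mm / 2.0,
        medium.slab_z_mm,
        int(n_photons),
        int(seed) & 0x7FFFFFFF,
        float(r_max_mm),
        path_max,
    )
    return PathRecords(
        path_mm=path,
        radius_mm=radius,
        weight=weight,
        n_launched=int(n_photons),
        medium=medium,
        seed=int(seed),
        r_max_mm=float(r_max_mm),
        specular_fraction=float(r_sp),
        escaped_top_fraction=float(f_top),
        absorbed_boundary_fraction=float(f_lost),
        residual_fraction=float(f_resid),
    )
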