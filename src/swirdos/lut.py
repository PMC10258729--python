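"""Reflectance look-up tables: Beer-Lambert absorption rescaling of white-MC
path records, LUT construction over (mus', mua) grids, and interpolation.

The LUT is the fast forward model: a grid of spatially resolved diffuse
reflectance Rd (per mm^2 of detector area) over reduced scattering 0.2-10
mm^-1 and absorption 0.001-0.2 mm^-1 at each source-detector separation.
Detection uses annular rings centred on each separation (half-width 1.5 mm
by default), exploiting the radial symmetry of the slab problem; Rd is
normalized per unit ring area so the ring width cancels to first order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .montecarlo import PathRecords, TransportMedium, run_white_mc
from .optics import ProbeGeometry

__all__ = [
    "rescale_absorption",
    "ReflectanceLUT",
    "build_lut",
    "DEFAULT_MUSP_GRID",
    "DEFAULT_MUA_GRID",
]

#: Default optical-property grids: 15 linear mus' nodes over 0.2-10 mm^-1,
#: 20 log-spaced mua nodes over 0.001-0.2 mm^-1 (absorption rescaling of a
#: white run is nearly free, so the mua axis is cheap to refine).
DEFAULT_MUSP_GRID = np.linspace(0.2, 10.0, 15)
DEFAULT_MUA_GRID = np.geomspace(0.001, 0.2, 20)

DEFAULT_RING_HALFWIDTH_MM = 1.5


class LUTRangeError(ValueError):
    """Query outside the tabulated optical-property range (no extrapolation)."""


def _ring_edges(separations: np.ndarray, halfwidth: float) -> np.ndarray:
    seps = np.asarray(separations, dtype=float)
    lo = seps - halfwidth
    hi = seps + halfwidth
    if np.any(lo <= 0):
        raise ValueError("ring inner edge must be positive; reduce halfwidth")
    if np.any(hi[:-1] > lo[1:]):
        raise ValueError("detector rings overlap; reduce halfwidth")
    return np.column_stack([lo, hi])


def rescale_absorption(
    records: PathRecords,
    mua: float | np.ndarray,
    separations_mm,
    ring_halfwidth_mm: float = DEFAULT_RING_HALFWIDTH_MM,
    return_se: bool = False,
) -> np.ndarray:
    """Apply Beer-Lambert absorption to white-MC records and bin into rings.

    Rd(rho) = sum_i w_i exp(-mua L_i) [r_i in ring rho] / (N_launched * A_ring),
    giving reflectance per unit area (mm^-2).  ``mua`` may be a scalar or a
    1-D grid; the result has shape ``(len(mua), n_separations)`` for a grid
    and ``(n_separations,)`` for a scalar.  With ``return_se`` the Monte
    Carlo standard error of each estimate is returned alongside.
    """
    mua_arr = np.atleast_1d(np.asarray(mua, dtype=float))
    if np.any(mua_arr < 0):
        raise ValueError("mua must be >= 0")
    edges = _ring_edges(np.asarray(separations_mm, dtype=float), ring_halfwidth_mm)
    if np.any(edges[:, 1] > records.r_max_mm + 1e-9):
        raise ValueError(
            f"ring outer edge {edges[:, 1].max():g} mm exceeds the recorded "
            f"radius range r_max={records.r_max_mm:g} mm"
        )
    out = np.zeros((mua_arr.size, edges.shape[0]))
    var = np.zeros_like(out)
    for j, (lo, hi) in enumerate(edges):
        mask = (records.radius_mm >= lo) & (records.radius_mm < hi)
        if not np.any(mask):
            continue
        L = records.path_mm[mask]
        w = records.weight[mask]
        area = np.pi * (hi * hi - lo * lo)
        contrib = np.exp(-np.outer(mua_arr, L)) * w  # (n_mua, n_ring_photons)
        norm = records.n_launched * area
        out[:, j] = contrib.sum(axis=1) / norm
        # standard error of the sum estimator (per-photon contributions are
        # i.i.d.; the sum-of-squares dominates for rare heavy contributions)
        var[:, j] = (contrib**2).sum(axis=1) / norm**2
    se = np.sqrt(var)
    if np.isscalar(mua) or np.ndim(mua) == 0:
        return (out[0], se[0]) if return_se else out[0]
    return (out, se) if return_se else out


@dataclass
class ReflectanceLUT:
    """Tabulated diffuse reflectance over (mus', mua, separation).

    ``values[i, j, k]`` is Rd at ``musp_grid[i]``, ``mua_grid[j]``,
    ``separations_mm[k]`` in mm^-2.  Interpolation is bilinear in
    (mus', log mua) and exact at grid nodes; queries outside the grid raise
    :class:`LUTRangeError`.
    """

    musp_grid: np.ndarray
    mua_grid: np.ndarray
    separations_mm: np.ndarray
    values: np.ndarray
    meta: dict
    se: np.ndarray | None = None  # per-cell Monte Carlo standard error

    def __post_init__(self) -> None:
        self.musp_grid = np.asarray(self.musp_grid, dtype=float)
        self.mua_grid = np.asarray(self.mua_grid, dtype=float)
        self.separations_mm = np.asarray(self.separations_mm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.values.shape:
                raise ValueError("se shape must match values shape")
        for name, g in (("musp_grid", self.musp_grid), ("mua_grid", self.mua_grid)):
            if g.ndim != 1 or g.size == 0:
                raise ValueError(f"{name} must be a non-empty 1-D array")
            if g.size > 1 and np.any(np.diff(g) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
        expected = (self.musp_grid.size, self.mua_grid.size, self.separations_mm.size)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        if np.any(self.values < 0):
            raise ValueError("Rd values must be non-negative")

    @property
    def musp_bounds(self) -> tuple[float, float]:
        return float(self.musp_grid[0]), float(self.musp_grid[-1])

    @property
    def mua_bounds(self) -> tuple[float, float]:
        return float(self.mua_grid[0]), float(self.mua_grid[-1])

    def _sep_index(self, separation_mm: float) -> int:
        idx = np.nonzero(np.isclose(self.separations_mm, separation_mm))[0]
        if idx.size == 0:
            raise LUTRangeError(
                f"separation {separation_mm} mm not tabulated "
                f"(available: {self.separations_mm.tolist()})"
            )
        return int(idx[0])

    def lookup(self, musp, mua, separation_mm: float):
        """Interpolate Rd at (mus', mua) for one tabulated separation.

        ``musp`` and ``mua`` may be scalars or broadcastable arrays.
        """
        k = self._sep_index(separation_mm)
        musp_a = np.asarray(musp, dtype=float)
        mua_a = np.asarray(mua, dtype=float)
        tol_s = 1e-9 * max(1.0, abs(self.musp_grid[-1]))
        tol_a = 1e-12
        if np.any(musp_a < self.musp_grid[0] - tol_s) or np.any(
            musp_a > self.musp_grid[-1] + tol_s
        ):
            bad = musp_a[(musp_a < self.musp_grid[0] - tol_s) | (musp_a > self.musp_grid[-1] + tol_s)]
            raise LUTRangeError(
                f"musp query {float(np.atleast_1d(bad)[0]):g} mm^-1 outside grid "
                f"[{self.musp_grid[0]:g}, {self.musp_grid[-1]:g}]"
            )
        if np.any(mua_a < self.mua_grid[0] - tol_a) or np.any(
            mua_a > self.mua_grid[-1] + tol_a
        ):
            bad = mua_a[(mua_a < self.mua_grid[0] - tol_a) | (mua_a > self.mua_grid[-1] + tol_a)]
            raise LUTRangeError(
                f"mua query {float(np.atleast_1d(bad)[0]):g} mm^-1 outside grid "
                f"[{self.mua_grid[0]:g}, {self.mua_grid[-1]:g}]"
            )
        musp_c = np.clip(musp_a, self.musp_grid[0], self.musp_grid[-1])
        mua_c = np.clip(mua_a, self.mua_grid[0], self.mua_grid[-1])

        log_mua_grid = np.log(self.mua_grid)
        i = np.clip(np.searchsorted(self.musp_grid, musp_c) - 1, 0, self.musp_grid.size - 2)
        j = np.clip(np.searchsorted(self.mua_grid, mua_c) - 1, 0, self.mua_grid.size - 2)
        ts = (musp_c - self.musp_grid[i]) / (self.musp_grid[i + 1] - self.musp_grid[i])
        ta = (np.log(mua_c) - log_mua_grid[j]) / (log_mua_grid[j + 1] - log_mua_grid[j])
        v = self.values[..., k]
        out = (
            v[i, j] * (1 - ts) * (1 - ta)
            + v[i + 1, j] * ts * (1 - ta)
            + v[i, j + 1] * (1 - ts) * ta
            + v[i + 1, j + 1] * ts * ta
        )
        return float(out) if np.isscalar(musp) and np.isscalar(mua) else out

    def save(self, path) -> None:
        arrays = dict(
            musp_grid=self.musp_grid,
            mua_grid=self.mua_grid,
            separations_mm=self.separations_mm,
            values=self.values,
            meta=np.str_(json.dumps(self.meta)),
        )
        if self.se is not None:
            arrays["se"] = self.se
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ReflectanceLUT":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                musp_grid=z["musp_grid"],
                mua_grid=z["mua_grid"],
                separations_mm=z["separations_mm"],
                values=z["values"],
                meta=json.loads(str(z["meta"])),
                se=z["se"] if "se" in z.files else None,
            )


def build_lut(
    musp_grid=DEFAULT_MUSP_GRID,
    mua_grid=DEFAULT_MUA_GRID,
    separations_mm=(7.0, 10.0, 13.0, 16.0),
    n_photons: int = 1_000_000,
    seed: int = 0,
    g: float = 0.7,
    n: float = 1.435,
    ring_halfwidth_mm: float = DEFAULT_RING_HALFWIDTH_MM,
    slab_xy_mm: float = 60.0,
    slab_z_mm: float = 100.0,
    path_cutoff_diagonals: float = 40.0,
) -> ReflectanceLUT:
    """Build a reflectance LUT with one white-MC run per mus' grid node.

    The run for node ``i`` uses seed ``seed + i`` so that nodes are
    independent but the whole build is reproducible from one seed.  The LUT
    does not depend on wavelength: wavelengths enter only through the
    optical properties queried at lookup time.
    """
    musp_grid = np.asarray(musp_grid, dtype=float)
    mua_grid = np.asarray(mua_grid, dtype=float)
    separations = np.asarray(separations_mm, dtype=float)
    if musp_grid.size == 0 or mua_grid.size == 0:
        raise ValueError("grids must be non-empty")
    r_max = float(separations.max() + ring_halfwidth_mm + 0.5)
    values = np.empty((musp_grid.size, mua_grid.size, separations.size))
    se = np.empty_like(values)
    for i, musp in enumerate(musp_grid):
        medium = TransportMedium(
            musp=float(musp), g=g, n=n, slab_xy_mm=slab_xy_mm, slab_z_mm=slab_z_mm
        )
        records = run_white_mc(
            medium,
            n_photons,
            seed=seed + i,
            r_max_mm=r_max,
            path_cutoff_diagonals=path_cutoff_diagonals,
        )
        values[i], se[i] = rescale_absorption(
            records, mua_grid, separations, ring_halfwidth_mm, return_se=True
        )
    from . import __version__

    meta = {
        "version": __version__,
        "g": g,
        "n": n,
        "n_photons": int(n_photons),
        "seed": int(seed),
        "ring_halfwidth_mm": ring_halfwidth_mm,
        "slab_xy_mm": slab_xy_mm,
        "slab_z_mm": slab_z_mm,
        "path_cutoff_diagonals": path_cutoff_diagonals,
    }
    return ReflectanceLUT(musp_grid, mua_grid, separations, values, meta, se=se)


def lut_for_geometry(lut: ReflectanceLUT, geometry: ProbeGeometry) -> ReflectanceLUT:
    """Restrict a LUT to the separations of a probe geometry (e.g. the
    9-channel variant that drops the 16 mm ring)."""
    idx = [lut._sep_index(s) for s in geometry.separations_mm]
    return ReflectanceLUT(
        lut.musp_grid,
        lut.mua_grid,
        np.asarray(geometry.separations_mm, dtype=float),
        lut.values[:, :, idx],
        dict(lut.meta),
    )
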