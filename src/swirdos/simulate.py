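"""Randomized emulsion samples and their forward-modelled reflectance.

This is the synthetic-data backbone of the package: compositions are drawn
from the study distributions (water uniform on 0-100 %, scatter amplitude
uniform on 0.2-10 mm^-1 at 980 nm, scatter slope normal with mean 1.29 and
SD 0.52), forward-modelled through the Monte Carlo reflectance LUT, and
optionally corrupted with 5 % relative Gaussian noise per channel.

Three composition modes mirror the phantom experiments:

``sum-to-100``
    water ~ U(0, 100), lipid = 100 - water (pure two-component emulsion).
``d2o-dilution``
    water ~ U(0, 100), lipid ~ U(0, 2), the remainder is D2O; scattering is
    fixed to the 1 % Intralipid values per wavelength (particle
    concentration constant under dilution).
``fixed``
    a caller-supplied list of compositions (phantom series).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .lut import LUTRangeError, ReflectanceLUT
from .optics import (
    INTRALIPID_1PCT_MUSP,
    ChromophoreTable,
    ProbeGeometry,
    SampleComposition,
    ScatteringPowerLaw,
    absorption_at,
    default_table,
    scattering_at,
)

__all__ = [
    "GeneratorConfig",
    "Dataset",
    "draw_composition",
    "forward_reflectance",
    "add_noise",
    "make_dataset",
]

#: Noisy reflectance values are clipped below at this floor (fraction of the
#: noiseless value) so log-normalization stays defined at extreme noise draws.
NOISE_FLOOR_FRACTION = 1e-6


@dataclass(frozen=True)
class GeneratorConfig:
    """Distributional description of the random sample generator."""

    mode: str = "sum-to-100"  # or "d2o-dilution", "fixed"
    amplitude_range: tuple[float, float] = (0.2, 10.0)  # mm^-1 at 980 nm
    slope_mean: float = 1.29
    slope_sd: float = 0.52
    noise_sigma: float = 0.05  # relative, per channel
    d2o_lipid_max_pct: float = 2.0
    fixed_musp: dict[float, float] | None = None  # wavelength -> mus', overrides power law
    fixed_compositions: tuple[SampleComposition, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in ("sum-to-100", "d2o-dilution", "fixed"):
            raise ValueError(f"unknown generator mode {self.mode!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.amplitude_range[0] <= 0 or self.amplitude_range[1] <= self.amplitude_range[0]:
            raise ValueError(f"bad amplitude range {self.amplitude_range}")
        if self.slope_sd < 0:
            raise ValueError("slope SD must be >= 0")

    @staticmethod
    def d2o_dilution(noise_sigma: float = 0.05) -> "GeneratorConfig":
        """Generator for the heavy-water dilution study: fixed 1 % Intralipid
        scattering, trace lipid, remainder split between H2O and D2O."""
        return GeneratorConfig(
            mode="d2o-dilution",
            noise_sigma=noise_sigma,
            fixed_musp=dict(INTRALIPID_1PCT_MUSP),
        )


def draw_composition(
    config: GeneratorConfig,
    rng: np.random.Generator,
    geometry: ProbeGeometry,
    musp_bounds: tuple[float, float],
) -> tuple[SampleComposition, int]:
    """Draw one composition; returns (composition, n_rejected_scatter_draws).

    The (A, b) pair is redrawn until mus'(lambda) stays inside
    ``musp_bounds`` at every probe wavelength, so every drawn sample is
    forward-modelable with the LUT in use.
    """
    rejections = 0
    if config.fixed_musp is not None:
        law = ScatteringPowerLaw(1.0, 0.0)  # placeholder; overridden per channel
    else:
        while True:
            a = rng.uniform(*config.amplitude_range)
            b = rng.normal(config.slope_mean, config.slope_sd)
            law = ScatteringPowerLaw(a, b)
            musp = [scattering_at(law, w) for w in geometry.wavelengths_nm]
            if musp_bounds[0] <= min(musp) and max(musp) <= musp_bounds[1]:
                break
            rejections += 1

    if config.mode == "sum-to-100":
        water = rng.uniform(0.0, 100.0)
        comp = SampleComposition(water, 100.0 - water, 0.0, law)
    elif config.mode == "d2o-dilution":
        water = rng.uniform(0.0, 100.0)
        lipid = rng.uniform(0.0, min(config.d2o_lipid_max_pct, 100.0 - water))
        comp = SampleComposition(water, lipid, 100.0 - water - lipid, law)
    else:
        raise ValueError("draw_composition requires a random mode")
    return comp, rejections


def _channel_properties(
    composition: SampleComposition,
    geometry: ProbeGeometry,
    table: ChromophoreTable,
    fixed_musp: dict[float, float] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-wavelength (mua, musp) arrays in geometry wavelength order."""
    mua = np.array(
        [absorption_at(composition, w, table) for w in geometry.wavelengths_nm]
    )
    if fixed_musp is not None:
        musp = np.array([fixed_musp[w] for w in geometry.wavelengths_nm])
    else:
        musp = np.array(
            [scattering_at(composition.scattering, w) for w in geometry.wavelengths_nm]
        )
    return mua, musp


def forward_reflectance(
    composition: SampleComposition,
    geometry: ProbeGeometry,
    lut: ReflectanceLUT,
    table: ChromophoreTable | None = None,
    fixed_musp: dict[float, float] | None = None,
) -> np.ndarray:
    """Noiseless reflectance vector of a composition, in channel order
    (wavelength-major, separation-minor)."""
    table = table if table is not None else default_table()
    mua, musp = _channel_properties(composition, geometry, table, fixed_musp)
    out = np.empty(geometry.n_channels)
    c = 0
    for iw, w in enumerate(geometry.wavelengths_nm):
        for s in geometry.separations_mm:
            try:
                out[c] = lut.lookup(musp[iw], mua[iw], s)
            except LUTRangeError as e:
                raise LUTRangeError(
                    f"channel {w:g} nm / {s:g} mm out of LUT bounds: {e}"
                ) from e
            c += 1
    return out


def add_noise(vector: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative zero-mean Gaussian noise, i.i.d. per channel:
    x -> x * (1 + eps), eps ~ N(0, sigma^2), floored at a tiny positive value."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    vector = np.asarray(vector, dtype=float)
    if sigma == 0:
        return vector.copy()
    noisy = vector * (1.0 + rng.normal(0.0, sigma, size=vector.shape))
    return np.maximum(noisy, NOISE_FLOOR_FRACTION * np.abs(vector))


@dataclass
class Dataset:
    """Labeled reflectance samples: compositions plus (noisy, clean) vectors."""

    water_pct: np.ndarray
    lipid_pct: np.ndarray
    d2o_pct: np.ndarray
    amplitude: np.ndarray
    slope: np.ndarray
    rd: np.ndarray  # (n, n_channels), noise-added
    rd_clean: np.ndarray  # (n, n_channels), noiseless
    geometry: ProbeGeometry
    config: GeneratorConfig
    seed: int
    rejection_count: int = 0
    extra: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.rd.shape[0]

    @property
    def labels_pct(self) -> np.ndarray:
        """(n, 2) array of (water, lipid) labels in percent."""
        return np.column_stack([self.water_pct, self.lipid_pct])

    def save(self, path) -> None:
        meta = {
            "wavelengths_nm": list(self.geometry.wavelengths_nm),
            "separations_mm": list(self.geometry.separations_mm),
            "mode": self.config.mode,
            "noise_sigma": self.config.noise_sigma,
            "seed": self.seed,
            "rejection_count": self.rejection_count,
        }
        np.savez(
            path,
            water_pct=self.water_pct,
            lipid_pct=self.lipid_pct,
            d2o_pct=self.d2o_pct,
            amplitude=self.amplitude,
            slope=self.slope,
            rd=self.rd,
            rd_clean=self.rd_clean,
            meta=np.str_(json.dumps(meta)),
        )

    @classmethod
    def load(cls, path) -> "Dataset":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            geometry = ProbeGeometry(
                tuple(meta["wavelengths_nm"]), tuple(meta["separations_mm"])
            )
            config = GeneratorConfig(mode=meta["mode"], noise_sigma=meta["noise_sigma"])
            return cls(
                water_pct=z["water_pct"],
                lipid_pct=z["lipid_pct"],
                d2o_pct=z["d2o_pct"],
                amplitude=z["amplitude"],
                slope=z["slope"],
                rd=z["rd"],
                rd_clean=z["rd_clean"],
                geometry=geometry,
                config=config,
                seed=int(meta["seed"]),
                rejection_count=int(meta["rejection_count"]),
            )


def make_dataset(
    n: int,
    config: GeneratorConfig,
    geometry: ProbeGeometry,
    lut: ReflectanceLUT,
    table: ChromophoreTable | None = None,
    seed: int = 0,
) -> Dataset:
    """Generate ``n`` labeled samples (i.i.d. draws, forward model, noise).

    Fixed-composition mode iterates the configured composition list instead
    of drawing (``n`` must equal its length in that case).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    table = table if table is not None else default_table()
    rng = np.random.default_rng(seed)
    musp_bounds = lut.musp_bounds

    if config.mode == "fixed":
        comps = list(config.fixed_compositions)
        if len(comps) != n:
            raise ValueError(
                f"fixed mode: n={n} != {len(comps)} configured compositions"
            )
        rejections = 0
    else:
        comps = []
        rejections = 0
        for _ in range(n):
            comp, rej = draw_composition(config, rng, geometry, musp_bounds)
            comps.append(comp)
            rejections += rej

    # vectorized forward model: one interpolation call per channel
    n_wav = len(geometry.wavelengths_nm)
    mua_mat = np.empty((n, n_wav))
    musp_mat = np.empty((n, n_wav))
    for i, comp in enumerate(comps):
        mua_mat[i], musp_mat[i] = _channel_properties(
            comp, geometry, table, config.fixed_musp
        )
    rd_clean = np.empty((n, geometry.n_channels))
    c = 0
    for iw, w in enumerate(geometry.wavelengths_nm):
        for s in geometry.separations_mm:
            try:
                rd_clean[:, c] = lut.lookup(musp_mat[:, iw], mua_mat[:, iw], s)
            except LUTRangeError as e:
                raise LUTRangeError(
                    f"channel {w:g} nm / {s:g} mm out of LUT bounds: {e}"
                ) from e
            c += 1
    rd = add_noise(rd_clean, config.noise_sigma, rng)
    return Dataset(
        water_pct=np.array([c.water_pct for c in comps]),
        lipid_pct=np.array([c.lipid_pct for c in comps]),
        d2o_pct=np.array([c.d2o_pct for c in comps]),
        amplitude=np.array([c.scattering.amplitude for c in comps]),
        slope=np.array([c.scattering.slope for c in comps]),
        rd=rd,
        rd_clean=rd_clean,
        geometry=geometry,
        config=config,
        seed=int(seed),
        rejection_count=rejections,
    )
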