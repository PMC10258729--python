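"""Chromophore absorption, scattering power law, sample compositions, probe geometry.

Absorption of a water/lipid emulsion is modelled with Beer's law as a linear
sum of pure-chromophore absorption coefficients weighted by volume fraction.
Heavy water (D2O) is treated as spectrally collinear with H2O at one tenth
the magnitude, which is the standard approximation in the 900-1300 nm band.
Reduced scattering follows a power law ``mus'(lam) = A * (lam/lam_ref)**-b``
referenced to 980 nm.

Volume fractions are stored in percent (0-100) throughout the package,
matching how emulsion phantoms are specified; conversion to [0, 1] happens
only inside :func:`absorption_at`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreTable",
    "ScatteringPowerLaw",
    "SampleComposition",
    "ProbeGeometry",
    "absorption_at",
    "scattering_at",
    "default_table",
    "SWIR_WAVELENGTHS",
    "NIR_WAVELENGTHS",
    "SEPARATIONS_MM",
    "INTRALIPID_1PCT_MUSP",
]

#: Probe wavelength sets (nm) and source-detector separations (mm).
SWIR_WAVELENGTHS = (980.0, 1200.0, 1300.0)
NIR_WAVELENGTHS = (900.0, 930.0, 970.0)
SEPARATIONS_MM = (7.0, 10.0, 13.0, 16.0)

# Pure-chromophore absorption coefficients, mm^-1 at unit volume fraction.
# Water: Hale & Querry (1973) / Kou et al. (1993) compilations, rounded.
# Lipid: soybean-oil measurements (van Veen et al. 2005), rounded.
# The lipid band peaks near 1200 nm; water rises monotonically 980->1300 nm.
_DEFAULT_TABLE_CSV = """\
chromophore,wavelength_nm,mua_per_unit_fraction_mm-1,source
water,900,0.0068,Hale&Querry1973
water,930,0.0166,Hale&Querry1973
water,970,0.0353,Hale&Querry1973
water,980,0.0377,Hale&Querry1973
water,1200,0.1036,Hale&Querry1973
water,1300,0.1245,Kou1993
lipid,900,0.0011,vanVeen2005
lipid,930,0.0106,vanVeen2005
lipid,970,0.0020,vanVeen2005
lipid,980,0.0016,vanVeen2005
lipid,1200,0.0500,vanVeen2005
lipid,1300,0.0060,vanVeen2005
"""

# Reduced scattering of a 1% Intralipid suspension at the SWIR probe
# wavelengths, mm^-1 (within the 0.49-0.78 mm^-1 range quoted for such
# suspensions in this band).  Used as the fixed-scattering fixture for the
# D2O dilution experiment, where lipid particle concentration is constant.
INTRALIPID_1PCT_MUSP = {980.0: 0.78, 1200.0: 0.58, 1300.0: 0.49}


class ConfigurationError(ValueError):
    """A table or geometry is inconsistent with the requested computation."""


@dataclass(frozen=True)
class ChromophoreTable:
    """Absorption coefficients of pure chromophores at discrete wavelengths.

    ``entries`` maps ``(chromophore, wavelength_nm)`` to the absorption
    coefficient of the *pure* substance in mm^-1 (i.e. per unit volume
    fraction); ``sources`` carries a provenance tag per entry.
    """

    entries: dict[tuple[str, float], float]
    sources: dict[tuple[str, float], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.entries.items():
            if value <= 0:
                raise ConfigurationError(
                    f"non-positive absorption coefficient for {key}: {value}"
                )

    def mua(self, chromophore: str, wavelength_nm: float) -> float:
        key = (chromophore, float(wavelength_nm))
        try:
            return self.entries[key]
        except KeyError:
            raise ConfigurationError(
                f"no absorption entry for chromophore {chromophore!r} "
                f"at {wavelength_nm} nm"
            ) from None

    def wavelengths(self, chromophore: str) -> list[float]:
        return sorted(w for (c, w) in self.entries if c == chromophore)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ChromophoreTable":
        required = {"chromophore", "wavelength_nm", "mua_per_unit_fraction_mm-1"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"table missing columns: {sorted(missing)}")
        entries: dict[tuple[str, float], float] = {}
        sources: dict[tuple[str, float], str] = {}
        has_source = "source" in frame.columns
        for _, row in frame.iterrows():
            key = (str(row["chromophore"]), float(row["wavelength_nm"]))
            entries[key] = float(row["mua_per_unit_fraction_mm-1"])
            sources[key] = str(row["source"]) if has_source else ""
        return cls(entries=entries, sources=sources)

    @classmethod
    def from_csv(cls, path_or_buffer) -> "ChromophoreTable":
        """Load a table from delimited text with columns
        chromophore, wavelength_nm, mua_per_unit_fraction_mm-1, source."""
        frame = pd.read_csv(path_or_buffer)
        return cls.from_frame(frame)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chromophore": c,
                "wavelength_nm": w,
                "mua_per_unit_fraction_mm-1": v,
                "source": self.sources.get((c, w), ""),
            }
            for (c, w), v in sorted(self.entries.items())
        ]
        return pd.DataFrame(rows)


def default_table() -> ChromophoreTable:
    """The built-in water/lipid absorption fixture table."""
    return ChromophoreTable.from_csv(io.StringIO(_DEFAULT_TABLE_CSV))


@dataclass(frozen=True)
class ScatteringPowerLaw:
    """Reduced-scattering spectrum ``mus'(lam) = A * (lam / lam_ref)**-b``.

    ``amplitude`` (A) is mus' at the reference wavelength, mm^-1; ``slope``
    (b) is the dimensionless scatter power.
    """

    amplitude: float
    slope: float
    reference_nm: float = 980.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.reference_nm <= 0:
            raise ValueError(f"reference wavelength must be > 0, got {self.reference_nm}")


def scattering_at(law: ScatteringPowerLaw, wavelength_nm: float) -> float:
    """Evaluate the reduced scattering coefficient (mm^-1) at a wavelength."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be > 0, got {wavelength_nm}")
    return law.amplitude * (wavelength_nm / law.reference_nm) ** (-law.slope)


@dataclass(frozen=True)
class SampleComposition:
    """Volume-fraction composition (percent) plus scattering spectrum.

    Fractions may sum to less than 100 (the remainder is non-absorbing);
    generators that require water + lipid = 100 enforce that themselves.
    """

    water_pct: float
    lipid_pct: float
    d2o_pct: float = 0.0
    scattering: ScatteringPowerLaw = ScatteringPowerLaw(1.0, 1.29)

    def __post_init__(self) -> None:
        for name in ("water_pct", "lipid_pct", "d2o_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        total = self.water_pct + self.lipid_pct + self.d2o_pct
        if total > 100.0 + 1e-9:
            raise ValueError(f"fractions sum to {total} > 100")

    def with_scattering(self, law: ScatteringPowerLaw) -> "SampleComposition":
        return replace(self, scattering=law)


def absorption_at(
    composition: SampleComposition,
    wavelength_nm: float,
    table: ChromophoreTable,
) -> float:
    """Beer's-law absorption coefficient (mm^-1) of a composition.

    mua = f_water * eps_water + f_lipid * eps_lipid + f_d2o * eps_water / 10,
    with fractions converted from percent to [0, 1].  D2O contributes through
    the water spectrum scaled by exactly 1/10.
    """
    mua = 0.0
    if composition.water_pct > 0 or composition.d2o_pct > 0:
        eps_w = table.mua("water", wavelength_nm)
        mua += composition.water_pct / 100.0 * eps_w
        mua += composition.d2o_pct / 100.0 * eps_w / 10.0
    if composition.lipid_pct > 0:
        mua += composition.lipid_pct / 100.0 * table.mua("lipid", wavelength_nm)
    return mua


@dataclass(frozen=True)
class ProbeGeometry:
    """Wavelength x separation channel set of a multi-distance probe.

    The channel list is the cartesian product in wavelength-major,
    separation-minor order; this ordering is part of the on-disk contract
    for datasets and trained inverse models.
    """

    wavelengths_nm: tuple[float, ...]
    separations_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, values in (
            ("wavelengths_nm", self.wavelengths_nm),
            ("separations_mm", self.separations_mm),
        ):
            arr = np.asarray(values, dtype=float)
            if arr.size == 0 or np.any(arr <= 0):
                raise ValueError(f"{name} must be non-empty and strictly positive")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be sorted strictly ascending")
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm))
        object.__setattr__(self, "separations_mm", tuple(float(s) for s in self.separations_mm))

    @property
    def n_channels(self) -> int:
        return len(self.wavelengths_nm) * len(self.separations_mm)

    def channels(self) -> list[tuple[float, float]]:
        """(wavelength_nm, separation_mm) pairs in stable order."""
        return [(w, s) for w in self.wavelengths_nm for s in self.separations_mm]

    def channel_labels(self) -> list[str]:
        return [f"{w:g}nm_{s:g}mm" for w, s in self.channels()]


def swir_geometry(separations: tuple[float, ...] = SEPARATIONS_MM) -> ProbeGeometry:
    return ProbeGeometry(SWIR_WAVELENGTHS, separations)


def nir_geometry(separations: tuple[float, ...] = SEPARATIONS_MM) -> ProbeGeometry:
    return ProbeGeometry(NIR_WAVELENGTHS, separations)
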