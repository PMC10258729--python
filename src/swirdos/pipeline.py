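"""Raw probe voltages -> calibrated diffuse reflectance, plus SNR and drift.

The probe records, for each wavelength/separation channel, a photodiode
voltage ``Vp`` behind a switchable transimpedance gain (0.5, 1 or 10 MOhm)
together with a dark voltage ``Vd`` taken with the LEDs off.  The pipeline
is linear until the neural network:

1. gain correction and dark subtraction: ``V = (Vp - Vd) / gain`` expressed
   on a 1 MOhm reference gain;
2. calibration against a phantom of known optical properties: the Monte
   Carlo LUT maps the phantom's (mua, mus') to a theoretical Rd per channel
   and the per-channel scale is ``s = Rd_theory / V_cal``;
3. sample reflectance ``Rd = s * V`` feeds the trained inverse model.

Characterization metrics on a dark-subtracted voltage series:
SNR = 10 log10(mean / SD) in dB, and drift as the least-squares slope
normalized to the fitted voltage at t = 0, in % per hour.

Measurement files are delimited text with one row per
(timestamp_s, wavelength_nm, separation_mm, vp_v, vd_v, gain_mohm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .inversion import InverseModel
from .lut import ReflectanceLUT
from .optics import ChromophoreTable, ProbeGeometry, SampleComposition, default_table

__all__ = [
    "GAIN_LEVELS_MOHM",
    "REFERENCE_GAIN_MOHM",
    "correct_frame",
    "CalibrationReference",
    "build_calibration",
    "to_reflectance",
    "snr_db",
    "drift_pct_per_hour",
    "read_measurements",
    "fabricate_voltage_frames",
]

GAIN_LEVELS_MOHM = (0.5, 1.0, 10.0)
REFERENCE_GAIN_MOHM = 1.0

MEASUREMENT_COLUMNS = [
    "timestamp_s",
    "wavelength_nm",
    "separation_mm",
    "vp_v",
    "vd_v",
    "gain_mohm",
]


class CalibrationError(RuntimeError):
    pass


def _check_gains(gain) -> np.ndarray:
    g = np.asarray(gain, dtype=float)
    ok = np.isclose(g[:, None], np.asarray(GAIN_LEVELS_MOHM)[None, :]).any(axis=1)
    if not np.all(ok):
        raise ValueError(
            f"gain values {np.unique(g[~ok])} not in {GAIN_LEVELS_MOHM} MOhm"
        )
    return g


def read_measurements(path_or_buffer) -> pd.DataFrame:
    """Read a delimited measurement file and validate its columns."""
    frame = pd.read_csv(path_or_buffer)
    missing = set(MEASUREMENT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"measurement file missing columns: {sorted(missing)}")
    for _, series in frame.groupby(["wavelength_nm", "separation_mm"]):
        if np.any(np.diff(series["timestamp_s"].to_numpy()) < 0):
            raise ValueError("timestamps must be nondecreasing per channel")
    return frame


def correct_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Gain-correct and dark-subtract; adds a ``v_corrected`` column (volts
    at the 1 MOhm reference gain) and a ``nonpositive`` flag column.

    Rows where the dark voltage exceeds the sample voltage are flagged
    rather than dropped; downstream calibration excludes them.
    """
    gains = _check_gains(frame["gain_mohm"])
    v = (frame["vp_v"].to_numpy() - frame["vd_v"].to_numpy()) / gains * REFERENCE_GAIN_MOHM
    out = frame.copy()
    out["v_corrected"] = v
    out["nonpositive"] = v <= 0
    return out


@dataclass
class CalibrationReference:
    """Per-channel linear scale Rd_theory / V_cal from a known phantom."""

    channels: list[tuple[float, float]]  # (wavelength_nm, separation_mm)
    scale: np.ndarray  # Rd per volt, > 0
    rd_theory: np.ndarray
    v_cal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.scale <= 0):
            raise CalibrationError("calibration scale factors must be > 0")


def _mean_corrected_per_channel(
    frames: pd.DataFrame, geometry: ProbeGeometry
) -> np.ndarray:
    corrected = correct_frame(frames)
    means = np.empty(geometry.n_channels)
    for c, (w, s) in enumerate(geometry.channels()):
        sel = corrected[
            np.isclose(corrected["wavelength_nm"], w)
            & np.isclose(corrected["separation_mm"], s)
            & ~corrected["nonpositive"]
        ]
        if len(sel) == 0:
            raise CalibrationError(f"no usable frames for channel {w:g} nm / {s:g} mm")
        means[c] = sel["v_corrected"].mean()
    return means


def build_calibration(
    frames: pd.DataFrame,
    phantom_mua: dict[float, float],
    phantom_musp: dict[float, float],
    geometry: ProbeGeometry,
    lut: ReflectanceLUT,
) -> CalibrationReference:
    """Derive per-channel scale factors from calibration-phantom frames.

    ``phantom_mua`` / ``phantom_musp`` map wavelength (nm) to the phantom's
    known optical properties, which must lie inside the LUT grid.
    """
    v_cal = _mean_corrected_per_channel(frames, geometry)
    if np.any(v_cal <= 0):
        raise CalibrationError("mean calibration voltage non-positive on a channel")
    rd_theory = np.array(
        [lut.lookup(phantom_musp[w], phantom_mua[w], s) for w, s in geometry.channels()]
    )
    return CalibrationReference(
        channels=geometry.channels(),
        scale=rd_theory / v_cal,
        rd_theory=rd_theory,
        v_cal=v_cal,
        meta={"phantom_mua": phantom_mua, "phantom_musp": phantom_musp},
    )


def to_reflectance(
    frames: pd.DataFrame,
    calibration: CalibrationReference,
    geometry: ProbeGeometry,
) -> np.ndarray:
    """Calibrated Rd vectors, one row per timestamp, channels in geometry order."""
    if geometry.channels() != calibration.channels:
        raise ValueError("channel set differs from the calibration reference")
    corrected = correct_frame(frames)
    times = np.unique(corrected["timestamp_s"].to_numpy())
    out = np.empty((times.size, geometry.n_channels))
    for i, t in enumerate(times):
        at_t = corrected[np.isclose(corrected["timestamp_s"], t)]
        for c, (w, s) in enumerate(geometry.channels()):
            sel = at_t[
                np.isclose(at_t["wavelength_nm"], w)
                & np.isclose(at_t["separation_mm"], s)
            ]
            if len(sel) != 1:
                raise ValueError(
                    f"expected one frame for channel {w:g} nm / {s:g} mm "
                    f"at t={t}, got {len(sel)}"
                )
            out[i, c] = sel["v_corrected"].iloc[0] * calibration.scale[c]
    return out


def snr_db(series: np.ndarray) -> float:
    """SNR of a dark-subtracted voltage series: 10 log10(mean / sample SD).

    Returns +inf for a constant series and NaN when the mean is
    non-positive (undefined SNR).
    """
    v = np.asarray(series, dtype=float)
    if v.size < 2:
        raise ValueError("SNR requires at least 2 samples")
    mean = v.mean()
    sd = v.std(ddof=1)
    if mean <= 0:
        return float("nan")
    if sd == 0:
        return float("inf")
    return float(10.0 * np.log10(mean / sd))


def drift_pct_per_hour(timestamps_s: np.ndarray, series: np.ndarray) -> float:
    """Least-squares drift slope normalized to the fitted initial voltage.

    The series is regressed against time in hours; the result is
    ``100 * slope / intercept`` in % V/h, with the intercept (fitted voltage
    at t = 0 of the series) as the normalizer.
    """
    t = np.asarray(timestamps_s, dtype=float)
    v = np.asarray(series, dtype=float)
    if t.size != v.size or t.size < 2:
        raise ValueError("drift requires matching series of length >= 2")
    t_h = (t - t[0]) / 3600.0
    if np.ptp(t_h) == 0:
        raise ValueError("drift requires a series spanning > 0 time")
    fit = sstats.linregress(t_h, v)
    if fit.intercept <= 0:
        raise ValueError("fitted initial voltage must be positive")
    return float(100.0 * fit.slope / fit.intercept)


def fabricate_voltage_frames(
    compositions: list[SampleComposition],
    geometry: ProbeGeometry,
    lut: ReflectanceLUT,
    true_scale: np.ndarray,
    table: ChromophoreTable | None = None,
    fixed_musp: dict[float, float] | None = None,
    n_frames: int = 10,
    noise_sigma: float = 0.0,
    dark_v: float = 0.05,
    drift_pct_per_hour: float = 0.0,
    gain_mohm: float = 1.0,
    dt_s: float = 1.0,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Synthesize raw voltage frames for a phantom series (test stand-in).

    For each composition the forward model gives Rd per channel; the "true"
    instrument responds with ``Vp = Rd / true_scale * gain + Vd`` plus
    optional relative Gaussian noise and a linear drift term.  Returns one
    measurement DataFrame per composition.
    """
    from .simulate import forward_reflectance  # local import avoids cycle

    table = table if table is not None else default_table()
    rng = np.random.default_rng(seed)
    frames = []
    for comp in compositions:
        rd = forward_reflectance(comp, geometry, lut, table, fixed_musp=fixed_musp)
        rows = []
        for i in range(n_frames):
            t = i * dt_s
            drift_factor = 1.0 + drift_pct_per_hour / 100.0 * (t / 3600.0)
            for c, (w, s) in enumerate(geometry.channels()):
                v_clean = rd[c] / true_scale[c] * drift_factor
                v = v_clean * (1.0 + rng.normal(0.0, noise_sigma)) if noise_sigma else v_clean
                rows.append(
                    {
                        "timestamp_s": t,
                        "wavelength_nm": w,
                        "separation_mm": s,
                        "vp_v": v * gain_mohm / REFERENCE_GAIN_MOHM + dark_v,
                        "vd_v": dark_v,
                        "gain_mohm": gain_mohm,
                    }
                )
        frames.append(pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS))
    return frames


def predict_from_frames(
    frames: pd.DataFrame,
    calibration: CalibrationReference,
    geometry: ProbeGeometry,
    model: InverseModel,
) -> np.ndarray:
    """Full chain: frames -> calibrated Rd -> (water %, lipid %) per timestamp."""
    rd = to_reflectance(frames, calibration, geometry)
    return np.atleast_2d(model.predict(rd, channel_labels=geometry.channel_labels()))
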