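"""Needle-probe thickness measurement from force-displacement curves.

A fine needle is driven vertically into the cartilage at constant speed until
a 0.5 N stop criterion is reached in the subchondral bone.  Two positions are
read off the force-displacement record: (1) the cartilage surface, where the
force first rises persistently out of the pre-contact baseline, and (2) the
cartilage/bone interface, where the loading rate first exceeds a 0.25 N/s
limit and stays above it to the stop force (the bone being much stiffer than
the cartilage).  When no clean rate crossing exists the interface falls back
to the inflection of the smoothed force-displacement curve — the programmatic
analogue of the study's manual correction.  The vertical span between the
two positions, multiplied by the cosine of the surface orientation angle
determined during indentation mapping, is the cartilage thickness normal to
the surface.

Records where either detection fails get status ``"failed"`` and count
toward the needle-probe failure rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .grid import MAX_VALID_ANGLE_DEG

__all__ = [
    "NeedleProbeCurve",
    "ThicknessMeasurement",
    "DetectionConfig",
    "read_needle_curves",
    "detect_surface",
    "detect_interface",
    "compute_thickness",
    "measure_thickness",
]

DEFAULT_SPEED_UM_S = 100.0   # insertion speed (not stated in the study)
DEFAULT_STOP_FORCE_N = 0.5
DEFAULT_RATE_LIMIT_N_S = 0.25


class ProbeFailure(RuntimeError):
    """Surface or interface could not be identified in the record."""


@dataclass(frozen=True)
class NeedleProbeCurve:
    z: np.ndarray                           # vertical needle position, µm, increasing
    F: np.ndarray                           # normal force, N
    speed: float = DEFAULT_SPEED_UM_S       # µm/s
    stop_force: float = DEFAULT_STOP_FORCE_N
    site_id: str = ""

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        F = np.asarray(self.F, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "F", F)
        if len(z) != len(F):
            raise ValueError("z and F lengths differ")
        if np.any(np.diff(z) <= 0):
            raise ValueError("needle position must be monotone increasing")


@dataclass(frozen=True)
class ThicknessMeasurement:
    site_id: str
    status: str                       # "ok" | "failed"
    z_surface: float = float("nan")   # µm
    z_interface: float = float("nan")  # µm
    angle_deg: float = float("nan")
    thickness: float = float("nan")   # µm, angle-corrected


@dataclass(frozen=True)
class DetectionConfig:
    baseline_samples: int = 50
    k_sigma: float = 5.0
    persistence_samples: int = 10
    smooth_window: int = 21       # Savitzky-Golay window for the loading rate
    smooth_order: int = 2
    rate_limit: float = DEFAULT_RATE_LIMIT_N_S  # N/s


def read_needle_curves(path) -> list:
    """Read needle-probe records (TSV: site_id, z_um, F_N; '#' metadata
    comments may carry speed_um_s / stop_force_N)."""
    path = Path(path)
    meta = {}
    with open(path) as f:
        for line in f:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, val = line.lstrip("#").split("=", 1)
                meta[key.strip()] = float(val)
    df = pd.read_csv(path, sep="\t", comment="#")
    if {"z_um", "F_N"} - set(df.columns):
        raise ValueError(f"{path.name}: needle file needs columns z_um, F_N")
    speed = meta.get("speed_um_s", DEFAULT_SPEED_UM_S)
    stop = meta.get("stop_force_N", DEFAULT_STOP_FORCE_N)
    if "site_id" in df.columns:
        return [
            NeedleProbeCurve(g["z_um"].to_numpy(), g["F_N"].to_numpy(),
                             speed=speed, stop_force=stop, site_id=str(site))
            for site, g in df.groupby("site_id", sort=False)
        ]
    return [NeedleProbeCurve(df["z_um"].to_numpy(), df["F_N"].to_numpy(),
                             speed=speed, stop_force=stop, site_id=path.stem)]


def detect_surface(curve: NeedleProbeCurve, config: DetectionConfig | None = None) -> float:
    """First z (µm) where the force exceeds baseline mean + k*sigma and stays
    above for the persistence window."""
    cfg = config or DetectionConfig()
    n0 = min(cfg.baseline_samples, max(len(curve.F) // 10, 5))
    base = curve.F[:n0]
    thr = float(np.mean(base)) + cfg.k_sigma * float(np.std(base))
    above = curve.F > thr
    k = cfg.persistence_samples
    run = np.convolve(above.astype(int), np.ones(k, dtype=int), mode="valid")
    idx = np.nonzero(run == k)[0]
    idx = idx[idx >= n0 - 1] if len(idx) else idx
    if len(idx) == 0:
        raise ProbeFailure("no persistent force rise above baseline (no surface contact)")
    i0 = int(idx[0])
    # sub-sample refinement: interpolate the threshold crossing
    if i0 > 0 and curve.F[i0] > thr and curve.F[i0 - 1] < curve.F[i0]:
        frac = (thr - curve.F[i0 - 1]) / (curve.F[i0] - curve.F[i0 - 1])
        frac = float(np.clip(frac, 0.0, 1.0))
        return float(curve.z[i0 - 1] + frac * (curve.z[i0] - curve.z[i0 - 1]))
    return float(curve.z[i0])


def _loading_rate(curve: NeedleProbeCurve, cfg: DetectionConfig) -> np.ndarray:
    win = min(cfg.smooth_window, len(curve.F) - (1 - len(curve.F) % 2))
    if win < cfg.smooth_order + 2:
        raise ProbeFailure("record too short to estimate a loading rate")
    if win % 2 == 0:
        win -= 1
    dz = float(np.median(np.diff(curve.z)))
    dFdz = savgol_filter(curve.F, win, cfg.smooth_order, deriv=1, delta=dz)
    return dFdz * curve.speed  # N/s


def detect_interface(curve: NeedleProbeCurve, z_surface: float,
                     config: DetectionConfig | None = None) -> float:
    """First z beyond the surface where the smoothed loading rate exceeds the
    0.25 N/s limit and remains above it up to the stop force; falls back to
    the maximum of the smoothed second derivative of F(z)."""
    cfg = config or DetectionConfig()
    if float(np.max(curve.F)) < curve.stop_force:
        raise ProbeFailure(
            "record ends before the stop force (truncated before the bone rise)")
    rate = _loading_rate(curve, cfg)
    beyond = curve.z > z_surface
    reach = curve.F >= curve.stop_force
    i_stop = int(np.nonzero(reach)[0][0]) if np.any(reach) else None
    if i_stop is not None:
        above = rate >= cfg.rate_limit
        # sustained-above flag: True where above from here through the stop
        sustained = np.zeros_like(above)
        j = i_stop
        ok = True
        for i in range(i_stop, -1, -1):
            ok = ok and above[i]
            sustained[i] = ok
        cand = np.nonzero(beyond & sustained)[0]
        if len(cand):
            i0 = int(cand[0])
            if i0 > 0 and rate[i0] > cfg.rate_limit > rate[i0 - 1]:
                frac = (cfg.rate_limit - rate[i0 - 1]) / (rate[i0] - rate[i0 - 1])
                return float(curve.z[i0 - 1]
                             + float(np.clip(frac, 0, 1)) * (curve.z[i0] - curve.z[i0 - 1]))
            return float(curve.z[i0])
    # fallback: inflection point (maximum curvature of F(z)) past the surface
    win = min(cfg.smooth_window, len(curve.F) - (1 - len(curve.F) % 2))
    if win % 2 == 0:
        win -= 1
    if win < cfg.smooth_order + 2:
        raise ProbeFailure("record too short for inflection fallback")
    dz = float(np.median(np.diff(curve.z)))
    d2 = savgol_filter(curve.F, win, max(cfg.smooth_order, 2), deriv=2, delta=dz)
    idx = np.nonzero(beyond)[0]
    if len(idx) == 0 or np.all(d2[idx] <= 0):
        raise ProbeFailure("no interface rise found before end of record")
    i_best = idx[int(np.argmax(d2[idx]))]
    if d2[i_best] <= 1e-12:
        raise ProbeFailure("no inflection found (record truncated before bone rise?)")
    return float(curve.z[i_best])


def compute_thickness(z_surface: float, z_interface: float, angle_deg: float) -> float:
    """Angle-corrected cartilage thickness (µm): (z2 - z1) * cos(theta)."""
    if z_interface <= z_surface:
        raise ValueError("interface position must lie below the surface position")
    if angle_deg >= MAX_VALID_ANGLE_DEG:
        raise ValueError(
            f"surface angle {angle_deg:.1f}° >= {MAX_VALID_ANGLE_DEG:.0f}°: "
            "site must be excluded upstream"
        )
    return float((z_interface - z_surface) * np.cos(np.radians(angle_deg)))


def measure_thickness(curve: NeedleProbeCurve, angle_deg: float,
                      config: DetectionConfig | None = None) -> ThicknessMeasurement:
    """Full per-site measurement; failures are captured in the status field."""
    try:
        z1 = detect_surface(curve, config)
        z2 = detect_interface(curve, z1, config)
        th = compute_thickness(z1, z2, angle_deg)
    except (ProbeFailure, ValueError):
        return ThicknessMeasurement(site_id=curve.site_id, status="failed",
                                    angle_deg=angle_deg)
    return ThicknessMeasurement(site_id=curve.site_id, status="ok",
                                z_surface=z1, z_interface=z2,
                                angle_deg=angle_deg, thickness=th)
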