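"""Stress-relaxation indentation records: parsing, QC and feature extraction.

Each record is a 20 µm / 1 s ramp followed by a 90 s hold along the local
surface normal, producing the classic stress-relaxation shape: a sharp force
rise during the ramp and gradual relaxation toward equilibrium during the
hold.  Features extracted per curve are the peak force (ramp plus a short
window of early hold, to tolerate sampling jitter at the ramp/hold junction),
the force at a prescribed strain on the loading ramp (input to the thin-layer
modulus inversion), and the equilibrium force over the hold tail.

Curves that fail quality control ("atypical": non-monotone ramp loading,
late peak, or low ramp signal-to-noise, typically high-angle peripheral
sites) carry no features and are counted in the acquisition error rate.

TSV dialect (tab-separated, header line): either one file per site-repeat
with columns ``time_s  w_um  F_N``, or a combined file with leading
``site_id  repeat`` columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CurveMeta",
    "IndentationCurve",
    "IndentationFeatures",
    "QCConfig",
    "read_curves",
    "qc_curve",
    "extract_peak_force",
    "force_at_strain",
    "extract_equilibrium_force",
    "extract_features",
]

RAMP_DEPTH_UM = 20.0
RAMP_TIME_S = 1.0
HOLD_TIME_S = 90.0


class CurveFormatError(ValueError):
    """Malformed indentation record."""


@dataclass(frozen=True)
class CurveMeta:
    site_id: str = ""
    repeat: str = "A"
    ramp_depth: float = RAMP_DEPTH_UM   # µm
    ramp_time: float = RAMP_TIME_S      # s
    hold_time: float = HOLD_TIME_S      # s


@dataclass(frozen=True)
class IndentationCurve:
    t: np.ndarray     # s, strictly increasing
    w: np.ndarray     # indentation depth along the surface normal, µm
    F: np.ndarray     # normal force, N
    meta: CurveMeta = field(default_factory=CurveMeta)

    def __post_init__(self):
        t, w, F = (np.asarray(a, dtype=float) for a in (self.t, self.w, self.F))
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "F", F)
        if not (len(t) == len(w) == len(F)):
            raise CurveFormatError("time, displacement and force lengths differ")
        if np.any(np.diff(t) <= 0):
            raise CurveFormatError("time column must be strictly increasing")
        if not np.all(np.isfinite(F)):
            raise CurveFormatError("force column contains non-finite values")
        if np.any(w < -1e-9) or np.any(w > self.meta.ramp_depth * (1 + 1e-6)):
            raise CurveFormatError("displacement outside [0, ramp_depth]")


@dataclass(frozen=True)
class IndentationFeatures:
    qc: str                                   # "pass" | "atypical"
    peak_force: float = float("nan")          # N
    equilibrium_force: float = float("nan")   # N


@dataclass(frozen=True)
class QCConfig:
    """Operational definition of an 'atypical' curve (package defaults;
    the source study reports only the count of atypical curves)."""

    max_negative_increment_fraction: float = 0.10  # of ramp dF steps
    max_ramp_drawdown_fraction: float = 0.20       # drop below running max
    min_snr: float = 5.0                           # peak / ramp noise sd
    peak_delay_tolerance_s: float = 0.5            # peak after ramp end +


def read_curves(path) -> list:
    """Read indentation records from a TSV file or a directory of them."""
    path = Path(path)
    if path.is_dir():
        out = []
        for p in sorted(path.glob("*.tsv")):
            out.extend(read_curves(p))
        return out
    df = pd.read_csv(path, sep="\t", comment="#")
    if {"time_s", "w_um", "F_N"} - set(df.columns):
        missing = sorted({"time_s", "w_um", "F_N"} - set(df.columns))
        raise CurveFormatError(f"{path.name}: missing column(s) {missing}")
    curves = []
    if {"site_id", "repeat"} <= set(df.columns):
        for (site, rep), g in df.groupby(["site_id", "repeat"], sort=False):
            curves.append(
                IndentationCurve(
                    g["time_s"].to_numpy(), g["w_um"].to_numpy(), g["F_N"].to_numpy(),
                    CurveMeta(site_id=str(site), repeat=str(rep)),
                )
            )
    else:
        stem = path.stem
        site, _, rep = stem.rpartition("_")
        curves.append(
            IndentationCurve(
                df["time_s"].to_numpy(), df["w_um"].to_numpy(), df["F_N"].to_numpy(),
                CurveMeta(site_id=site or stem, repeat=rep if site else "A"),
            )
        )
    return curves


def _ramp_slice(curve: IndentationCurve) -> np.ndarray:
    return curve.t <= curve.meta.ramp_time + 1e-9


def qc_curve(curve: IndentationCurve, config: QCConfig | None = None) -> str:
    """Classify a curve as ``"pass"`` or ``"atypical"`` (no errors raised)."""
    cfg = config or QCConfig()
    ramp = _ramp_slice(curve)
    F_ramp = curve.F[ramp]
    if len(F_ramp) < 5:
        return "atypical"
    dF = np.diff(F_ramp)
    if np.mean(dF < 0) > cfg.max_negative_increment_fraction:
        return "atypical"
    running_max = np.maximum.accumulate(F_ramp)
    peak_ramp = running_max[-1]
    if peak_ramp > 0 and np.any(
        running_max - F_ramp > cfg.max_ramp_drawdown_fraction * peak_ramp
    ):
        return "atypical"
    t_peak = curve.t[int(np.argmax(curve.F))]
    if t_peak > curve.meta.ramp_time + cfg.peak_delay_tolerance_s:
        return "atypical"
    # ramp noise from second differences of the force signal
    if len(F_ramp) >= 8:
        sigma = float(np.std(np.diff(F_ramp, n=2))) / np.sqrt(6.0)
        peak = float(np.max(curve.F))
        if sigma > 0 and peak / sigma < cfg.min_snr:
            return "atypical"
        if sigma == 0 and peak <= 0:
            return "atypical"
    return "pass"


def extract_peak_force(curve: IndentationCurve, early_hold_s: float = 1.0) -> float:
    """Peak force (N) over the ramp and the first second of hold."""
    window = curve.t <= curve.meta.ramp_time + early_hold_s + 1e-9
    return float(np.max(curve.F[window]))


def force_at_strain(curve: IndentationCurve, h: float, strain: float = 0.2) -> float:
    """Force (N) interpolated on the loading ramp at depth w = strain * h.

    No extrapolation: raises when the target depth exceeds the ramp depth.
    """
    w_target = strain * h
    if w_target > curve.meta.ramp_depth * (1 + 1e-9):
        raise ValueError(
            f"target depth {w_target:.1f} µm (strain {strain:.0%} of h={h:.0f} µm) "
            f"exceeds the {curve.meta.ramp_depth:.0f} µm ramp depth"
        )
    ramp = _ramp_slice(curve)
    w, F = curve.w[ramp], curve.F[ramp]
    order = np.argsort(w, kind="stable")
    return float(np.interp(w_target, w[order], F[order]))


def extract_equilibrium_force(curve: IndentationCurve, tail_window: float = 10.0) -> float:
    """Mean force (N) over the final ``tail_window`` seconds of the hold."""
    t_end = curve.t[-1]
    hold_len = t_end - curve.meta.ramp_time
    if tail_window > hold_len + 1e-9:
        raise ValueError(
            f"tail window {tail_window} s exceeds the {hold_len:.1f} s hold phase"
        )
    sel = curve.t >= t_end - tail_window - 1e-9
    return float(np.mean(curve.F[sel]))


def extract_features(curve: IndentationCurve, config: QCConfig | None = None,
                     tail_window: float = 10.0) -> IndentationFeatures:
    status = qc_curve(curve, config)
    if status != "pass":
        return IndentationFeatures(qc="atypical")
    return IndentationFeatures(
        qc="pass",
        peak_force=extract_peak_force(curve),
        equilibrium_force=extract_equilibrium_force(curve, tail_window),
    )
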