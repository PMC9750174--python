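"""The 31-site condyle testing grid and per-site surface orientation.

Measurements are taken on a standardized grid of 31 positions over the distal
femoral condyles: 14 on the lateral condyle (L1-L14) and 17 on the medial
(M1-M17), each condyle split into anterior and posterior sub-regions with at
least five sites apiece.  At every site the instrument probes four contact
points (front, back, left, right) on a 0.075 mm scanning cross around the
site centre; the local surface normal is the cross product of the two chords
and the surface orientation angle theta is measured from the vertical
indentation axis.  Sites with theta >= 60 degrees are unreliable and flagged
invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Site",
    "SiteGrid",
    "SurfacePatch",
    "NormalEstimate",
    "load_grid",
    "default_grid",
    "estimate_surface_normal",
    "patch_from_plane",
    "read_patches",
    "MAX_VALID_ANGLE_DEG",
    "PATCH_OFFSET_MM",
]

MAX_VALID_ANGLE_DEG = 60.0
PATCH_OFFSET_MM = 0.075

N_SITES = 31
N_LATERAL = 14
N_MEDIAL = 17
MIN_SUBREGION_SITES = 5


class GridConfigError(ValueError):
    """Malformed or invariant-violating grid configuration."""


@dataclass(frozen=True)
class Site:
    site_id: str
    condyle: str     # "lateral" | "medial"
    subregion: str   # "anterior" | "posterior"
    x_mm: float
    y_mm: float


@dataclass(frozen=True)
class SiteGrid:
    sites: tuple

    def __post_init__(self):
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GridConfigError(f"duplicate site ids: {dup}")
        if len(ids) != N_SITES:
            raise GridConfigError(f"site count != {N_SITES} (got {len(ids)})")
        n_lat = sum(s.condyle == "lateral" for s in self.sites)
        n_med = sum(s.condyle == "medial" for s in self.sites)
        if n_lat != N_LATERAL or n_med != N_MEDIAL:
            raise GridConfigError(
                f"condyle sizes must be {N_LATERAL} lateral / {N_MEDIAL} medial "
                f"(got {n_lat}/{n_med})"
            )
        for cond in ("lateral", "medial"):
            for sub in ("anterior", "posterior"):
                n = sum(s.condyle == cond and s.subregion == sub for s in self.sites)
                if n < MIN_SUBREGION_SITES:
                    raise GridConfigError(
                        f"sub-region {cond}/{sub} has {n} sites; "
                        f"at least {MIN_SUBREGION_SITES} required"
                    )

    def __len__(self):
        return len(self.sites)

    def __getitem__(self, site_id: str) -> Site:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    @property
    def site_ids(self):
        return [s.site_id for s in self.sites]

    def condyle_of(self, site_id: str) -> str:
        return self[site_id].condyle

    def subregion_of(self, site_id: str) -> str:
        s = self[site_id]
        return f"{s.condyle}/{s.subregion}"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.site_id, s.condyle, s.subregion, s.x_mm, s.y_mm) for s in self.sites],
            columns=["site_id", "condyle", "subregion", "x_mm", "y_mm"],
        )


def load_grid(config) -> SiteGrid:
    """Build a validated SiteGrid from a YAML/JSON path, dict, or DataFrame.

    The config lists, per site: ``site_id``, ``condyle``, ``subregion``,
    ``x_mm``, ``y_mm``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as f:
            config = yaml.safe_load(f)
    if isinstance(config, pd.DataFrame):
        records = config.to_dict("records")
    elif isinstance(config, dict):
        records = config.get("sites")
        if records is None:
            raise GridConfigError("grid config missing 'sites' key")
    else:
        records = list(config)
    sites = []
    for i, rec in enumerate(records):
        for key in ("site_id", "condyle", "subregion", "x_mm", "y_mm"):
            if key not in rec or rec[key] is None:
                raise GridConfigError(f"site entry {i} missing field '{key}'")
        if rec["condyle"] not in ("lateral", "medial"):
            raise GridConfigError(
                f"site {rec['site_id']}: condyle must be 'lateral' or 'medial', "
                f"got {rec['condyle']!r}"
            )
        if rec["subregion"] not in ("anterior", "posterior"):
            raise GridConfigError(
                f"site {rec['site_id']}: subregion must be 'anterior' or 'posterior', "
                f"got {rec['subregion']!r}"
            )
        sites.append(
            Site(
                site_id=str(rec["site_id"]),
                condyle=rec["condyle"],
                subregion=rec["subregion"],
                x_mm=float(rec["x_mm"]),
                y_mm=float(rec["y_mm"]),
            )
        )
    return SiteGrid(tuple(sites))


def default_grid() -> SiteGrid:
    """The packaged default 31-site layout.

    Two anterior-to-posterior columns per condyle at 0.15 mm pitch; the
    anteroposterior split (L1-L7 / L8-L14, M1-M8 / M9-M17) is a declared
    configuration default — downstream analysis uses only the labels and
    per-site angles, never the planar coordinates.
    """
    with resources.as_file(resources.files("indentmap.data") / "default_grid.yaml") as p:
        return load_grid(p)


@dataclass(frozen=True)
class SurfacePatch:
    """Four-point contact cross around a site centre (heights in µm)."""

    center_xy_mm: tuple
    z_front: float
    z_back: float
    z_left: float
    z_right: float
    offset_mm: float = PATCH_OFFSET_MM


@dataclass(frozen=True)
class NormalEstimate:
    normal: tuple       # unit vector, +z toward the indenter
    angle_deg: float    # angle between normal and vertical axis
    valid: bool         # False when angle >= 60 deg


def estimate_surface_normal(patch: SurfacePatch) -> NormalEstimate:
    """Surface normal and orientation angle from the four contact heights.

    The normal is the unit cross product of the front->back and left->right
    chord vectors, oriented with positive vertical component.  Convention:
    right-handed axes, front/back along +x/-x, right/left along +y/-y,
    vertical +z toward the indenter; heights in µm, offsets in mm.
    """
    zs = np.array([patch.z_front, patch.z_back, patch.z_left, patch.z_right])
    if not np.all(np.isfinite(zs)):
        raise ValueError("surface patch has non-finite contact heights")
    d_um = patch.offset_mm * 1000.0
    chord_fb = np.array([2 * d_um, 0.0, patch.z_front - patch.z_back])
    chord_lr = np.array([0.0, 2 * d_um, patch.z_right - patch.z_left])
    n = np.cross(chord_fb, chord_lr)
    n /= np.linalg.norm(n)
    if n[2] < 0:
        n = -n
    angle = float(np.degrees(np.arccos(np.clip(n[2], -1.0, 1.0))))
    return NormalEstimate(normal=tuple(n), angle_deg=angle,
                          valid=angle < MAX_VALID_ANGLE_DEG - 1e-9)


def patch_from_plane(angle_deg: float, azimuth_deg: float = 0.0,
                     center_xy_mm=(0.0, 0.0), z0_um: float = 0.0,
                     offset_mm: float = PATCH_OFFSET_MM) -> SurfacePatch:
    """Sample the four contact heights from an inclined plane (test helper
    and generator primitive): the plane has the given inclination to the
    horizontal and downhill azimuth."""
    t = np.tan(np.radians(angle_deg))
    az = np.radians(azimuth_deg)
    gx, gy = t * np.cos(az), t * np.sin(az)
    d = offset_mm * 1000.0

    def z(x, y):
        return z0_um + gx * x + gy * y

    return SurfacePatch(
        center_xy_mm=tuple(center_xy_mm),
        z_front=z(+d, 0), z_back=z(-d, 0), z_left=z(0, -d), z_right=z(0, +d),
        offset_mm=offset_mm,
    )


def read_patches(path) -> dict:
    """Read per-site contact records (TSV: site_id, contact, z_um).

    Returns {site_id: SurfacePatch}.  Sites with missing contact points are
    returned as None (measurement failure; they count toward the acquisition
    error rate).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"site_id", "contact", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"patch file missing columns: {sorted(missing)}")
    out = {}
    for site_id, g in df.groupby("site_id", sort=False):
        zs = dict(zip(g["contact"], g["z_um"]))
        try:
            out[str(site_id)] = SurfacePatch(
                center_xy_mm=(np.nan, np.nan),
                z_front=float(zs["front"]), z_back=float(zs["back"]),
                z_left=float(zs["left"]), z_right=float(zs["right"]),
            )
        except KeyError:
            out[str(site_id)] = None
    return out
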