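"""Forward generator for complete synthetic indentation-mapping studies.

Emulates the measured world of the murine femoral-condyle experiments so the
whole pipeline is testable without raw data: per-site ground truth (thickness,
instantaneous modulus, surface angle) drawn from genotype- and condyle-level
distributions; triplicate stress-relaxation curves whose ramp follows the
thin-layer elastic relation and whose hold decays by a Prony reduced
relaxation; needle-probe curves with a soft cartilage rise and a steep
subchondral-bone rise to the 0.5 N stop; and voxelised condyle-shell phantoms
with landmarks for the volumetric workflow.

Defaults are the study's printed conditions: n=10 control vs n=6 Prg4-/-
knockout specimens, 20 µm / 1 s ramp + 90 s hold, R = 150 µm, nu = 0.5,
4.39 µm voxels; group thickness/modulus means and SDs from the printed
tables (control lateral/medial thickness 60.3/39.8 µm, knockout 67.9/56.3;
moduli 10.85/19.52 vs 8.73/8.67 MPa); repeat-level force noise 4.7 % (the
printed intra-assay CV); atypical-curve and probe-failure injection at the
printed 2.26 % and 2.58 % acquisition error rates.  All randomness flows
from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hayes
from .curves import CurveMeta, IndentationCurve
from .grid import SiteGrid, SurfacePatch, default_grid, patch_from_plane
from .needle import NeedleProbeCurve
from .volume import VolumeImage, save_volume

__all__ = [
    "ProtocolConstants",
    "StudyConfig",
    "GroundTruth",
    "simulate_relaxation_curve",
    "simulate_needle_curve",
    "voxelize_condyle",
    "StudyData",
    "make_study",
    "write_study",
    "read_study",
]


@dataclass(frozen=True)
class ProtocolConstants:
    ramp_depth: float = 20.0    # µm
    ramp_time: float = 1.0      # s
    hold_time: float = 90.0     # s
    R: float = 150.0            # indenter radius, µm
    nu: float = 0.5
    np_speed: float = 100.0     # needle insertion speed, µm/s
    stop_force: float = 0.5     # N
    n_ramp: int = 120           # ramp samples (dense for interpolation)
    n_hold: int = 300


@dataclass(frozen=True)
class StudyConfig:
    n_control: int = 10
    n_knockout: int = 6
    repeats: int = 3
    protocol: ProtocolConstants = field(default_factory=ProtocolConstants)
    voxel_um: float = 4.39
    n_volumes: int = 0          # specimens per genotype to voxelise
    seed: int = 0


@dataclass(frozen=True)
class GroundTruth:
    """Population parameters of the emulated study.

    ``thickness`` / ``modulus``: {genotype: {condyle: (mean, sd)}} with the
    SD at specimen level; site-level scatter is separate.  The knockout
    defaults encode the degenerate phenotype: thicker and softer cartilage,
    most strongly on the medial condyle.
    """

    thickness: dict = field(default_factory=lambda: {
        "control":  {"lateral": (60.3, 6.3), "medial": (39.8, 2.9)},
        "knockout": {"lateral": (67.9, 3.5), "medial": (56.3, 3.7)},
    })
    modulus: dict = field(default_factory=lambda: {
        "control":  {"lateral": (10.85, 1.73), "medial": (19.52, 2.44)},
        "knockout": {"lateral": (8.73, 2.39), "medial": (8.67, 1.79)},
    })
    site_thickness_sd: dict = field(default_factory=lambda: {
        "lateral": 7.0, "medial": 3.0})   # µm, within-specimen site scatter
    site_modulus_rel_sd: float = 0.12     # relative within-specimen scatter
    angle_range_deg: tuple = (5.0, 40.0)
    thickness_bounds: tuple = (28.0, 95.0)  # keeps 20% strain on the ramp
    force_noise: float = 0.047        # multiplicative, one draw per repeat
                                      # (repositioning scatter; sets the
                                      # between-repeat CV of peak force)
    sample_noise: float = 0.001       # multiplicative, per force sample
                                      # (calibrated to the printed ramp-fit
                                      # RMSE of ~0.1% of E)
    baseline_noise_N: float = 2e-4    # additive needle-curve noise
    probe_noise_um: float = 0.5       # needle position jitter
    atypical_rate: float = 0.0226     # injected unusable indentation curves
    np_failure_rate: float = 0.0258   # injected truncated needle records
    prony: tuple = (0.3, 0.4, 1.0, 0.3, 10.0)  # g_inf, g1, tau1, g2, tau2
    cartilage_slope: float = 0.0010   # N/µm (0.10 N/s at 100 µm/s)
    bone_slope: float = 0.0040        # N/µm (0.40 N/s: the 0.25 N/s interface
                                      # criterion sits mid-transition)
    transition_width_um: float = 2.0
    contact_z_um: float = 100.0


def _reduced_relaxation(tau, prony):
    g_inf, g1, t1, g2, t2 = prony
    norm = g_inf + g1 + g2
    return (g_inf + g1 * np.exp(-tau / t1) + g2 * np.exp(-tau / t2)) / norm


def simulate_relaxation_curve(
    E: float,
    h: float,
    protocol: ProtocolConstants = ProtocolConstants(),
    prony=(0.3, 0.4, 1.0, 0.3, 10.0),
    noise: float = 0.0,
    rng=None,
    meta: CurveMeta | None = None,
    sample_noise: float = 0.0,
) -> IndentationCurve:
    """Forward stress-relaxation record for modulus E (MPa), thickness h (µm).

    Ramp force follows the thin-layer elastic relation at each instantaneous
    depth; the hold decays as peak times the Prony reduced relaxation.
    ``noise`` is a multiplicative Gaussian scale drawn once per record (the
    repositioning scatter that sets the between-repeat CV); ``sample_noise``
    is multiplicative Gaussian noise on every force sample (instrument).
    """
    p = protocol
    t_ramp = np.linspace(0.0, p.ramp_time, p.n_ramp + 1)
    t_hold = np.linspace(p.ramp_time, p.ramp_time + p.hold_time, p.n_hold + 1)[1:]
    w_ramp = p.ramp_depth * t_ramp / p.ramp_time
    F_ramp = hayes.hayes_force(E, w_ramp, h, p.R, p.nu)
    F_peak = F_ramp[-1]
    F_hold = F_peak * _reduced_relaxation(t_hold - p.ramp_time, prony)
    t = np.concatenate([t_ramp, t_hold])
    w = np.concatenate([w_ramp, np.full_like(t_hold, p.ramp_depth)])
    F = np.concatenate([F_ramp, F_hold])
    if noise > 0 or sample_noise > 0:
        rng = rng or np.random.default_rng()
        if noise > 0:
            F = F * (1.0 + noise * rng.standard_normal())
        if sample_noise > 0:
            F = F * (1.0 + sample_noise * rng.standard_normal(len(F)))
    m = meta or CurveMeta(ramp_depth=p.ramp_depth, ramp_time=p.ramp_time,
                          hold_time=p.hold_time)
    return IndentationCurve(t, w, F, m)


def _atypical_curve(protocol: ProtocolConstants, scale: float, rng,
                    meta: CurveMeta) -> IndentationCurve:
    """A noisy, unusable record (the high-angle periphery failure mode)."""
    p = protocol
    t = np.linspace(0.0, p.ramp_time + p.hold_time, p.n_ramp + p.n_hold + 1)
    w = np.clip(p.ramp_depth * t / p.ramp_time, 0, p.ramp_depth)
    F = scale * 0.15 * rng.standard_normal(len(t))
    return IndentationCurve(t, w, F, meta)


def simulate_needle_curve(
    h: float,
    angle_deg: float = 0.0,
    cartilage_slope: float = 0.0010,
    bone_slope: float = 0.0040,
    speed: float = 100.0,
    stop_force: float = 0.5,
    transition_width: float = 2.0,
    contact_z: float = 100.0,
    noise: float = 0.0,
    dz: float = 0.5,
    fail: bool = False,
    rng=None,
    site_id: str = "",
) -> NeedleProbeCurve:
    """Needle-probe force-displacement record for true thickness h (µm).

    The needle travels vertically, so the cartilage occupies a span of
    h / cos(theta); force rises softly through cartilage, then steeply in
    bone until the stop force, with a smooth slope transition of the given
    width.  ``fail=True`` truncates the record before the bone rise (the
    injected probe-failure mode).
    """
    span = h / np.cos(np.radians(angle_deg))
    z_i = contact_z + span
    z_max = z_i + (stop_force / bone_slope) + 80.0
    z = np.arange(0.0, z_max, dz)
    zc = z - contact_z
    soft = np.where(zc > 0, cartilage_slope * zc, 0.0)
    # softplus integral of a logistic slope blend from cartilage to bone
    x = (z - z_i) / transition_width
    bump = (bone_slope - cartilage_slope) * transition_width * np.logaddexp(0.0, x)
    F = soft + np.where(z > contact_z, bump, 0.0)
    if noise > 0:
        rng = rng or np.random.default_rng()
        F = F + noise * rng.standard_normal(len(F))
    if fail:
        keep = z <= contact_z + 0.5 * span
        return NeedleProbeCurve(z[keep], F[keep], speed=speed,
                                stop_force=stop_force, site_id=site_id)
    reach = np.nonzero(F >= stop_force)[0]
    end = reach[0] + 1 if len(reach) else len(z)
    return NeedleProbeCurve(z[:end], F[:end], speed=speed,
                            stop_force=stop_force, site_id=site_id)


def voxelize_condyle(
    thickness_um,
    voxel_um: float = 4.39,
    bone_radius_um: float = 180.0,
    length_um: float = 420.0,
    sites: list | None = None,
    two_condyles: bool = False,
    condyle_gap_um: float = 120.0,
    intensity=(20.0, 120.0),
    noise_sd: float = 0.0,
    needle_track_radius_um: float = 0.0,
    rng=None,
    pad_um: float = 20.0,
):
    """Voxelise a half-cylindrical cartilage shell (condyle phantom).

    ``thickness_um`` is a scalar, or a mapping site_id -> thickness when
    ``sites`` (list of site ids) is given: the field then varies smoothly
    between site anchors along the shell.  Returns (VolumeImage, landmarks)
    with landmarks placed at mid-shell on each site, keyed by site_id, in
    (z, y, x) µm coordinates.  ``two_condyles=True`` builds two shells
    separated along x (for condyle splitting).
    """
    rng = rng or np.random.default_rng()
    h_max = float(np.max(list(thickness_um.values()))) if isinstance(thickness_um, dict) \
        else float(thickness_um)
    r_out = bone_radius_um + h_max
    nx_half = int(np.ceil((r_out + pad_um) / voxel_um))
    ny = int(np.ceil(length_um / voxel_um))
    nz = int(np.ceil((r_out + pad_um) / voxel_um)) + 2
    n_shell = 2 if two_condyles else 1
    centers_x = []
    width = 2 * nx_half + 1
    if two_condyles:
        gap_vox = int(np.ceil(condyle_gap_um / voxel_um))
        nx = 2 * width + gap_vox
        centers_x = [nx_half, width + gap_vox + nx_half]
    else:
        nx = width
        centers_x = [nx_half]

    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    vol = np.full((nz, ny, nx), intensity[0], dtype=float)
    landmarks = {}
    site_lists = [None] * n_shell
    if sites is not None:
        lat = [s for s in sites if s.startswith("L")] or list(sites)
        med = [s for s in sites if s.startswith("M")]
        site_lists = [lat, med] if two_condyles else [list(sites)]

    for ci, cx in enumerate(centers_x):
        rad = np.sqrt((xx - cx) ** 2 + zz**2) * voxel_um  # axis at z=0 plane
        phi = np.arctan2((xx - cx) * voxel_um, rad + 1e-9)  # unused for scalar h
        ids = site_lists[ci]
        if isinstance(thickness_um, dict) and ids:
            # smooth axial variation between site anchors
            ys = np.linspace(0.1, 0.9, len(ids)) * length_um
            hs = np.array([thickness_um[s] for s in ids])
            h_field = np.interp(yy * voxel_um, ys, hs)
        else:
            h_field = h_max
        shell = (rad > bone_radius_um) & (rad <= bone_radius_um + h_field)
        vol[shell] = intensity[1]
        if ids:
            ys = np.linspace(0.1, 0.9, len(ids)) * length_um
            for k, sid in enumerate(ids):
                h_here = (thickness_um[sid] if isinstance(thickness_um, dict)
                          else h_max)
                r_mid = bone_radius_um + 0.5 * h_here
                landmarks[sid] = (r_mid, ys[k], cx * voxel_um)  # (z, y, x) µm

    if needle_track_radius_um > 0 and landmarks:
        rt = needle_track_radius_um / voxel_um
        for sid, (lz, ly, lx) in landmarks.items():
            track = (
                ((xx - lx / voxel_um) ** 2 + (yy - ly / voxel_um) ** 2) <= rt**2
            ) & (zz * voxel_um >= lz - 5)
            vol[track] = intensity[0]
    if noise_sd > 0:
        vol = vol + noise_sd * rng.standard_normal(vol.shape)
    return VolumeImage(vol, voxel_um=voxel_um), landmarks


@dataclass
class StudyData:
    """One complete synthetic study, in memory."""

    config: StudyConfig
    truth: GroundTruth
    grid: SiteGrid
    truth_table: pd.DataFrame            # specimen, genotype, site_id, h, E, angle
    patches: dict                        # (specimen, site_id) -> SurfacePatch
    indentation: dict                    # (specimen, site_id, repeat) -> curve
    needle: dict                         # (specimen, site_id) -> curve
    volumes: dict = field(default_factory=dict)   # specimen -> (VolumeImage, landmarks)

    @property
    def specimens(self) -> pd.DataFrame:
        return self.truth_table[["specimen", "genotype"]].drop_duplicates()


def make_study(
    config: StudyConfig | None = None,
    truth: GroundTruth | None = None,
    seed: int | None = None,
    grid: SiteGrid | None = None,
) -> StudyData:
    """Generate a full two-genotype study; deterministic given the seed."""
    cfg = config or StudyConfig()
    gt = truth or GroundTruth()
    grid = grid or default_grid()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    p = cfg.protocol

    repeats = "ABC"[: cfg.repeats]
    rows, patches, indent, needle = [], {}, {}, {}
    specimens = [("control", f"C{i+1:02d}") for i in range(cfg.n_control)] + \
                [("knockout", f"K{i+1:02d}") for i in range(cfg.n_knockout)]
    for genotype, spec in specimens:
        spec_h = {c: rng.normal(*gt.thickness[genotype][c]) for c in ("lateral", "medial")}
        spec_E = {c: rng.normal(*gt.modulus[genotype][c]) for c in ("lateral", "medial")}
        for site in grid.sites:
            c = site.condyle
            h = float(np.clip(rng.normal(spec_h[c], gt.site_thickness_sd[c]),
                              *gt.thickness_bounds))
            E = float(max(rng.normal(spec_E[c], gt.site_modulus_rel_sd * abs(spec_E[c])),
                          1.0))
            angle = float(rng.uniform(*gt.angle_range_deg))
            azimuth = float(rng.uniform(0.0, 360.0))
            rows.append((spec, genotype, site.site_id, h, E, angle))
            patches[(spec, site.site_id)] = patch_from_plane(
                angle, azimuth, center_xy_mm=(site.x_mm, site.y_mm))
            for rep in repeats:
                meta = CurveMeta(site_id=site.site_id, repeat=rep,
                                 ramp_depth=p.ramp_depth, ramp_time=p.ramp_time,
                                 hold_time=p.hold_time)
                if rng.uniform() < gt.atypical_rate:
                    scale = hayes.hayes_force(E, p.ramp_depth, h, p.R, p.nu)
                    indent[(spec, site.site_id, rep)] = _atypical_curve(
                        p, float(scale), rng, meta)
                else:
                    indent[(spec, site.site_id, rep)] = simulate_relaxation_curve(
                        E, h, p, gt.prony, gt.force_noise, rng, meta,
                        sample_noise=gt.sample_noise)
            zc = gt.contact_z_um + float(gt.probe_noise_um * rng.standard_normal())
            needle[(spec, site.site_id)] = simulate_needle_curve(
                h, angle, gt.cartilage_slope, gt.bone_slope, p.np_speed,
                p.stop_force, gt.transition_width_um, zc,
                gt.baseline_noise_N, fail=rng.uniform() < gt.np_failure_rate,
                rng=rng, site_id=site.site_id)

    truth_table = pd.DataFrame(
        rows, columns=["specimen", "genotype", "site_id", "h_um", "E_MPa", "angle_deg"])

    volumes = {}
    for genotype in ("control", "knockout"):
        chosen = truth_table[truth_table.genotype == genotype]["specimen"].unique()
        for spec in chosen[: cfg.n_volumes]:
            tt = truth_table[truth_table.specimen == spec].set_index("site_id")
            h_by_site = tt["h_um"].to_dict()
            vol, lms = voxelize_condyle(
                h_by_site, voxel_um=cfg.voxel_um, sites=list(tt.index),
                two_condyles=True, noise_sd=8.0, rng=rng)
            volumes[spec] = (vol, lms)
    return StudyData(cfg, gt, grid, truth_table, patches, indent, needle, volumes)


def write_study(study: StudyData, outdir) -> Path:
    """Emit the study in the pipeline's file formats (TSV/CSV/YAML/TIFF)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "grid.yaml", "w") as f:
        yaml.safe_dump({"sites": study.grid.to_frame().to_dict("records")}, f,
                       sort_keys=False)
    study.truth_table.to_csv(out / "truth.csv", index=False)
    study.specimens.to_csv(out / "specimens.csv", index=False)
    for spec in study.specimens["specimen"]:
        d = out / spec
        d.mkdir(exist_ok=True)
        pat = [
            {"site_id": sid, "contact": c, "z_um": getattr(p_, f"z_{c}")}
            for (sp, sid), p_ in study.patches.items() if sp == spec
            for c in ("front", "back", "left", "right")
        ]
        pd.DataFrame(pat).to_csv(d / "patches.tsv", sep="\t", index=False)
        rows = []
        for (sp, sid, rep), cv in study.indentation.items():
            if sp != spec:
                continue
            rows.append(pd.DataFrame({
                "site_id": sid, "repeat": rep,
                "time_s": cv.t, "w_um": cv.w, "F_N": cv.F}))
        pd.concat(rows).to_csv(d / "indentation.tsv", sep="\t", index=False,
                               float_format="%.8g")
        nrows = []
        speed = stop = None
        for (sp, sid), nc in study.needle.items():
            if sp != spec:
                continue
            speed, stop = nc.speed, nc.stop_force
            nrows.append(pd.DataFrame({"site_id": sid, "z_um": nc.z, "F_N": nc.F}))
        with open(d / "needle.tsv", "w") as f:
            f.write(f"# speed_um_s = {speed}\n# stop_force_N = {stop}\n")
            pd.concat(nrows).to_csv(f, sep="\t", index=False, float_format="%.8g")
        if spec in study.volumes:
            vol, lms = study.volumes[spec]
            save_volume(vol, d / "xrm.tif")
            pd.DataFrame(
                [(sid, x, y, z) for sid, (z, y, x) in lms.items()],
                columns=["site_id", "x_um", "y_um", "z_um"],
            ).to_csv(d / "landmarks.csv", index=False)
    return out


def read_study(path) -> StudyData:
    """Load a study previously written by :func:`write_study`."""
    from .curves import read_curves
    from .grid import load_grid, read_patches
    from .needle import read_needle_curves
    from .volume import load_volume, read_landmarks

    root = Path(path)
    grid = load_grid(root / "grid.yaml")
    truth_table = pd.read_csv(root / "truth.csv")
    specs = pd.read_csv(root / "specimens.csv")
    patches, indent, needle, volumes = {}, {}, {}, {}
    for spec in specs["specimen"]:
        d = root / spec
        for sid, patch in read_patches(d / "patches.tsv").items():
            patches[(spec, sid)] = patch
        for cv in read_curves(d / "indentation.tsv"):
            indent[(spec, cv.meta.site_id, cv.meta.repeat)] = cv
        for nc in read_needle_curves(d / "needle.tsv"):
            needle[(spec, nc.site_id)] = nc
        if (d / "xrm.tif").exists():
            vol = load_volume(d / "xrm.tif")
            lms = read_landmarks(d / "landmarks.csv")
            volumes[spec] = (vol, lms)
    return StudyData(StudyConfig(), GroundTruth(), grid, truth_table,
                     patches, indent, needle, volumes)
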