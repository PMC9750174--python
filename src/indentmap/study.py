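"""Whole-study analysis: the IndentationStudy model and its results.

``IndentationStudy`` is built from the raw per-site records of one study
(surface patches, triplicate indentation curves, needle-probe curves, and
optionally volumes with landmarks); ``fit()`` runs the full pipeline —
surface angles, curve QC and features, thickness detection, thin-layer
modulus inversion, reliability and agreement statistics, regional pooling
and genotype contrasts — and returns a :class:`StudyResults` with the
per-site table, summary blocks and an accounting of every input record as
used, flagged or missing.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .curves import QCConfig, extract_peak_force, qc_curve
from .grid import SiteGrid, estimate_surface_normal, default_grid
from .hayes import HayesIndentation
from .needle import DetectionConfig, measure_thickness
from .stats import (
    BlandAltmanResult,
    ICCResult,
    RegionSummary,
    bland_altman,
    compare_groups,
    dataset_accounting,
    icc_absolute_single,
    intra_assay_cv,
    pearson_r,
    pool_regions,
    site_cv,
)
from .volume import segment_cartilage, roi_disk_thickness

__all__ = ["IndentationStudy", "StudyResults", "run_study", "table_fixture_check"]

METRICS = ("peak_force_N", "thickness_np_um", "thickness_xrm_um",
           "E_MPa", "rmse_MPa")


@dataclass
class IndentationStudy:
    """Model object over one study's raw records.

    Parameters mirror the file layout written by the synthetic generator;
    ``from_simulation`` and ``from_directory`` are the usual constructors.
    """

    grid: SiteGrid
    patches: dict                  # (specimen, site_id) -> SurfacePatch | None
    indentation: dict              # (specimen, site_id, repeat) -> IndentationCurve
    needle: dict                   # (specimen, site_id) -> NeedleProbeCurve
    genotypes: dict                # specimen -> genotype label
    volumes: dict = field(default_factory=dict)  # specimen -> (VolumeImage, landmarks)
    qc_config: QCConfig = field(default_factory=QCConfig)
    detection_config: DetectionConfig = field(default_factory=DetectionConfig)
    radius_um: float = 150.0
    nu: float = 0.5
    strain: float = 0.2
    parametric: bool = True
    seed: int | None = None

    @classmethod
    def from_simulation(cls, study, **kwargs) -> "IndentationStudy":
        genotypes = dict(zip(study.specimens["specimen"], study.specimens["genotype"]))
        return cls(grid=study.grid, patches=study.patches,
                   indentation=study.indentation, needle=study.needle,
                   genotypes=genotypes, volumes=study.volumes,
                   seed=study.config.seed, **kwargs)

    @classmethod
    def from_directory(cls, path, **kwargs) -> "IndentationStudy":
        from .simulate import read_study

        return cls.from_simulation(read_study(path), **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "StudyResults":
        rows = []
        indent_statuses, np_statuses = [], []
        specimens = sorted({k[0] for k in self.needle} | {k[0] for k in self.indentation})
        repeats = sorted({k[2] for k in self.indentation})
        for spec in specimens:
            for site in self.grid.site_ids:
                rec = {"specimen": spec, "genotype": self.genotypes.get(spec, ""),
                       "site_id": site,
                       "condyle": self.grid.condyle_of(site),
                       "subregion": self.grid.subregion_of(site)}
                patch = self.patches.get((spec, site))
                if patch is None:
                    rec.update(angle_deg=np.nan, angle_valid=False,
                               site_status="no_patch")
                else:
                    est = estimate_surface_normal(patch)
                    rec.update(angle_deg=est.angle_deg, angle_valid=est.valid,
                               site_status="ok" if est.valid else "angle_invalid")
                peaks = {}
                for rep in repeats:
                    curve = self.indentation.get((spec, site, rep))
                    if curve is None:
                        continue
                    status = qc_curve(curve, self.qc_config)
                    indent_statuses.append(status)
                    rec[f"qc_{rep}"] = status
                    if status == "pass":
                        peaks[rep] = extract_peak_force(curve)
                for rep in repeats:
                    rec[f"peak_{rep}"] = peaks.get(rep, np.nan)
                rec["peak_force_N"] = float(np.mean(list(peaks.values()))) \
                    if peaks else np.nan
                rec["cv_pct"] = site_cv(list(peaks.values())) \
                    if len(peaks) >= 2 else np.nan

                ncurve = self.needle.get((spec, site))
                th = np.nan
                if ncurve is not None and rec["site_status"] == "ok":
                    meas = measure_thickness(ncurve, rec["angle_deg"],
                                             self.detection_config)
                    np_statuses.append(meas.status)
                    rec["np_status"] = meas.status
                    if meas.status == "ok":
                        th = meas.thickness
                elif ncurve is not None:
                    rec["np_status"] = "excluded_angle"
                rec["thickness_np_um"] = th

                E = rmse = np.nan
                if np.isfinite(th) and peaks and self.strain * th <= 20.0 + 1e-9:
                    Es, rs = [], []
                    for rep, _ in peaks.items():
                        curve = self.indentation[(spec, site, rep)]
                        try:
                            res = HayesIndentation(
                                curve, th, self.radius_um, self.nu, self.strain
                            ).fit()
                        except ValueError:
                            continue
                        Es.append(res.contact.E)
                        rs.append(res.contact.rmse)
                    if Es:
                        E, rmse = float(np.mean(Es)), float(np.mean(rs))
                rec["E_MPa"], rec["rmse_MPa"] = E, rmse
                rows.append(rec)
        site_table = pd.DataFrame(rows)

        # volumetric site thickness, when volumes are present
        site_table["thickness_xrm_um"] = np.nan
        for spec, (vol, landmarks) in self.volumes.items():
            try:
                cmask = segment_cartilage(vol)
            except Exception as e:  # pragma: no cover - degenerate volumes
                warnings.warn(f"segmentation failed for {spec}: {e}")
                continue
            for site, lm in landmarks.items():
                v = roi_disk_thickness(cmask, lm)
                site_table.loc[(site_table.specimen == spec)
                               & (site_table.site_id == site),
                               "thickness_xrm_um"] = v

        reliability = self._reliability(site_table, repeats)
        agreement = self._method_agreement(site_table)
        regional, contrasts = self._regional(site_table)
        accounting = {
            "indentation": dataset_accounting(indent_statuses),
            "needle_probe": dataset_accounting(np_statuses),
        }
        return StudyResults(
            model=self, site_table=site_table, reliability=reliability,
            agreement=agreement, regional=regional,
            genotype_contrasts=contrasts, accounting=accounting,
        )

    # ------------------------------------------------------------------
    def _reliability(self, site_table: pd.DataFrame, repeats) -> dict:
        out = {}
        peak_cols = [f"peak_{r}" for r in repeats]
        ctrl = site_table[site_table.genotype.isin(["control", ""])]
        if not ctrl.empty and peak_cols:
            cvs = ctrl["cv_pct"].dropna()
            out["intra_assay_cv_pct"] = float(cvs.mean()) if len(cvs) else np.nan
            out["icc"] = {}
            for condyle in ("lateral", "medial"):
                X = ctrl.loc[ctrl.condyle == condyle, peak_cols].to_numpy(dtype=float)
                X = X[~np.isnan(X).any(axis=1)]
                if len(X) >= 3:
                    out["icc"][condyle] = icc_absolute_single(X)
        return out

    def _method_agreement(self, site_table: pd.DataFrame):
        a = site_table["thickness_np_um"].to_numpy(dtype=float)
        b = site_table["thickness_xrm_um"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 3:
            return None
        r, p = pearson_r(a[ok], b[ok])
        ba = bland_altman(a[ok], b[ok])
        return {"pearson_r": r, "pearson_p": p, "bland_altman": ba,
                "n_pairs": int(ok.sum())}

    def _regional(self, site_table: pd.DataFrame):
        regional, summaries = {}, {}
        for genotype, g in site_table.groupby("genotype"):
            regional[genotype] = {}
            for metric in METRICS:
                if metric not in g.columns or g[metric].dropna().empty:
                    continue
                tab = g[["specimen", "site_id", metric]].rename(
                    columns={metric: "value"})
                try:
                    regional[genotype][metric] = pool_regions(
                        tab, self.grid, parametric=self.parametric)
                except ValueError:
                    continue
            summaries[genotype] = regional[genotype]
        contrasts = {}
        genos = sorted(regional)
        if len(genos) == 2:
            g0, g1 = ("control", "knockout") if set(genos) == {"control", "knockout"} \
                else (genos[0], genos[1])
            for metric in ("thickness_np_um", "E_MPa"):
                if metric in regional.get(g0, {}) and metric in regional.get(g1, {}):
                    contrasts[metric] = compare_groups(
                        regional[g0][metric], regional[g1][metric],
                        labels=(g0, g1), parametric=False)
        return regional, contrasts


@dataclass
class StudyResults:
    """Fitted study: per-site estimates, summary blocks, accounting."""

    model: IndentationStudy
    site_table: pd.DataFrame
    reliability: dict
    agreement: dict | None
    regional: dict
    genotype_contrasts: dict
    accounting: dict

    def heatmap_matrix(self, metric: str = "E_MPa") -> pd.DataFrame:
        """Site x specimen matrix of one metric (CSV-ready for heatmaps)."""
        return self.site_table.pivot(index="site_id", columns="specimen",
                                     values=metric).loc[self.model.grid.site_ids]

    def region_table(self, genotype: str, metric: str) -> pd.DataFrame:
        return self.regional[genotype][metric].group_stats

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = ["Automated indentation mapping - study summary",
                 "=============================================="]
        acc = self.accounting
        for block, d in acc.items():
            lines.append(
                f"{block:14s} {d['total']:5d} records, {d['flagged']} flagged "
                f"({d['rate_percent']:.2f}% error rate)")
        rel = self.reliability
        if rel:
            lines.append(f"intra-assay CV (control): {rel.get('intra_assay_cv_pct', float('nan')):.1f}%")
            for condyle, icc in rel.get("icc", {}).items():
                lines.append(
                    f"ICC(A,1) {condyle:8s}: {icc.icc:.3f} "
                    f"({icc.ci_low:.3f}, {icc.ci_high:.3f}), n={icc.n}")
        if self.agreement:
            ba = self.agreement["bland_altman"]
            lines.append(
                f"NP vs XRM: R={self.agreement['pearson_r']:.3f} "
                f"(n={self.agreement['n_pairs']}), bias={ba.bias:.1f} µm "
                f"[{ba.loa_low:.1f}, {ba.loa_high:.1f}]")
        for genotype, metrics in self.regional.items():
            for metric, rs in metrics.items():
                gs = rs.group_stats
                if "lateral" in gs.index and "medial" in gs.index:
                    lines.append(
                        f"{genotype:9s} {metric:16s} lateral "
                        f"{gs.loc['lateral','mean']:8.3f} ({gs.loc['lateral','sd']:.3f})  "
                        f"medial {gs.loc['medial','mean']:8.3f} "
                        f"({gs.loc['medial','sd']:.3f})")
        for metric, df in self.genotype_contrasts.items():
            for r in df.itertuples():
                lines.append(
                    f"contrast {metric} {r.region:18s} diff={r.difference:+.2f} "
                    f"p_adj={r.p_adjusted:.4f}")
        return "\n".join(lines)

    def report_dict(self) -> dict:
        def ser(o):
            if isinstance(o, (ICCResult, BlandAltmanResult)):
                return o.__dict__
            if isinstance(o, RegionSummary):
                return {"group_stats": o.group_stats.to_dict(),
                        "comparisons": o.comparisons.to_dict("records")}
            if isinstance(o, pd.DataFrame):
                return o.to_dict("records")
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        payload = {
            "accounting": self.accounting,
            "reliability": self.reliability,
            "agreement": self.agreement,
            "regional": self.regional,
            "genotype_contrasts": self.genotype_contrasts,
            "provenance": {"package_version": __version__,
                           "seed": self.model.seed},
        }
        return json.loads(json.dumps(payload, default=ser))

    def report_hash(self) -> str:
        blob = json.dumps(self.report_dict(), sort_keys=True) + \
            self.site_table.round(9).to_csv()
        return hashlib.sha256(blob.encode()).hexdigest()

    def save(self, outdir) -> Path:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.site_table.to_csv(out / "site_results.csv", index=False)
        for metric in METRICS:
            if metric in self.site_table.columns and \
                    self.site_table[metric].notna().any():
                self.heatmap_matrix(metric).to_csv(out / f"heatmap_{metric}.csv")
        with open(out / "report.json", "w") as f:
            json.dump(self.report_dict(), f, indent=1)
        with open(out / "summary.txt", "w") as f:
            f.write(self.summary() + "\n")
        return out

    def plot_heatmap(self, metric: str = "E_MPa", ax=None):
        """Quick-look site x specimen heatmap (matplotlib)."""
        import matplotlib.pyplot as plt

        m = self.heatmap_matrix(metric)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 8))
        im = ax.imshow(m.to_numpy(dtype=float), aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(m.index)), m.index, fontsize=6)
        ax.set_xticks(range(len(m.columns)), m.columns, rotation=90, fontsize=6)
        ax.set_title(metric)
        plt.colorbar(im, ax=ax)
        return ax


def run_study(config) -> StudyResults:
    """End-to-end run from a config mapping or YAML path.

    Keys: either ``data_dir`` (analyze files on disk) or ``synthetic``
    (a mapping of StudyConfig overrides); plus optional ``out_dir``,
    ``seed``, ``parametric``.
    """
    import yaml

    from .simulate import StudyConfig, make_study

    if isinstance(config, (str, Path)):
        with open(config) as f:
            config = yaml.safe_load(f)
    config = dict(config or {})
    parametric = bool(config.get("parametric", True))
    if "data_dir" in config:
        model = IndentationStudy.from_directory(config["data_dir"],
                                                parametric=parametric)
    else:
        syn = dict(config.get("synthetic") or {})
        if "seed" in config:
            syn["seed"] = int(config["seed"])
        proto_keys = {k: syn.pop(k) for k in list(syn)
                      if k in ("ramp_depth", "ramp_time", "hold_time", "R", "nu",
                               "np_speed", "stop_force", "n_ramp", "n_hold")}
        from .simulate import ProtocolConstants

        if proto_keys:
            syn["protocol"] = ProtocolConstants(**proto_keys)
        study = make_study(StudyConfig(**syn))
        model = IndentationStudy.from_simulation(study, parametric=parametric)
    results = model.fit()
    if config.get("out_dir"):
        results.save(config["out_dir"])
    return results


def table_fixture_check(table1, grid: SiteGrid | None = None) -> dict:
    """Pool a Table-1-style per-site transcription into condyle summaries.

    ``table1``: CSV path or DataFrame with columns ``site_id``, ``specimen``,
    ``mean_N``, ``cv_pct`` (missing cells empty).  Returns pooled lateral /
    medial (and sub-region) means and SDs across per-specimen means, plus the
    intra-assay CV, exactly as the pooling and CV operations define them.
    """
    grid = grid or default_grid()
    df = table1 if isinstance(table1, pd.DataFrame) else pd.read_csv(table1)
    tab = df.rename(columns={"mean_N": "value"})[["specimen", "site_id", "value"]]
    rs = pool_regions(tab, grid)
    cv = intra_assay_cv(df.rename(columns={"cv_pct": "cv"})[["cv"]])
    return {
        "group_stats": rs.group_stats,
        "specimen_means": rs.specimen_means,
        "comparisons": rs.comparisons,
        "intra_assay_cv_pct": cv,
        "lateral_mean_N": float(rs.group_stats.loc["lateral", "mean"]),
        "medial_mean_N": float(rs.group_stats.loc["medial", "mean"]),
    }
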