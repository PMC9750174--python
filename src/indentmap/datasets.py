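"""Packaged reference data: default grid, per-site peak-force table, kappa table."""

from importlib import resources

import pandas as pd


def _data(name: str):
    return resources.files("indentmap.data") / name


def load_table1() -> pd.DataFrame:
    """Per-site mean peak force (N) and CV (%) transcription (long format:
    site_id, specimen, mean_N, cv_pct; missing cells are NaN)."""
    with resources.as_file(_data("table1_peak_force.csv")) as p:
        return pd.read_csv(p, comment="#")


def load_kappa_table() -> pd.DataFrame:
    """The packaged thin-layer correction-factor table (aspect, nu, kappa)."""
    with resources.as_file(_data("kappa_sphere_bonded_synthetic.csv")) as p:
        return pd.read_csv(p, comment="#")


def default_grid_path():
    return _data("default_grid.yaml")
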