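"""Thin-layer elastic indentation model for cartilage (spherical indenter).

The instantaneous (rapid-loading) response of cartilage is treated as that of
an incompressible elastic layer bonded to rigid bone.  For a sphere of radius
``R`` pressed to depth ``w0`` into a layer of thickness ``h``, the load is

    P = 2 a w0 kappa(a/h, nu) E / (1 - nu^2),        a = sqrt(R w0)

where ``kappa`` is the finite-thickness correction factor (kappa = 2/3
recovers Hertz).  Inverting at a fixed strain ``w0 = 0.2 h`` yields the
instantaneous modulus E reported per testing site.

Units at the interface are the laboratory's: µm for lengths, N for force,
MPa for moduli.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

from ._layer import edge_pressure, kappa_solve

__all__ = [
    "HayesInput",
    "HayesResult",
    "KappaTable",
    "contact_radius",
    "kappa",
    "hayes_force",
    "instantaneous_modulus",
    "fit_ramp_rmse",
    "HayesIndentation",
    "HayesIndentationResults",
]

HERTZ_KAPPA = 2.0 / 3.0

# force [N] from µm lengths and MPa modulus: µm^2 * MPa = 1e-6 N
_UM2_MPA_TO_N = 1e-6


class ExtrapolationError(ValueError):
    """Aspect ratio outside the tabulated/solved kappa range."""


@dataclass(frozen=True)
class HayesInput:
    """Inputs of a single-site modulus inversion (µm / N)."""

    P: float          # indentation force, N
    w0: float         # indentation depth, µm
    h: float          # cartilage thickness, µm
    R: float = 150.0  # indenter radius, µm (0.3 mm sphere)
    nu: float = 0.5   # Poisson's ratio (incompressible instantaneous response)

    def __post_init__(self):
        if self.P <= 0:
            raise ValueError("indentation force must be positive")
        if self.w0 <= 0 or self.h <= 0 or self.R <= 0:
            raise ValueError("w0, h and R must be positive")
        if not 0.0 < self.nu <= 0.5:
            raise ValueError("Poisson's ratio must be in (0, 0.5]")


@dataclass(frozen=True)
class HayesResult:
    """Outcome of a modulus inversion."""

    a: float        # contact radius, µm
    aspect: float   # a/h
    kappa: float    # thin-layer correction factor
    E: float        # instantaneous modulus, MPa
    rmse: float = float("nan")  # ramp-fit RMSE, MPa (when a curve was fitted)


def contact_radius(R: float, w0: float) -> float:
    """Hertzian contact radius a = sqrt(R w0), µm.

    Requires 0 <= w0 < R; the paraboloidal approximation of the sphere (and
    with it the whole thin-layer analysis) breaks down as w0 approaches R.
    """
    if w0 < 0:
        raise ValueError("indentation depth must be non-negative")
    if w0 >= R:
        raise ValueError(
            f"indentation depth w0={w0} µm must be smaller than the indenter radius R={R} µm"
        )
    return float(np.sqrt(R * w0))


def contact_radius_hayes(R: float, w0: float, h: float, nu: float = 0.5) -> float:
    """Contact radius under the edge-pressure-zero (Hayes) contact condition.

    Optional alternative to the Hertzian convention: the contact circle is
    enlarged until the rim pressure vanishes.  Solved by bracketing the
    outermost-ring pressure sign; falls back to sqrt(R w0) when the layer is
    effectively a half-space (where the two conventions coincide).
    """
    a0 = contact_radius(R, w0)
    if a0 / h < 0.05:
        return a0

    def rim(a):
        # rescale: unit contact radius, depth profile w0 - r^2/(2R)
        # delta(rho)/w0 = 1 - (a^2/(2 R w0)) rho^2 ; solver assumes 1 - rho^2/2
        # so solve with an equivalent aspect and scale: use direct solve below.
        return _rim_pressure(a, R, w0, h, nu)

    lo, hi = a0, a0
    flo = rim(lo)
    # rim pressure at the Hertz radius is >= 0 for a bonded layer; expand out
    while rim(hi) > 0 and hi < 4 * a0:
        hi *= 1.2
    if rim(hi) > 0:
        return hi
    if flo <= 0:
        return lo
    return float(brentq(rim, lo, hi, xtol=1e-3 * a0))


def _rim_pressure(a: float, R: float, w0: float, h: float, nu: float) -> float:
    from ._layer import _influence_matrix  # reuse the ring machinery

    n = 80
    j = np.arange(n + 1)
    s = np.sin(0.5 * np.pi * j / n)
    r = 0.5 * (s[:-1] + s[1:])
    A = _influence_matrix(s, r, h / a, min(nu, 0.5 - 1e-12))
    delta = (w0 - (a * r) ** 2 / (2 * R)) / w0
    p = np.linalg.solve(A, delta)
    return float(p[-1])


class KappaTable:
    """Interpolator over a (aspect, nu) grid of correction factors.

    Interpolation is linear in log(aspect) and linear in nu (kappa itself is
    interpolated on a log scale, which is near-linear for this kernel).
    Below the smallest tabulated aspect the factor blends linearly to the
    exact Hertz limit 2/3 at aspect 0; above the largest tabulated aspect an
    :class:`ExtrapolationError` is raised.
    """

    def __init__(self, aspect: np.ndarray, nu: np.ndarray, table: np.ndarray):
        aspect = np.asarray(aspect, dtype=float)
        nu = np.asarray(nu, dtype=float)
        table = np.asarray(table, dtype=float)
        if table.shape != (len(aspect), len(nu)):
            raise ValueError("kappa table shape does not match its grids")
        self.aspect = aspect
        self.nu = nu
        self._interp = RegularGridInterpolator(
            (np.log(aspect), nu), np.log(table), method="linear", bounds_error=True
        )

    @classmethod
    def from_csv(cls, path) -> "KappaTable":
        df = pd.read_csv(path, comment="#")
        piv = df.pivot(index="aspect", columns="nu", values="kappa").sort_index()
        return cls(piv.index.to_numpy(), piv.columns.to_numpy(), piv.to_numpy())

    @classmethod
    def packaged(cls) -> "KappaTable":
        with resources.as_file(
            resources.files("indentmap.data") / "kappa_sphere_bonded_synthetic.csv"
        ) as p:
            return cls.from_csv(p)

    def __call__(self, aspect, nu: float = 0.5):
        aspect = np.asarray(aspect, dtype=float)
        scalar = aspect.ndim == 0
        aspect = np.atleast_1d(aspect)
        if np.any(aspect < 0):
            raise ValueError("aspect ratio must be non-negative")
        if not self.nu.min() <= nu <= self.nu.max():
            raise ExtrapolationError(f"nu={nu} outside tabulated range")
        amax = self.aspect.max()
        if np.any(aspect > amax * (1 + 1e-12)):
            raise ExtrapolationError(
                f"aspect ratio {aspect.max():.3g} exceeds tabulated maximum {amax:.3g}"
            )
        amin = self.aspect.min()
        out = np.empty_like(aspect)
        low = aspect < amin
        if np.any(low):
            k_amin = float(np.exp(self._interp([[np.log(amin), nu]])[0]))
            out[low] = HERTZ_KAPPA + (k_amin - HERTZ_KAPPA) * aspect[low] / amin
        if np.any(~low):
            pts = np.column_stack(
                [np.log(np.clip(aspect[~low], amin, amax)), np.full(np.sum(~low), nu)]
            )
            out[~low] = np.exp(self._interp(pts))
        return float(out[0]) if scalar else out


_default_table: KappaTable | None = None


def _table() -> KappaTable:
    global _default_table
    if _default_table is None:
        _default_table = KappaTable.packaged()
    return _default_table


def kappa(aspect, nu: float = 0.5, *, method: str = "table"):
    """Thin-layer correction factor kappa(a/h, nu).

    ``method="table"`` (default) interpolates the packaged table;
    ``method="solve"`` runs the ring-discretised contact solver directly
    (slower, used for cross-checks and off-table Poisson's ratios).
    """
    if method == "table":
        return _table()(aspect, nu)
    if method == "solve":
        aspect = np.asarray(aspect, dtype=float)
        if aspect.ndim == 0:
            return kappa_solve(float(aspect), nu)
        return np.array([kappa_solve(float(a_), nu) for a_ in aspect])
    raise ValueError(f"unknown kappa method {method!r}")


def hayes_force(E, w, h, R: float = 150.0, nu: float = 0.5, kappa_fn=None):
    """Forward model: force (N) at depth(s) w (µm) for modulus E (MPa)."""
    w = np.asarray(w, dtype=float)
    a = np.sqrt(R * w)
    k = (kappa_fn or _table())(a / h, nu)
    return 2.0 * a * w * k * E / (1.0 - nu**2) * _UM2_MPA_TO_N


def instantaneous_modulus(inp: HayesInput, *, kappa_fn=None) -> HayesResult:
    """Invert the thin-layer relation for the instantaneous modulus (MPa)."""
    a = contact_radius(inp.R, inp.w0)
    aspect = a / inp.h
    k = float((kappa_fn or _table())(aspect, inp.nu))
    E = inp.P * (1.0 - inp.nu**2) / (2.0 * a * inp.w0 * k) / _UM2_MPA_TO_N
    return HayesResult(a=a, aspect=aspect, kappa=k, E=E)


def fit_ramp_rmse(
    curve,
    h: float,
    E_fit: float,
    R: float = 150.0,
    nu: float = 0.5,
    start_fraction: float = 0.05,
    strain: float = 0.2,
    kappa_fn=None,
) -> float:
    """RMSE (MPa) of pointwise apparent moduli along the loading ramp.

    Apparent moduli E_i are computed by inverting the thin-layer relation at
    every ramp sample with depth between ``start_fraction*h`` and
    ``strain*h``; the RMSE is their root-mean-square deviation from the
    fitted modulus.  Requires at least 5 usable ramp points.
    """
    ramp = curve.t <= curve.meta.ramp_time + 1e-9
    w = curve.w[ramp]
    F = curve.F[ramp]
    sel = (w >= start_fraction * h) & (w <= strain * h) & (F > 0)
    if np.sum(sel) < 5:
        raise ValueError("fewer than 5 usable ramp points for the RMSE fit")
    a = np.sqrt(R * w[sel])
    k = (kappa_fn or _table())(a / h, nu)
    E_i = F[sel] * (1.0 - nu**2) / (2.0 * a * w[sel] * k) / _UM2_MPA_TO_N
    return float(np.sqrt(np.mean((E_i - E_fit) ** 2)))


@dataclass
class HayesIndentation:
    """Per-site thin-layer indentation model, statsmodels-style.

    Built from a stress-relaxation :class:`~indentmap.curves.IndentationCurve`
    and the site's needle-probe thickness; ``fit()`` evaluates the model at
    20 % strain (where the instantaneous response is taken as linear elastic
    and flow-independent) and returns a results object with the modulus, its
    ramp-residual-based uncertainty and a ``summary()`` table.
    """

    curve: object
    thickness_um: float
    radius_um: float = 150.0
    nu: float = 0.5
    strain: float = 0.2
    start_fraction: float = 0.05
    kappa_fn: object = None

    def fit(self) -> "HayesIndentationResults":
        from .curves import force_at_strain

        h = self.thickness_um
        P = force_at_strain(self.curve, h, strain=self.strain)
        inp = HayesInput(P=P, w0=self.strain * h, h=h, R=self.radius_um, nu=self.nu)
        res = instantaneous_modulus(inp, kappa_fn=self.kappa_fn)
        rmse = fit_ramp_rmse(
            self.curve, h, res.E, self.radius_um, self.nu,
            self.start_fraction, self.strain, self.kappa_fn,
        )
        ramp = self.curve.t <= self.curve.meta.ramp_time + 1e-9
        w = self.curve.w[ramp]
        n_pts = int(np.sum((w >= self.start_fraction * h) & (w <= self.strain * h)))
        return HayesIndentationResults(
            model=self,
            contact=HayesResult(res.a, res.aspect, res.kappa, res.E, rmse),
            force_N=P,
            n_ramp_points=n_pts,
        )

    def predict(self, w_um, E_MPa: float):
        """Forward force (N) at depth(s) w_um for a given modulus."""
        return hayes_force(E_MPa, w_um, self.thickness_um, self.radius_um,
                           self.nu, self.kappa_fn)


@dataclass
class HayesIndentationResults:
    model: HayesIndentation
    contact: HayesResult
    force_N: float
    n_ramp_points: int

    @property
    def params(self) -> dict:
        return {"E_MPa": self.contact.E}

    @property
    def rmse(self) -> float:
        return self.contact.rmse

    @property
    def bse(self) -> dict:
        # standard error of the mean apparent modulus along the ramp
        n = max(self.n_ramp_points, 1)
        return {"E_MPa": self.contact.rmse / np.sqrt(n)}

    def predict(self, w_um):
        return self.model.predict(w_um, self.contact.E)

    def summary(self) -> str:
        c = self.contact
        m = self.model
        lines = [
            "Thin-layer elastic indentation fit",
            "==================================",
            f"indenter radius R        {m.radius_um:8.1f} µm",
            f"cartilage thickness h    {m.thickness_um:8.2f} µm",
            f"strain (w0/h)            {m.strain:8.2f}",
            f"Poisson's ratio nu       {m.nu:8.2f}",
            "----------------------------------",
            f"force at strain          {self.force_N:8.4f} N",
            f"contact radius a         {c.a:8.2f} µm",
            f"aspect ratio a/h         {c.aspect:8.3f}",
            f"correction factor kappa  {c.kappa:8.3f}",
            f"E (instantaneous)        {c.E:8.3f} MPa",
            f"ramp RMSE                {c.rmse:8.4f} MPa",
            f"se(E)                    {self.bse['E_MPa']:8.4f} MPa  ({self.n_ramp_points} ramp pts)",
        ]
        return "\n".join(lines)
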