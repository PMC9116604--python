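"""Simmons rectangular-barrier tunneling model: forward curve and fitting.

The intermediate-bias Simmons expression for the current density through
a rectangular barrier of height ``phi`` and width ``d`` is

    J(V) = e / (2 pi h d^2) * [ (phi - eV/2) exp(-B sqrt(phi - eV/2))
                              - (phi + eV/2) exp(-B sqrt(phi + eV/2)) ],
    B = 4 pi d sqrt(2 m) / h,

valid while e|V| < 2 phi, with ``e`` the elementary charge, ``m`` the
electron mass and ``h`` Planck's constant; the measured current is
``I = J * area``.  No image-force correction is applied: this is the
standard form for sub-3 nm metal gaps at biases of a few hundred mV.

Fitting is multi-start weighted least squares over (d, phi, area); the
gap distance is the well-determined parameter, while phi and area are
strongly correlated with d, so the fit also reports covariance
diagnostics instead of bare point estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy.optimize import least_squares

if TYPE_CHECKING:  # avoid a circular import with simulate
    from .models import IVSweep

__all__ = [
    "E_CHARGE",
    "M_ELECTRON",
    "PLANCK",
    "SimmonsParams",
    "SimmonsFitResult",
    "OutOfRegimeError",
    "simmons_current",
    "fit_simmons",
    "gap_distance_summary",
]

# CODATA 2018. e and h are exact by the SI definition; m_e is known to
# ~3e-10 relative uncertainty, far beyond what these fits resolve.
E_CHARGE = 1.602176634e-19  # C
M_ELECTRON = 9.1093837015e-31  # kg
PLANCK = 6.62607015e-34  # J s


class OutOfRegimeError(ValueError):
    """Bias outside the intermediate-bias branch (e|V| >= 2 phi)."""


@dataclass(frozen=True)
class SimmonsParams:
    """Rectangular-barrier parameters: gap ``d`` (m), height ``phi`` (J),
    effective tunneling ``area`` (m^2)."""

    d: float
    phi: float
    area: float

    def __post_init__(self) -> None:
        if self.d <= 0 or self.phi <= 0 or self.area <= 0:
            raise ValueError("d, phi and area must all be > 0")

    @classmethod
    def from_bench_units(cls, d_nm: float, phi_eV: float, area_nm2: float) -> "SimmonsParams":
        return cls(d=d_nm * 1e-9, phi=phi_eV * E_CHARGE, area=area_nm2 * 1e-18)

    @property
    def d_nm(self) -> float:
        return self.d * 1e9

    @property
    def phi_eV(self) -> float:
        return self.phi / E_CHARGE

    @property
    def area_nm2(self) -> float:
        return self.area * 1e18


def simmons_current(params: SimmonsParams, bias: "np.ndarray | float") -> np.ndarray:
    """Tunneling current (A) at the given bias(es), odd in V, I(0) = 0."""
    V = np.asarray(bias, dtype=float)
    half = E_CHARGE * V / 2.0
    if np.any(np.abs(half) >= params.phi):
        raise OutOfRegimeError(
            f"bias exceeds the model regime e|V| < 2 phi "
            f"(phi = {params.phi_eV:.3g} eV)"
        )
    b = 4.0 * np.pi * params.d * np.sqrt(2.0 * M_ELECTRON) / PLANCK
    lo = params.phi - half
    hi = params.phi + half
    j = (E_CHARGE / (2.0 * np.pi * PLANCK * params.d**2)) * (
        lo * np.exp(-b * np.sqrt(lo)) - hi * np.exp(-b * np.sqrt(hi))
    )
    out = j * params.area
    return out if out.shape else float(out)


@dataclass(frozen=True)
class SimmonsFitResult:
    params: SimmonsParams
    residual_rms: float
    converged: bool
    cost: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")


_DEFAULT_BOUNDS = {
    "d_nm": (1.0, 4.0),
    "phi_eV": (1.0, 5.0),
    "area_nm2": (1.0, 100.0),
}


def fit_simmons(
    sweep: "IVSweep",
    init: SimmonsParams | None = None,
    bounds: dict | None = None,
    fix_phi_eV: float | None = None,
    weights: np.ndarray | None = None,
) -> SimmonsFitResult:
    """Fit (d, phi, area) to an I-V sweep by multi-start least squares.

    Starts a bounded trust-region solver from a log-spaced grid of
    initial gaps (1-4 nm) and barrier heights (1-5 eV) plus any
    user-supplied ``init`` and returns the best converged start.
    Residuals are unweighted by default (uniform current noise); pass
    per-point ``weights`` to override.  Non-convergence is reported via
    ``converged=False`` rather than raised.

    ``diagnostics`` carries the scaled-parameter correlation matrix,
    approximate 1-sigma errors and the Jacobian condition number: with
    phi free, d/phi/area are mutually correlated and the d confidence
    interval widens quickly with noise, so point estimates alone are not
    trustworthy.
    """
    if sweep.n_points < 5:
        raise ValueError("need at least 5 sweep points")
    if not np.any(sweep.current != 0):
        raise ValueError("all-zero currents cannot constrain the model")
    bnd = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnd.update(bounds)

    i_obs = sweep.current
    scale = np.max(np.abs(i_obs))
    w = np.ones_like(i_obs) if weights is None else np.asarray(weights, float)

    free_phi = fix_phi_eV is None
    vmax = float(np.max(np.abs(sweep.bias)))

    def residuals(theta: np.ndarray) -> np.ndarray:
        d_nm, phi_eV, area_nm2 = theta
        if not free_phi:
            phi_eV = fix_phi_eV
        p = SimmonsParams.from_bench_units(d_nm, phi_eV, area_nm2)
        return w * (simmons_current(p, sweep.bias) - i_obs) / scale

    lo = np.array([bnd["d_nm"][0], bnd["phi_eV"][0], bnd["area_nm2"][0]])
    hi = np.array([bnd["d_nm"][1], bnd["phi_eV"][1], bnd["area_nm2"][1]])
    # keep every candidate phi inside the formula's regime e|V| < 2 phi
    lo[1] = max(lo[1], 0.55 * vmax)

    d_starts = np.geomspace(bnd["d_nm"][0], bnd["d_nm"][1], 3)
    phi_starts = np.geomspace(max(bnd["phi_eV"][0], 0.55 * vmax), bnd["phi_eV"][1], 3)
    starts = [
        np.array([d0, p0, 10.0 if bnd["area_nm2"][0] <= 10.0 <= bnd["area_nm2"][1] else np.sqrt(bnd["area_nm2"][0] * bnd["area_nm2"][1])])
        for d0 in d_starts
        for p0 in phi_starts
    ]
    if init is not None:
        starts.insert(0, np.array([init.d_nm, init.phi_eV, init.area_nm2]))

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except (ValueError, OutOfRegimeError):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-18:  # residuals at solver noise floor: done
            break
    if best is None:
        raise RuntimeError("no fit start was feasible")

    d_nm, phi_eV, area_nm2 = best.x
    if not free_phi:
        phi_eV = fix_phi_eV
    params = SimmonsParams.from_bench_units(d_nm, phi_eV, area_nm2)
    resid = simmons_current(params, sweep.bias) - i_obs
    rms = float(np.sqrt(np.mean(resid**2)))

    jac = best.jac
    jtj = jac.T @ jac
    dof = max(sweep.n_points - jac.shape[1], 1)
    diagnostics: dict = {"condition_number": float(np.linalg.cond(jtj))}
    try:
        cov = np.linalg.inv(jtj) * 2.0 * best.cost / dof
        sd = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sd, sd)
        diagnostics["param_sd"] = {
            "d_nm": float(sd[0]), "phi_eV": float(sd[1]), "area_nm2": float(sd[2])
        }
        diagnostics["correlation"] = corr
    except np.linalg.LinAlgError:
        diagnostics["param_sd"] = None
        diagnostics["correlation"] = None
    return SimmonsFitResult(
        params=params,
        residual_rms=rms,
        converged=bool(best.status > 0),
        cost=float(best.cost),
        diagnostics=diagnostics,
    )


def gap_distance_summary(
    fits: "list[SimmonsFitResult]",
    window: tuple[float, float] = (1.5e-9, 3.1e-9),
) -> dict:
    """Mean +/- sd of fitted gap distances over converged fits.

    ``window`` (meters) is the usable-gap selection range; the count of
    fits falling inside it is reported alongside the moments.  A single
    fit yields sd = 0 with a degenerate-sd warning flag.
    """
    d = np.array([f.params.d for f in fits if f.converged])
    if d.size == 0:
        raise ValueError("no converged fits")
    degenerate = d.size < 2
    if degenerate:
        warnings.warn("sd of a single gap distance is degenerate", stacklevel=2)
    return {
        "mean_d": float(d.mean()),
        "sd_d": 0.0 if degenerate else float(d.std(ddof=1)),
        "n": int(d.size),
        "n_in_window": int(np.sum((d >= window[0]) & (d <= window[1]))),
        "degenerate_sd": degenerate,
    }
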