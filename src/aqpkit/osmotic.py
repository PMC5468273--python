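"""Forward model of Xenopus-oocyte volume change under osmotic/solute gradients.

The oocyte is treated as a single well-mixed compartment of osmotically
active volume ``V`` bounded by a membrane of fixed surface area ``S``.
Water flux follows the osmotic gradient,

    dV/dt = Pf * S * Vw * (osm_in(t) - osm_out),

with the internal osmolyte amount conserved, so ``osm_in(t) = osm_in0 *
V0 / V(t)`` in a water-only experiment.  In a solute-challenge
experiment a permeant test solute (glycerol or urea) additionally
crosses the membrane,

    ds/dt = Ps * S * (sol_out - sol_in(t)),      sol_in = s / V,

and contributes ``sol_in`` to the internal osmolarity while the bath
osmolarity ``osm_out`` is taken as the *total* bath osmolarity
(impermeant background plus test solute).

Swelling is first-order and relaxes monotonically toward the
equilibrium ratio ``V/V0 = osm_in0/osm_out``; there is no overshoot.
The model deliberately omits membrane tension, unstirred layers and any
non-osmotic (solid) volume fraction, and holds S constant during
swelling — the same idealizations under which the initial-slope
permeability formulas are exact.  At large V/V0 a real oocyte unfolds
membrane so the constant-S assumption progressively underestimates the
true water flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .units import mm_to_internal, mosm_to_internal

__all__ = [
    "OocyteGeometry",
    "BathCondition",
    "Trajectory",
    "IntegrationError",
    "simulate_water_swelling",
    "simulate_solute_swelling",
    "equilibrium_relative_volume",
    "analytic_initial_slope_water",
    "apply_mercury",
]


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails to converge."""


@dataclass(frozen=True)
class OocyteGeometry:
    """Physical constants of the standard oocyte.

    Attributes
    ----------
    v0 : float
        Average initial oocyte volume, cm^3.
    s : float
        Average initial oocyte surface area, cm^2 (held fixed).
    vw : float
        Molar volume of water, cm^3/mol.
    """

    v0: float = 9e-4
    s: float = 0.045
    vw: float = 18.0

    def __post_init__(self) -> None:
        if not (self.v0 > 0 and self.s > 0 and self.vw > 0):
            raise ValueError("oocyte geometry constants must be strictly positive")

    @property
    def radius(self) -> float:
        """Sphere-equivalent radius, cm."""
        return (3.0 * self.v0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def cross_section(self) -> float:
        """Sphere-equivalent cross-sectional area A0 = pi r^2, cm^2."""
        return math.pi * self.radius**2


@dataclass(frozen=True)
class BathCondition:
    """External bath during a swelling record.

    ``osm_out`` is the total bath osmolarity (mOsm), including any test
    solute; ``sol_out`` is the test-solute concentration (mM), zero for
    a water-only (hypo-osmotic) challenge.  ``hg_treated``/``reversal``
    record pre-incubation in HgCl2 and subsequent 2-mercaptoethanol
    rescue.
    """

    osm_out: float
    sol_out: float = 0.0
    solute: str = "water-only"
    hg_treated: bool = False
    reversal: bool = False

    def __post_init__(self) -> None:
        if not (np.isfinite(self.osm_out) and self.osm_out >= 0):
            raise ValueError("osm_out must be finite and >= 0")
        if not (np.isfinite(self.sol_out) and self.sol_out >= 0):
            raise ValueError("sol_out must be finite and >= 0")
        if self.solute == "water-only" and self.sol_out != 0:
            raise ValueError("water-only bath must have sol_out = 0")


@dataclass
class Trajectory:
    """A simulated swelling record sampled on a regular time grid."""

    times: np.ndarray          # s
    relative_volume: np.ndarray  # V/V0, dimensionless
    internal_osm: np.ndarray   # total internal osmolarity, mOsm
    internal_sol: np.ndarray   # internal test-solute concentration, mM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.relative_volume = np.asarray(self.relative_volume, dtype=float)
        if self.times.size < 2 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 samples")
        if not math.isclose(self.relative_volume[0], 1.0, rel_tol=1e-9):
            raise ValueError("relative volume must start at 1")


def _check_common(pf: float, duration: float, dt: float) -> None:
    for name, val in (("pf", pf), ("duration", duration), ("dt", dt)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")
    if pf < 0:
        raise ValueError("pf must be >= 0")
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be > 0")


def _time_grid(duration: float, dt: float) -> np.ndarray:
    n = int(round(duration / dt))
    return np.linspace(0.0, n * dt, n + 1)


def _integrate(rhs, y0, times, v_scale: float):
    sol = solve_ivp(
        rhs,
        (times[0], times[-1]),
        y0,
        t_eval=times,
        method="RK45",
        rtol=1e-10,
        atol=v_scale * 1e-13,
    )
    if not sol.success:
        raise IntegrationError(f"ODE integration failed: {sol.message}")
    return sol.y


def analytic_initial_slope_water(
    geom: OocyteGeometry, pf: float, osm_in0: float, osm_out: float
) -> float:
    """Closed-form d(V/V0)/dt at t=0: Pf*S*Vw*(osm_in0-osm_out)/V0, 1/s."""
    d_osm = mosm_to_internal(osm_in0) - mosm_to_internal(osm_out)
    return pf * geom.s * geom.vw * d_osm / geom.v0


def simulate_water_swelling(
    geom: OocyteGeometry,
    pf: float,
    osm_in0: float,
    bath: BathCondition,
    duration: float,
    dt: float,
) -> Trajectory:
    """Simulate a water-only swelling record.

    Internal osmolyte amount ``osm_in0 * V0`` is conserved; the bath is
    an infinite reservoir at ``bath.osm_out``.  Returns the trajectory
    sampled at ``0, dt, 2 dt, ...`` up to ``duration``.
    """
    _check_common(pf, duration, dt)
    if not np.isfinite(osm_in0) or osm_in0 < 0:
        raise ValueError("osm_in0 must be finite and >= 0")
    if bath.sol_out != 0:
        raise ValueError("water-only simulation requires sol_out = 0")

    times = _time_grid(duration, dt)
    n_osm = mosm_to_internal(osm_in0) * geom.v0  # osmol, conserved
    c_out = mosm_to_internal(bath.osm_out)
    k = pf * geom.s * geom.vw  # cm^3/s per (osmol/cm^3)

    if pf == 0.0 or osm_in0 == bath.osm_out:
        v = np.full_like(times, geom.v0)
    else:
        def rhs(_t, y):
            return [k * (n_osm / y[0] - c_out)]

        v = _integrate(rhs, [geom.v0], times, geom.v0)[0]

    vv0 = v / geom.v0
    osm_in = np.where(v > 0, n_osm / v, np.inf) / mosm_to_internal(1.0)
    return Trajectory(times, vv0, osm_in, np.zeros_like(times))


def simulate_solute_swelling(
    geom: OocyteGeometry,
    pf: float,
    ps: float,
    osm_in0: float,
    bath: BathCondition,
    duration: float,
    dt: float,
) -> Trajectory:
    """Simulate an isosmotic solute-challenge record.

    State is (V, s) with s the internal amount of test solute (mol);
    solute flux is ``Ps*S*(sol_out - s/V)`` and water flux follows the
    *total* osmotic imbalance ``(n_osm + s)/V - osm_out``.  With ps=0
    and an isosmotic bath the volume stays at V0; with pf=0 solute
    enters but water cannot follow, so the volume barely moves.
    """
    _check_common(pf, duration, dt)
    if not np.isfinite(ps) or ps < 0:
        raise ValueError("ps must be >= 0 and finite")
    if not np.isfinite(osm_in0) or osm_in0 < 0:
        raise ValueError("osm_in0 must be finite and >= 0")

    times = _time_grid(duration, dt)
    n_osm = mosm_to_internal(osm_in0) * geom.v0  # impermeant osmol, conserved
    c_out = mosm_to_internal(bath.osm_out)
    sol_out = mm_to_internal(bath.sol_out)
    kw = pf * geom.s * geom.vw
    ks = ps * geom.s

    def rhs(_t, y):
        v, s = y
        dv = kw * ((n_osm + s) / v - c_out)
        dsol = ks * (sol_out - s / v)
        return [dv, dsol]

    v, s = _integrate(rhs, [geom.v0, 0.0], times, geom.v0)
    vv0 = v / geom.v0
    osm_in = ((n_osm + s) / v) / mosm_to_internal(1.0)
    sol_in = (s / v) / mm_to_internal(1.0)
    return Trajectory(times, vv0, osm_in, sol_in)


def equilibrium_relative_volume(osm_in0: float, osm_out: float) -> float:
    """Equilibrium V/V0 = osm_in0/osm_out for the conserved-osmolyte model.

    ``osm_out = 0`` is rejected (swelling is unbounded).  ``osm_in0 = 0``
    returns 0, the model's mathematical limit; a real oocyte cannot shrink
    below its non-osmotic volume, so treat values near 0 as a model floor.
    """
    if osm_out <= 0:
        raise ValueError("osm_out must be > 0 (zero gradient sink: unbounded swelling)")
    if osm_in0 < 0:
        raise ValueError("osm_in0 must be >= 0")
    return osm_in0 / osm_out


def apply_mercury(
    pf: float,
    bath: BathCondition,
    inhibition_factor: float = 0.2,
    reversal_recovery: float = 0.9,
) -> float:
    """Effective Pf after optional Hg2+ block and 2-mercaptoethanol rescue.

    Hg2+ is modeled as a multiplicative reduction of Pf (default to 20%
    of the untreated value); reversal restores the factor toward 1
    (default 90%).  Binding kinetics are intentionally not modeled.
    """
    if not bath.hg_treated:
        return pf
    factor = reversal_recovery if bath.reversal else inhibition_factor
    return pf * factor
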