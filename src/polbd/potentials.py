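"""Energy landscapes and analytic generalized forces for both models.

Two pluggable well shapes are provided.  Escape statistics from a deep well
depend mainly on the well depth and bottom curvature, not on the detailed
shape, so the two forms are built with identical depth and identical bottom
curvature (2·depth/A²) and serve as a robustness pair:

* ``morse``:    w(ρ) = depth·[(1 − e^(−ρ/A))² − 1]
* ``gaussian``: w(ρ) = −depth·e^(−(ρ/A)²)

Rigid model: the flap-DNA particle at (x, y, z) feels two identical wells, one
at the polymerase active site (origin) and one at the 5'-nuclease active site
(7, 0, 0) nm.

Flexible model: the 5'-nuclease domain is a sphere of radius r whose pose is
(x, y, θ).  It carries (i) the entropic-spring energy ½KR² of the linker,
stretched by R(pose), (ii) a binding well of depth V0 centred at the active
pose (−r, d, π) in the scaled coordinates ((x+r)/A, (y−d)/A, (θ−π)/B) with
r·B = A, and (iii) optionally an external load along x with a lever torque.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WELL_FORMS",
    "PotentialSpec",
    "RigidPotential",
    "linker_extension",
    "spring_energy",
    "spring_forces",
    "binding_well_energy",
    "binding_well_forces",
    "flexible_energy",
    "flexible_generalized_forces",
]

WELL_FORMS = ("morse", "gaussian")


def _well(rho: np.ndarray, depth: float, A: float, form: str):
    """Radial well value and d/dρ, vectorized.  Minimum −depth at ρ = 0."""
    rho = np.asarray(rho, dtype=float)
    if form == "morse":
        e = np.exp(-rho / A)
        val = depth * ((1.0 - e) ** 2 - 1.0)
        dval = 2.0 * depth * (1.0 - e) * e / A
    elif form == "gaussian":
        e = np.exp(-((rho / A) ** 2))
        val = -depth * e
        dval = 2.0 * depth * rho / A**2 * e
    else:
        raise ValueError(f"unknown well form {form!r}")
    return val, dval


@dataclass(frozen=True)
class PotentialSpec:
    """Pluggable binding-well definition.

    depth in pN·nm; range_translational A in nm; range_angular B in rad
    (flexible model only, r·B = A); centers: well-centre configurations.
    """

    form: str = "morse"
    depth: float = 0.0
    range_translational: float = 0.5
    range_angular: float | None = None
    centers: Sequence[Sequence[float]] = ((0.0, 0.0, 0.0), (7.0, 0.0, 0.0))

    def __post_init__(self):
        if self.form not in WELL_FORMS:
            raise ValueError(f"form must be one of {WELL_FORMS}")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.range_translational <= 0:
            raise ValueError("range_translational must be positive")


class RigidPotential:
    """Sum of two identical radial wells at the polymerase and nuclease sites."""

    def __init__(self, depth: float, A: float = 0.5,
                 centers: Sequence[Sequence[float]] = ((0.0, 0.0, 0.0), (7.0, 0.0, 0.0)),
                 form: str = "morse"):
        if form not in WELL_FORMS:
            raise ValueError(f"form must be one of {WELL_FORMS}")
        self.depth = float(depth)
        self.A = float(A)
        self.centers = np.asarray(centers, dtype=float).reshape(-1, 3)
        self.form = form

    def energy(self, pos) -> np.ndarray:
        """U(x, y, z) in pN·nm; pos has shape (..., 3)."""
        pos = np.asarray(pos, dtype=float)
        u = np.zeros(pos.shape[:-1])
        for c in self.centers:
            rho = np.linalg.norm(pos - c, axis=-1)
            val, _ = _well(rho, self.depth, self.A, self.form)
            u = u + val
        return u

    def force(self, pos) -> np.ndarray:
        """−∇U, analytic; shape (..., 3)."""
        pos = np.asarray(pos, dtype=float)
        f = np.zeros_like(pos)
        for c in self.centers:
            dvec = pos - c
            rho = np.linalg.norm(dvec, axis=-1)
            _, dval = _well(rho, self.depth, self.A, self.form)
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = np.where(rho[..., None] > 0, dvec / np.maximum(rho, 1e-300)[..., None], 0.0)
            f = f - dval[..., None] * unit
        return f

    def energy_xr(self, x, rho) -> np.ndarray:
        """U on the axisymmetric (x, ρ) half-plane (ρ² = y² + z²)."""
        x = np.asarray(x, dtype=float)
        rho = np.asarray(rho, dtype=float)
        u = np.zeros(np.broadcast(x, rho).shape)
        for c in self.centers:
            dist = np.hypot(x - c[0], rho)
            val, _ = _well(dist, self.depth, self.A, self.form)
            u = u + val
        return u


# ---------------------------------------------------------------------------
# Flexible model: linker geometry, spring, binding well, load
# ---------------------------------------------------------------------------

def linker_extension(x, y, theta, r: float):
    """Stretch R of the linker for pose (x, y, θ) of the sphere of radius r.

    The linker runs from its anchor on the polymerase domain (the origin O) to
    the attachment point on the sphere surface, which sits at r·(cosθ, sinθ)
    relative to O for rotation angle θ:

        R = sqrt((x − r·cosθ)² + (y − r·sinθ)²)

    R = 0 at the resting pose (r, 0, 0) and R = d at the active pose (−r, d, π).
    """
    return np.hypot(np.asarray(x) - r * np.cos(theta), np.asarray(y) - r * np.sin(theta))


def spring_energy(x, y, theta, K: float, r: float):
    """Entropic-spring elastic energy ½KR² in pN·nm."""
    R = linker_extension(x, y, theta, r)
    return 0.5 * K * R**2


def spring_forces(x, y, theta, K: float, r: float):
    """Generalized elastic forces (Fx, Fy, torque) = −∇(½KR²)."""
    ct, st = np.cos(theta), np.sin(theta)
    Rx = np.asarray(x) - r * ct
    Ry = np.asarray(y) - r * st
    fx = -K * Rx
    fy = -K * Ry
    torque = -K * r * (Rx * st - Ry * ct)
    return fx, fy, torque


def _scaled_distance(x, y, theta, A: float, B: float, r: float, d: float):
    u = (np.asarray(x) + r) / A
    v = (np.asarray(y) - d) / A
    w = (np.asarray(theta) - math.pi) / B
    return u, v, w, np.sqrt(u**2 + v**2 + w**2)


def binding_well_energy(x, y, theta, *, V0: float, A: float, B: float, r: float,
                        d: float, form: str = "gaussian"):
    """Binding well of depth V0 centred at the active pose (−r, d, π).

    The well is radial in the scaled coordinate s = |((x+r)/A, (y−d)/A,
    (θ−π)/B)| with the same two shape options as the rigid wells (unit range
    in s, so translational range A and angular range B = A/r).
    """
    _, _, _, s = _scaled_distance(x, y, theta, A, B, r, d)
    val, _ = _well(s, V0, 1.0, form)
    return val


def binding_well_forces(x, y, theta, *, V0: float, A: float, B: float, r: float,
                        d: float, form: str = "gaussian"):
    """Generalized forces (−∂V/∂x, −∂V/∂y, −∂V/∂θ) of the binding well."""
    u, v, w, s = _scaled_distance(x, y, theta, A, B, r, d)
    _, dval = _well(s, V0, 1.0, form)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(s > 0, dval / np.maximum(s, 1e-300), 0.0)
    return -scale * u / A, -scale * v / A, -scale * w / B


def flexible_energy(x, y, theta, params):
    """Total energy: binding well + ½KR² (load potential not included)."""
    e = binding_well_energy(x, y, theta, V0=params.v0, A=params.A, B=params.B,
                            r=params.r, d=params.d, form=params.form)
    return e + spring_energy(x, y, theta, params.spring_constant, params.r)


def flexible_generalized_forces(x, y, theta, params):
    """Sum of elastic, binding-well and load generalized forces.

    The load F_load (pN) acts along +x on the linker-side surface point of the
    sphere; in "lever" mode this adds torque −F_load·r·sinθ (resisting the
    0 → π rotation), in "none" mode only the x-force is added.
    """
    fx, fy, tq = spring_forces(x, y, theta, params.spring_constant, params.r)
    bx, by, bt = binding_well_forces(x, y, theta, V0=params.v0, A=params.A,
                                     B=params.B, r=params.r, d=params.d,
                                     form=params.form)
    fx = fx + bx
    fy = fy + by
    tq = tq + bt
    if params.F_load:
        fx = fx + params.F_load
        if params.load_torque == "lever":
            tq = tq - params.F_load * params.r * np.sin(theta)
        elif params.load_torque != "none":
            raise ValueError(f"unknown load_torque mode {params.load_torque!r}")
    return fx, fy, tq
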