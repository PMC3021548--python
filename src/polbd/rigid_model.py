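"""Rigid-scenario dynamics: the flap-DNA particle between two binding sites.

The DNA substrate, coarse-grained to a point particle with the drag of a
3-nm sphere, starts in the polymerase-site well at the origin and diffuses in
the two-well landscape until it is either captured at the 5'-nuclease site at
(7, 0, 0) nm ("transfer") or reaches 10 nm from the origin ("dissociation").

Besides the Brownian-dynamics ensemble, this module carries two deterministic
oracles exact for overdamped diffusion: the committor (splitting-probability)
boundary-value problem and the mean-first-passage-time problem,

    ∇·(e^(−U/kBT) ∇q) = 0,                q = 1 on capture, 0 on dissociation,
    D ∇·(e^(−U/kBT) ∇T) = −e^(−U/kBT),    T = 0 on both absorbing sets,

solved by second-order finite volumes.  Both wells lie on the x-axis, so the
3D problems are solved exactly on the axisymmetric (x, ρ) half-plane
(ρ² = y² + z²) with cut-cell treatment of the spherical Dirichlet surfaces.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels
from .engine import FPTResult, IntegratorConfig, spawn_seeds
from .fpt_stats import EnsembleSummary, params_digest, summarize
from .physics import PhysicalEnvironment
from .potentials import RigidPotential

__all__ = [
    "RigidModelParams",
    "classify_rigid_state",
    "run_rigid_ensemble",
    "run_rigid_experiment",
    "committor_pde",
    "mfpt_pde",
    "PDEResult",
]

_FORM_ID = {"morse": _kernels.FORM_MORSE, "gaussian": _kernels.FORM_GAUSSIAN}
_OUTCOME = {
    _kernels.OUT_TIMEOUT: "timeout",
    _kernels.OUT_TRANSFER: "transfer",
    _kernels.OUT_DISSOCIATION: "dissociation",
}


@dataclass(frozen=True)
class RigidModelParams:
    """Parameters of the rigid scenario.

    u0_kbt: well depth of both sites in units of k_BT; A: interaction range
    (nm); capture at ``capture_radius`` around the nuclease site (a half-range
    ball makes "reached the active site" well-defined and dt-insensitive);
    dissociation at ``dissociation_radius`` from the origin.
    """

    u0_kbt: float = 16.0
    A: float = 0.5
    site_pol: tuple[float, float, float] = (0.0, 0.0, 0.0)
    site_nuc: tuple[float, float, float] = (7.0, 0.0, 0.0)
    capture_radius: Optional[float] = 0.25
    dissociation_radius: float = 10.0
    form: str = "morse"
    env: PhysicalEnvironment = field(default_factory=PhysicalEnvironment)

    def __post_init__(self):
        if self.capture_radius is not None and not (
            self.capture_radius < self.A < self.dissociation_radius
        ):
            raise ValueError("need capture_radius < A < dissociation_radius")
        if any(c != 0.0 for c in self.site_pol):
            raise ValueError("the polymerase site defines the origin")
        if self.site_nuc[1] != 0.0 or self.site_nuc[2] != 0.0:
            raise ValueError("the nuclease site must lie on the x-axis")

    @property
    def u0(self) -> float:
        """Well depth in pN·nm."""
        return self.u0_kbt * self.env.kBT

    @property
    def potential(self) -> RigidPotential:
        return RigidPotential(self.u0, self.A, (self.site_pol, self.site_nuc), self.form)

    def replace(self, **kw) -> "RigidModelParams":
        return dataclasses.replace(self, **kw)


def classify_rigid_state(pos, params: RigidModelParams) -> str:
    """"transfer" | "dissociation" | "bound" for a position (transfer first)."""
    pos = np.asarray(pos, dtype=float)
    if params.capture_radius is not None:
        if np.linalg.norm(pos - np.asarray(params.site_nuc)) <= params.capture_radius:
            return "transfer"
    if np.linalg.norm(pos) >= params.dissociation_radius:
        return "dissociation"
    return "bound"


def run_rigid_ensemble(
    params: RigidModelParams,
    n_replicates: int,
    config: IntegratorConfig,
    initial_state: Optional[tuple[float, float, float]] = None,
) -> list[FPTResult]:
    """BD ensemble of first-passage outcomes, one stream per replicate."""
    if initial_state is None:
        initial_state = params.site_pol
    x0, y0, z0 = (float(c) for c in initial_state)
    k_max = params.u0 / params.A**2
    if k_max > 0 and config.dt > params.env.gamma_dna / (10.0 * k_max):
        warnings.warn(
            f"dt = {config.dt} exceeds the stability guard "
            f"{params.env.gamma_dna / (10 * k_max):.3g} µs for this well depth",
            stacklevel=2,
        )
    method = _kernels.METHOD_SRK2 if config.method == "srk2" else _kernels.METHOD_EM
    cap = params.capture_radius if params.capture_radius is not None else -1.0
    seeds = spawn_seeds(config.seed, n_replicates)
    results = []
    for s in seeds:
        code, t = _kernels.rigid_fpt(
            np.uint64(s), params.u0, params.A, _FORM_ID[params.form],
            params.env.kBT, params.env.gamma_dna, config.dt, config.max_steps,
            params.site_nuc[0], cap, params.dissociation_radius,
            x0, y0, z0, method,
        )
        results.append(FPTResult(outcome=_OUTCOME[code], first_passage_time=t))
    return results


def run_rigid_experiment(
    params: RigidModelParams,
    n_replicates: int,
    config: IntegratorConfig,
) -> EnsembleSummary:
    """P_n and T_d from a BD ensemble started at the polymerase site.

    P_n = #transfer/(#transfer + #dissociation); T_d = mean first-passage
    time to either absorption over non-timeout replicates.
    """
    results = run_rigid_ensemble(params, n_replicates, config)
    return summarize(
        results,
        seed=config.seed,
        master_seed=config.seed,
        params_hash=params_digest(params),
    )


# ---------------------------------------------------------------------------
# Deterministic axisymmetric finite-volume oracles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PDEResult:
    """Solved scalar field on the (x, ρ) half-plane.

    ``value`` is the field at the polymerase site; ``at(x, rho)`` bilinearly
    interpolates anywhere in the domain.
    """

    value: float
    x_centers: np.ndarray
    r_centers: np.ndarray
    field: np.ndarray  # shape (nx, nr)
    h: float

    def at(self, x: float, rho: float = 0.0) -> float:
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            (self.x_centers, self.r_centers), self.field,
            bounds_error=False, fill_value=None,
        )
        rho = max(float(rho), float(self.r_centers[0]))
        return float(interp((x, rho)))


def _axisym_solve(params: RigidModelParams, h: float, problem: str) -> PDEResult:
    b = params.dissociation_radius
    cap_r = params.capture_radius
    cx = params.site_nuc[0]
    pot = params.potential
    beta = 1.0 / params.env.kBT
    D = params.env.kBT / params.env.gamma_dna

    ext = b + 2.0 * h
    nx = int(math.ceil(2.0 * ext / h))
    nr = int(math.ceil(ext / h))
    xc = -ext + (np.arange(nx) + 0.5) * h
    rc = (np.arange(nr) + 0.5) * h
    X, Rho = np.meshgrid(xc, rc, indexing="ij")

    r_origin = np.hypot(X, Rho)
    outer = r_origin >= b
    if cap_r is not None:
        capture = np.hypot(X - cx, Rho) <= cap_r
    else:
        capture = np.zeros_like(outer)
    unknown = ~(outer | capture)
    idx = -np.ones((nx, nr), dtype=np.int64)
    idx[unknown] = np.arange(int(unknown.sum()))
    n_unk = int(unknown.sum())

    def w_at(x, rho):
        return np.exp(-beta * pot.energy_xr(x, rho))

    def boundary_dist(x, rho, ex, er, target):
        """Distance from (x, rho) to the target surface along axis (ex, er)."""
        if target == "outer":
            # |(x,rho) + t(ex,er)| = b
            pu = x * ex + rho * er
            c0 = x * x + rho * rho - b * b
        else:
            dx = x - cx
            pu = dx * ex + rho * er
            c0 = dx * dx + rho * rho - cap_r * cap_r
        disc = pu * pu - c0
        if disc < 0.0:
            return h
        sq = math.sqrt(disc)
        roots = (-pu - sq, -pu + sq)
        best = h
        for t in roots:
            if 1e-12 < t <= h and t < best:
                best = t
        return max(best, 0.05 * h)

    row_parts: list[np.ndarray] = []
    col_parts: list[np.ndarray] = []
    val_parts: list[np.ndarray] = []
    rhs = np.zeros(n_unk)

    bval_capture = 1.0 if problem == "committor" else 0.0
    iu, ju = np.nonzero(unknown)
    p_all = idx[iu, ju]
    # neighbor offsets: (di, dj, ex, er)
    for di, dj, ex, er in ((1, 0, 1.0, 0.0), (-1, 0, -1.0, 0.0),
                           (0, 1, 0.0, 1.0), (0, -1, 0.0, -1.0)):
        ni = iu + di
        nj = ju + dj
        x_p = xc[iu]
        r_p = rc[ju]
        rho_f = r_p + dj * 0.5 * h  # = r_p for x-faces
        inside_grid = (ni >= 0) & (ni < nx) & (nj >= 0) & (nj < nr)
        # axis face (rho_f == 0) carries no flux
        active = inside_grid & (rho_f > 1e-14)
        nic = np.clip(ni, 0, nx - 1)
        njc = np.clip(nj, 0, nr - 1)
        nbr_unknown = active & unknown[nic, njc]
        nbr_dirichlet = active & ~unknown[nic, njc]

        # interior faces: conductance at the face midpoint, vectorized
        k = np.nonzero(nbr_unknown)[0]
        if len(k):
            fx = x_p[k] + di * 0.5 * h
            fr = rho_f[k] if dj != 0 else r_p[k]
            C = w_at(fx, fr) * rho_f[k]
            p = p_all[k]
            q = idx[nic[k], njc[k]]
            row_parts += [p, p]
            col_parts += [p, q]
            val_parts += [-C, C]

        # cut-cell Dirichlet faces: few (the absorbing surfaces), scalar loop
        for kk in np.nonzero(nbr_dirichlet)[0]:
            p = int(p_all[kk])
            target = "capture" if capture[nic[kk], njc[kk]] else "outer"
            db = boundary_dist(x_p[kk], r_p[kk], ex, er, target)
            mx = x_p[kk] + ex * 0.5 * db
            mr = r_p[kk] + er * 0.5 * db
            C = float(w_at(mx, mr)) * rho_f[kk] * (h / db)
            row_parts.append(np.array([p]))
            col_parts.append(np.array([p]))
            val_parts.append(np.array([-C]))
            phi_b = bval_capture if target == "capture" else 0.0
            rhs[p] -= C * phi_b
    rows = np.concatenate(row_parts)
    cols = np.concatenate(col_parts)
    vals = np.concatenate(val_parts)

    if problem == "mfpt":
        w_p = w_at(X[unknown], Rho[unknown])
        rhs += -(w_p / D) * rc[ju] * h * h

    A = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n_unk, n_unk))
    )
    sol = spla.spsolve(A, rhs)
    residual = np.linalg.norm(A @ sol - rhs)
    scale = np.linalg.norm(rhs) if np.linalg.norm(rhs) > 0 else 1.0
    if not np.all(np.isfinite(sol)) or residual / scale > 1e-6:
        raise RuntimeError(
            f"linear solve did not converge (relative residual {residual / scale:.2e})"
        )

    fld = np.zeros((nx, nr))
    fld[unknown] = sol
    fld[capture] = bval_capture
    fld[outer] = 0.0

    # field at the polymerase site (on the symmetry axis): nearest-axis cells
    i0 = int(np.argmin(np.abs(xc - 0.0)))
    val = 0.5 * (fld[i0, 0] + fld[min(i0 + 1, nx - 1), 0]) if abs(xc[i0] + h / 2) < 1e-12 else fld[i0, 0]
    return PDEResult(value=float(val), x_centers=xc, r_centers=rc, field=fld, h=h)


def committor_pde(params: RigidModelParams, h: float = 0.05) -> PDEResult:
    """Splitting probability q(x): P(capture at the nuclease site before
    dissociation).  ``result.value`` = P_n from the polymerase site."""
    if params.capture_radius is None:
        raise ValueError("committor needs a capture set")
    return _axisym_solve(params, h, "committor")


def mfpt_pde(params: RigidModelParams, h: float = 0.05) -> PDEResult:
    """Mean first-passage time T(x) to either absorbing set (µs).
    ``result.value`` = T_d from the polymerase site."""
    return _axisym_solve(params, h, "mfpt")
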