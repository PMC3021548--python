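"""Numba-compiled stochastic Runge-Kutta kernels for the two models.

These are specializations of the generic engine (``engine.srk2_step`` /
``engine.simulate_first_passage``) for the concrete rigid and flexible
landscapes, tight-looped for production ensemble sizes.  They are
cross-checked against the generic numpy path in the test suite.

Noise generation uses an inlined xorshift64* generator feeding Box-Muller,
which is several times faster than the interpreter-facing RNG inside numba
loops and passes normality tests.  Every kernel takes an explicit uint64
stream seed; ensembles derive per-replicate seeds from one master seed via
``numpy.random.SeedSequence`` so results are reproducible and independent of
execution order.

Integration schemes (overdamped Langevin, coordinate drag γ_i, Gaussian
increment g_i of variance 2·kBT·dt/γ_i per step):

* srk2 (Heun / stochastic Runge-Kutta 2, the default):
    predictor  x̃ = x + (dt/γ)F(x) + g
    corrector  x' = x + (dt/2γ)[F(x) + F(x̃)] + g   (same g in both stages)
* euler_maruyama: x' = x + (dt/γ)F(x) + g
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# xorshift64* output multiplier and 53-bit uniform scale
_M = np.uint64(2685821657736338717)
_TWO53 = 1.1102230246251565e-16
_SEED_MIX = np.uint64(0x9E3779B97F4A7C15)

FORM_MORSE = 0
FORM_GAUSSIAN = 1
METHOD_SRK2 = 0
METHOD_EM = 1

# outcome codes shared with engine.FPTResult
OUT_TIMEOUT = 0
OUT_TRANSFER = 1
OUT_DISSOCIATION = 2
OUT_ACTIVE = 3


@njit(cache=True, fastmath=True, inline="always")
def _xs(s):
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    return s


@njit(cache=True, fastmath=True, inline="always")
def _norm_pair(s):
    """Two independent standard normals via Box-Muller; returns (s, z1, z2)."""
    s = _xs(s)
    u1 = ((s * _M) >> np.uint64(11)) * _TWO53
    s = _xs(s)
    u2 = ((s * _M) >> np.uint64(11)) * _TWO53
    if u1 < 1e-300:
        u1 = 1e-300
    rr = math.sqrt(-2.0 * math.log(u1))
    a = 6.283185307179586 * u2
    return s, rr * math.cos(a), rr * math.sin(a)


@njit(cache=True, fastmath=True, inline="always")
def _init_state(seed):
    s = np.uint64(seed) ^ _SEED_MIX
    if s == np.uint64(0):
        s = _SEED_MIX
    for _ in range(8):
        s = _xs(s)
    return s


# ---------------------------------------------------------------------------
# Rigid model: 3D particle between two radial wells
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _rigid_force(x, y, z, u0, A, nuc_x, form):
    fx = 0.0
    fy = 0.0
    fz = 0.0
    # well at origin
    rho = math.sqrt(x * x + y * y + z * z)
    if rho > 0.0:
        if form == FORM_MORSE:
            e = math.exp(-rho / A)
            dval = 2.0 * u0 * (1.0 - e) * e / A
        else:
            dval = 2.0 * u0 * rho / (A * A) * math.exp(-((rho / A) ** 2))
        fx -= dval * x / rho
        fy -= dval * y / rho
        fz -= dval * z / rho
    # well at the nuclease site (nuc_x, 0, 0)
    dx = x - nuc_x
    rho = math.sqrt(dx * dx + y * y + z * z)
    if rho > 0.0:
        if form == FORM_MORSE:
            e = math.exp(-rho / A)
            dval = 2.0 * u0 * (1.0 - e) * e / A
        else:
            dval = 2.0 * u0 * rho / (A * A) * math.exp(-((rho / A) ** 2))
        fx -= dval * dx / rho
        fy -= dval * y / rho
        fz -= dval * z / rho
    return fx, fy, fz


@njit(cache=True, fastmath=True)
def rigid_fpt(seed, u0, A, form, kbt, gamma, dt, max_steps, nuc_x, capture_r,
              dissoc_r, x0, y0, z0, method):
    """First passage of the flap-DNA particle.

    Returns (outcome, time): OUT_TRANSFER when within capture_r of the
    nuclease site, OUT_DISSOCIATION when ≥ dissoc_r from the origin,
    OUT_TIMEOUT otherwise.  capture_r < 0 disables the capture set.
    """
    s = _init_state(seed)
    x, y, z = x0, y0, z0
    sig = math.sqrt(2.0 * kbt * dt / gamma)
    cap2 = capture_r * capture_r
    diss2 = dissoc_r * dissoc_r
    inv_g = dt / gamma
    for step in range(1, max_steps + 1):
        s, z1, z2 = _norm_pair(s)
        s, z3, _ = _norm_pair(s)
        gx = sig * z1
        gy = sig * z2
        gz = sig * z3
        fx, fy, fz = _rigid_force(x, y, z, u0, A, nuc_x, form)
        if method == METHOD_EM:
            x += inv_g * fx + gx
            y += inv_g * fy + gy
            z += inv_g * fz + gz
        else:
            xp = x + inv_g * fx + gx
            yp = y + inv_g * fy + gy
            zp = z + inv_g * fz + gz
            fx2, fy2, fz2 = _rigid_force(xp, yp, zp, u0, A, nuc_x, form)
            x += 0.5 * inv_g * (fx + fx2) + gx
            y += 0.5 * inv_g * (fy + fy2) + gy
            z += 0.5 * inv_g * (fz + fz2) + gz
        if capture_r > 0.0:
            ddx = x - nuc_x
            if ddx * ddx + y * y + z * z <= cap2:
                return OUT_TRANSFER, step * dt
        if x * x + y * y + z * z >= diss2:
            return OUT_DISSOCIATION, step * dt
    return OUT_TIMEOUT, max_steps * dt


# ---------------------------------------------------------------------------
# Flexible model: (x, y[, z], θ) pose of the tethered nuclease sphere
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _flex_force(x, y, z, th, v0, A, B, r, d, K, f_load, lever, form, use_z):
    ct = math.cos(th)
    st = math.sin(th)
    Rx = x - r * ct
    Ry = y - r * st
    fx = -K * Rx
    fy = -K * Ry
    ft = -K * r * (Rx * st - Ry * ct)
    fz = -K * z if use_z else 0.0
    u = (x + r) / A
    v = (y - d) / A
    w = (th - math.pi) / B
    s2 = u * u + v * v + w * w
    if use_z:
        s2 += (z / A) * (z / A)
    sdist = math.sqrt(s2)
    if sdist > 0.0:
        if form == FORM_MORSE:
            e = math.exp(-sdist)
            dval = 2.0 * v0 * (1.0 - e) * e
        else:
            dval = 2.0 * v0 * sdist * math.exp(-s2)
        scale = dval / sdist
        fx -= scale * u / A
        fy -= scale * v / A
        ft -= scale * w / B
        if use_z:
            fz -= scale * (z / A) / A
    if f_load != 0.0:
        fx += f_load
        if lever:
            ft -= f_load * r * st
    return fx, fy, fz, ft


@njit(cache=True, fastmath=True)
def flexible_fpt(seed, v0, A, B, r, d, K, na_cap, f_load, lever, form, use_z,
                 kbt, g_t, g_rot, dt, max_steps, eps_active, method):
    """First passage of the nuclease sphere from (r, 0, 0) to the active pose.

    Absorbs when the scaled distance to (−r, d, π) is ≤ eps_active.  Steps
    whose end state would stretch the linker past na_cap are rejected and the
    noise redrawn (reflecting-wall approximation of the inextensibility
    constraint).  Returns (outcome, time, max_R_accepted).
    """
    s = _init_state(seed)
    x = r
    y = 0.0
    z = 0.0
    th = 0.0
    sig_t = math.sqrt(2.0 * kbt * dt / g_t)
    sig_r = math.sqrt(2.0 * kbt * dt / g_rot)
    inv_t = dt / g_t
    inv_r = dt / g_rot
    eps2 = eps_active * eps_active
    cap2 = na_cap * na_cap
    max_R2 = 0.0
    for step in range(1, max_steps + 1):
        fx, fy, fz, ft = _flex_force(x, y, z, th, v0, A, B, r, d, K, f_load,
                                     lever, form, use_z)
        accepted = False
        xn = x
        yn = y
        zn = z
        tn = th
        for _ in range(1000):
            s, z1, z2 = _norm_pair(s)
            gx = sig_t * z1
            gy = sig_t * z2
            s, z3, z4 = _norm_pair(s)
            gt = sig_r * z3
            gz = sig_t * z4 if use_z else 0.0
            if method == METHOD_EM:
                xn = x + inv_t * fx + gx
                yn = y + inv_t * fy + gy
                zn = z + inv_t * fz + gz if use_z else 0.0
                tn = th + inv_r * ft + gt
            else:
                xp = x + inv_t * fx + gx
                yp = y + inv_t * fy + gy
                zp = z + inv_t * fz + gz if use_z else 0.0
                tp = th + inv_r * ft + gt
                fx2, fy2, fz2, ft2 = _flex_force(xp, yp, zp, tp, v0, A, B, r,
                                                 d, K, f_load, lever, form,
                                                 use_z)
                xn = x + 0.5 * inv_t * (fx + fx2) + gx
                yn = y + 0.5 * inv_t * (fy + fy2) + gy
                zn = z + 0.5 * inv_t * (fz + fz2) + gz if use_z else 0.0
                tn = th + 0.5 * inv_r * (ft + ft2) + gt
            ct = math.cos(tn)
            st = math.sin(tn)
            Rx = xn - r * ct
            Ry = yn - r * st
            R2 = Rx * Rx + Ry * Ry
            if use_z:
                R2 += zn * zn
            if R2 <= cap2 and -math.pi <= tn <= math.pi:
                accepted = True
                break
        if accepted:
            x = xn
            y = yn
            z = zn
            th = tn
            if R2 > max_R2:
                max_R2 = R2
        # else: keep the old state for this step (wall contact)
        u = (x + r) / A
        v = (y - d) / A
        w = (th - math.pi) / B
        s2 = u * u + v * v + w * w
        if use_z:
            s2 += (z / A) * (z / A)
        if s2 <= eps2:
            return OUT_ACTIVE, step * dt, math.sqrt(max_R2)
    return OUT_TIMEOUT, max_steps * dt, math.sqrt(max_R2)


@njit(cache=True, fastmath=True)
def flexible_trajectory(seed, v0, A, B, r, d, K, na_cap, f_load, lever, form,
                        kbt, g_t, g_rot, dt, max_steps, eps_active, stride,
                        out):
    """Like flexible_fpt (srk2, no z) but records (t, x, y, θ, R) every
    ``stride`` steps into ``out`` (shape (n, 5)).  Returns (outcome, time,
    n_recorded)."""
    s = _init_state(seed)
    x = r
    y = 0.0
    th = 0.0
    sig_t = math.sqrt(2.0 * kbt * dt / g_t)
    sig_r = math.sqrt(2.0 * kbt * dt / g_rot)
    inv_t = dt / g_t
    inv_r = dt / g_rot
    eps2 = eps_active * eps_active
    cap2 = na_cap * na_cap
    nrec = 0
    nmax = out.shape[0]
    for step in range(1, max_steps + 1):
        fx, fy, fz, ft = _flex_force(x, y, 0.0, th, v0, A, B, r, d, K, f_load,
                                     lever, form, False)
        accepted = False
        xn = x
        yn = y
        tn = th
        R2 = 0.0
        for _ in range(1000):
            s, z1, z2 = _norm_pair(s)
            gx = sig_t * z1
            gy = sig_t * z2
            s, z3, _ = _norm_pair(s)
            gt = sig_r * z3
            xp = x + inv_t * fx + gx
            yp = y + inv_t * fy + gy
            tp = th + inv_r * ft + gt
            fx2, fy2, fz2, ft2 = _flex_force(xp, yp, 0.0, tp, v0, A, B, r, d,
                                             K, f_load, lever, form, False)
            xn = x + 0.5 * inv_t * (fx + fx2) + gx
            yn = y + 0.5 * inv_t * (fy + fy2) + gy
            tn = th + 0.5 * inv_r * (ft + ft2) + gt
            ct = math.cos(tn)
            st = math.sin(tn)
            Rx = xn - r * ct
            Ry = yn - r * st
            R2 = Rx * Rx + Ry * Ry
            if R2 <= cap2 and -math.pi <= tn <= math.pi:
                accepted = True
                break
        if accepted:
            x = xn
            y = yn
            th = tn
        if step % stride == 0 and nrec < nmax:
            out[nrec, 0] = step * dt
            out[nrec, 1] = x
            out[nrec, 2] = y
            out[nrec, 3] = th
            ct = math.cos(th)
            st = math.sin(th)
            out[nrec, 4] = math.sqrt((x - r * ct) ** 2 + (y - r * st) ** 2)
            nrec += 1
        u = (x + r) / A
        v = (y - d) / A
        w = (th - math.pi) / B
        if u * u + v * v + w * w <= eps2:
            return OUT_ACTIVE, step * dt, nrec
    return OUT_TIMEOUT, max_steps * dt, nrec


# ---------------------------------------------------------------------------
# 1D reference problems used by the engine's statistical self-tests
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def double_well_fpt_1d(seed, barrier, kbt, gamma, dt, max_steps):
    """FPT from x = −1 to x ≥ +1 in the quartic double well U = ΔU·(x²−1)².

    Kramers: the mean FPT grows ∝ exp(ΔU/kBT) for deep barriers.
    """
    s = _init_state(seed)
    x = -1.0
    sig = math.sqrt(2.0 * kbt * dt / gamma)
    inv_g = dt / gamma
    for step in range(1, max_steps + 1):
        s, z1, _ = _norm_pair(s)
        g = sig * z1
        f = -4.0 * barrier * x * (x * x - 1.0)
        xp = x + inv_g * f + g
        f2 = -4.0 * barrier * xp * (xp * xp - 1.0)
        x += 0.5 * inv_g * (f + f2) + g
        if x >= 1.0:
            return step * dt
    return -1.0


@njit(cache=True, fastmath=True)
def boltzmann_histogram_1d(seed, u0, A, L, kbt, gamma, dt, burn_steps,
                           n_samples, stride, edges):
    """Long-run position histogram in a single closed 1D Morse-style well.

    The well w(|x|) of depth u0 is closed by reflecting walls at |x| = L
    (moves beyond are rejected).  Samples every ``stride`` steps after
    burn-in; returns histogram counts over ``edges``.
    """
    s = _init_state(seed)
    nb = edges.shape[0] - 1
    counts = np.zeros(nb, dtype=np.int64)
    x = 0.0
    sig = math.sqrt(2.0 * kbt * dt / gamma)
    inv_g = dt / gamma
    lo = edges[0]
    inv_w = nb / (edges[nb] - edges[0])
    taken = 0
    step = 0
    while taken < n_samples:
        step += 1
        s, z1, _ = _norm_pair(s)
        g = sig * z1
        ax = abs(x)
        e = math.exp(-ax / A)
        f = -2.0 * u0 * (1.0 - e) * e / A * (1.0 if x >= 0 else -1.0)
        xp = x + inv_g * f + g
        axp = abs(xp)
        ep = math.exp(-axp / A)
        f2 = -2.0 * u0 * (1.0 - ep) * ep / A * (1.0 if xp >= 0 else -1.0)
        xn = x + 0.5 * inv_g * (f + f2) + g
        if abs(xn) <= L:
            x = xn
        if step > burn_steps and step % stride == 0:
            if x >= lo:
                k = int((x - lo) * inv_w)
                if k < nb:
                    counts[k] += 1
            taken += 1
    return counts


@njit(cache=True, fastmath=True)
def harmonic_positions_1d(seed, k_spring, kbt, gamma, dt, burn_steps,
                          n_samples, stride):
    """Samples of the overdamped harmonic (Ornstein-Uhlenbeck) coordinate."""
    s = _init_state(seed)
    out = np.empty(n_samples)
    x = 0.0
    sig = math.sqrt(2.0 * kbt * dt / gamma)
    inv_g = dt / gamma
    total = burn_steps + n_samples * stride
    taken = 0
    for step in range(1, total + 1):
        s, z1, _ = _norm_pair(s)
        g = sig * z1
        f = -k_spring * x
        xp = x + inv_g * f + g
        f2 = -k_spring * xp
        x += 0.5 * inv_g * (f + f2) + g
        if step > burn_steps and (step - burn_steps) % stride == 0:
            out[taken] = x
            taken += 1
            if taken == n_samples:
                break
    return out


def normal_stream(seed: int, n: int) -> np.ndarray:
    """n draws from the kernels' normal generator (for statistical checks)."""
    return _normal_stream(np.uint64(seed), n)


@njit(cache=True, fastmath=True)
def _normal_stream(seed, n):
    s = _init_state(seed)
    out = np.empty(n)
    i = 0
    while i < n:
        s, z1, z2 = _norm_pair(s)
        out[i] = z1
        i += 1
        if i < n:
            out[i] = z2
            i += 1
    return out
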