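"""Overdamped Langevin integrators and first-passage simulation.

The generic, force-function-agnostic path lives here (numpy, reference
implementation); the model-specific production loops are the numba kernels in
``polbd._kernels``, which implement the identical schemes and are
cross-checked against this module in the tests.

Scheme (per coordinate i with drag γ_i, thermal energy kBT, time step dt):
noise increment g_i ~ N(0, 2·kBT·dt/γ_i); the stochastic Runge-Kutta (Heun)
update evaluates the drift at the predictor point and reuses the same noise
increment in both stages, giving weak second-order accuracy for the
statistics of interest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "IntegratorConfig",
    "FPTResult",
    "srk2_step",
    "euler_maruyama_step",
    "simulate_first_passage",
    "run_ensemble",
    "spawn_seeds",
    "check_stability",
]

_METHODS = ("srk2", "euler_maruyama")


@dataclass(frozen=True)
class IntegratorConfig:
    """Integration controls.

    dt and max_time in µs.  The default dt = 2e-5 µs (0.02 ns) is ~1/10 of
    the stiffest well relaxation time γ/(depth/A²) at 20 k_BT depth.
    n_parallel is a hint only: per-replicate noise streams make results
    independent of any batching.
    """

    method: str = "srk2"
    dt: float = 2.0e-5
    max_time: float = 1.0e4
    seed: int = 0
    n_parallel: int = 1

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.max_time <= self.dt:
            raise ValueError("max_time must exceed dt")

    @property
    def max_steps(self) -> int:
        return int(round(self.max_time / self.dt))

    def replace(self, **kw) -> "IntegratorConfig":
        return dataclasses.replace(self, **kw)


def check_stability(dt: float, gamma: float, k_max: float) -> None:
    """Guard dt ≤ γ/(10·k_max) with k_max the stiffest curvature scale."""
    if k_max > 0 and dt > gamma / (10.0 * k_max) * (1.0 + 1e-12):
        raise ValueError(
            f"dt = {dt} violates stability guard γ/(10·k_max) = {gamma / (10 * k_max):.3g}"
        )


@dataclass(frozen=True)
class FPTResult:
    """Outcome of one first-passage simulation.

    outcome: "transfer" | "dissociation" | "active_mode_reached" | "timeout";
    first_passage_time in µs; trajectory optionally holds a sampled path.
    """

    outcome: str
    first_passage_time: float
    trajectory: Optional[np.ndarray] = None

    @property
    def is_timeout(self) -> bool:
        return self.outcome == "timeout"


def _noise(rng: np.random.Generator, gammas: np.ndarray, kBT: float, dt: float):
    return rng.standard_normal(gammas.shape) * np.sqrt(2.0 * kBT * dt / gammas)


def srk2_step(state, force_fn, gammas, kBT, dt, noise=None, rng=None):
    """One Heun step; ``noise`` is the pre-scaled Gaussian increment g."""
    state = np.asarray(state, dtype=float)
    gammas = np.broadcast_to(np.asarray(gammas, dtype=float), state.shape)
    if noise is None:
        noise = _noise(rng, gammas, kBT, dt) if rng is not None else np.zeros_like(state)
    f1 = np.asarray(force_fn(state), dtype=float)
    if not np.all(np.isfinite(f1)):
        raise FloatingPointError(f"non-finite force at state {state!r}")
    pred = state + dt / gammas * f1 + noise
    f2 = np.asarray(force_fn(pred), dtype=float)
    if not np.all(np.isfinite(f2)):
        raise FloatingPointError(f"non-finite force at predictor state {pred!r}")
    return state + 0.5 * dt / gammas * (f1 + f2) + noise


def euler_maruyama_step(state, force_fn, gammas, kBT, dt, noise=None, rng=None):
    """One Euler-Maruyama step."""
    state = np.asarray(state, dtype=float)
    gammas = np.broadcast_to(np.asarray(gammas, dtype=float), state.shape)
    if noise is None:
        noise = _noise(rng, gammas, kBT, dt) if rng is not None else np.zeros_like(state)
    f1 = np.asarray(force_fn(state), dtype=float)
    if not np.all(np.isfinite(f1)):
        raise FloatingPointError(f"non-finite force at state {state!r}")
    return state + dt / gammas * f1 + noise


def simulate_first_passage(
    initial_state,
    force_fn: Callable[[np.ndarray], np.ndarray],
    gammas,
    kBT: float,
    stop_fn: Callable[[np.ndarray], Optional[str]],
    config: IntegratorConfig,
    rng: Optional[np.random.Generator] = None,
    accept_fn: Optional[Callable[[np.ndarray], bool]] = None,
    record_stride: int = 0,
) -> FPTResult:
    """Integrate until ``stop_fn`` names an outcome or max_time elapses.

    stop_fn(state) returns an outcome label (absorbing) or None.  accept_fn,
    if given, vetoes proposed states (noise is redrawn) — used for hard
    constraints such as the linker extensibility cap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = np.asarray(initial_state, dtype=float).copy()
    gammas = np.broadcast_to(np.asarray(gammas, dtype=float), state.shape).copy()
    step_fn = srk2_step if config.method == "srk2" else euler_maruyama_step

    label = stop_fn(state)
    if label is not None:
        return FPTResult(outcome=label, first_passage_time=0.0)

    traj = [] if record_stride else None
    dt = config.dt
    for step in range(1, config.max_steps + 1):
        if accept_fn is None:
            noise = _noise(rng, gammas, kBT, dt)
            state = step_fn(state, force_fn, gammas, kBT, dt, noise=noise)
        else:
            for _ in range(1000):
                noise = _noise(rng, gammas, kBT, dt)
                cand = step_fn(state, force_fn, gammas, kBT, dt, noise=noise)
                if accept_fn(cand):
                    state = cand
                    break
            # all rejected: state unchanged this step (wall contact)
        if traj is not None and step % record_stride == 0:
            traj.append(state.copy())
        label = stop_fn(state)
        if label is not None:
            return FPTResult(
                outcome=label,
                first_passage_time=step * dt,
                trajectory=np.array(traj) if traj else None,
            )
    return FPTResult(
        outcome="timeout",
        first_passage_time=config.max_steps * dt,
        trajectory=np.array(traj) if traj else None,
    )


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """n independent uint64 stream seeds derived from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)


def run_ensemble(
    simulate_one: Callable[[int], FPTResult],
    n_replicates: int,
    master_seed: int,
) -> list[FPTResult]:
    """Run n independent replicates with per-replicate derived streams.

    ``simulate_one(stream_seed)`` must be a pure function of its seed, so the
    ensemble is reproducible and the result is independent of batching order.
    Replicate failures are re-raised with the stream identified.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    seeds = spawn_seeds(master_seed, n_replicates)
    results = []
    for i, s in enumerate(seeds):
        try:
            results.append(simulate_one(int(s)))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"replicate {i} (stream seed {int(s)}) failed: {exc}") from exc
    return results
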