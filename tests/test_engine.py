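"""Integrator correctness: deterministic limits, noise statistics, and the
classical stochastic benchmarks (free-diffusion MFPT, OU variance, Boltzmann
sampling, Kramers escape)."""

import math

import numpy as np
import pytest
from scipy import stats

from polbd.engine import (
    FPTResult,
    IntegratorConfig,
    check_stability,
    euler_maruyama_step,
    run_ensemble,
    simulate_first_passage,
    spawn_seeds,
    srk2_step,
)
from polbd.rigid_model import RigidModelParams, run_rigid_ensemble
from polbd.fpt_stats import summarize

KBT = 4.1143
GAMMA = 5.655e-2  # 3-nm sphere at 1e-3 Pa·s, pN·µs/nm
D = KBT / GAMMA


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            IntegratorConfig(method="rk4")
        with pytest.raises(ValueError):
            IntegratorConfig(dt=0.0)
        with pytest.raises(ValueError):
            IntegratorConfig(dt=1.0, max_time=0.5)

    def test_max_steps(self):
        assert IntegratorConfig(dt=2e-5, max_time=1.0).max_steps == 50_000

    def test_stability_guard(self):
        check_stability(2e-5, GAMMA, 16 * KBT / 0.25)  # ok at U0 = 16 kBT
        with pytest.raises(ValueError):
            check_stability(2e-4, GAMMA, 16 * KBT / 0.25)


class TestDeterministicLimits:
    def test_zero_force_zero_noise(self):
        state = np.array([1.0, -2.0, 3.0])
        out = srk2_step(state, lambda x: np.zeros(3), GAMMA, KBT, 1e-4,
                        noise=np.zeros(3))
        assert np.allclose(out, state)

    @pytest.mark.parametrize("step_fn", [srk2_step, euler_maruyama_step])
    def test_harmonic_relaxation(self, step_fn):
        """Noise-free relaxation tracks exp(−kt/γ) to the scheme's order."""
        k = 50.0
        dt = 1e-4
        n = 400
        x = np.array([1.0])
        for _ in range(n):
            x = step_fn(x, lambda s: -k * s, GAMMA, KBT, dt, noise=np.zeros(1))
        exact = math.exp(-k * n * dt / GAMMA)
        order = 2 if step_fn is srk2_step else 1
        tol = (k * dt / GAMMA) ** order * n * exact * 2
        assert abs(x[0] - exact) < tol

    def test_nonfinite_force_raises(self):
        with pytest.raises(FloatingPointError):
            srk2_step(np.array([1.0]), lambda s: s * np.nan, GAMMA, KBT, 1e-4,
                      noise=np.zeros(1))


class TestKernelNoise:
    def test_normality_and_moments(self, warm_kernels):
        """The kernels' inlined normal generator: correct first four moments
        and passes a KS normality test over 1e6 draws."""
        z = warm_kernels.normal_stream(123, 1_000_000)
        n = len(z)
        assert abs(z.mean()) < 3 / math.sqrt(n)
        assert abs(z.var() - 1.0) < 3 * math.sqrt(2 / n)
        assert abs(stats.skew(z)) < 3 * math.sqrt(6 / n)
        assert abs(stats.kurtosis(z)) < 3 * math.sqrt(24 / n)
        assert stats.kstest(z, "norm").pvalue > 0.001

    def test_streams_independent(self, warm_kernels):
        a = warm_kernels.normal_stream(1, 50_000)
        b = warm_kernels.normal_stream(2, 50_000)
        assert abs(np.corrcoef(a, b)[0, 1]) < 3 / math.sqrt(50_000)


class TestFirstPassage:
    def test_immediate_outcome(self):
        res = simulate_first_passage(
            np.zeros(3), lambda s: np.zeros(3), GAMMA, KBT,
            lambda s: "transfer", IntegratorConfig(seed=1),
        )
        assert res.outcome == "transfer"
        assert res.first_passage_time == 0.0

    def test_timeout_outcome(self):
        cfg = IntegratorConfig(seed=1, dt=1e-3, max_time=0.01)
        res = simulate_first_passage(
            np.zeros(1), lambda s: np.zeros(1), GAMMA, KBT, lambda s: None, cfg
        )
        assert res.outcome == "timeout"
        assert res.first_passage_time == pytest.approx(0.01)

    def test_free_diffusion_mfpt_generic(self):
        """3D free diffusion to an absorbing sphere: ⟨T⟩ = L²γ/(6kBT)."""
        L = 3.0
        cfg = IntegratorConfig(seed=9, dt=1e-5, max_time=5.0)

        def one(seed):
            rng = np.random.default_rng(seed)
            return simulate_first_passage(
                np.zeros(3), lambda s: np.zeros(3), GAMMA, KBT,
                lambda s: "dissociation" if s @ s >= L * L else None,
                cfg, rng=rng,
            )

        results = run_ensemble(one, 80, master_seed=5)
        times = np.array([r.first_passage_time for r in results])
        exact = L**2 * GAMMA / (6 * KBT)
        assert abs(times.mean() - exact) < 3 * times.std() / math.sqrt(len(times))

    def test_free_diffusion_mfpt_kernel(self, warm_kernels):
        """Same closed form for the production kernel, at 1500 replicates."""
        L = 3.0
        params = RigidModelParams(u0_kbt=0.0, capture_radius=None,
                                  dissociation_radius=L)
        cfg = IntegratorConfig(seed=17, dt=1e-5, max_time=5.0)
        results = run_rigid_ensemble(params, 1500, cfg)
        times = np.array([r.first_passage_time for r in results])
        exact = L**2 * GAMMA / (6 * KBT)
        assert abs(times.mean() - exact) < 3 * times.std() / math.sqrt(len(times))

    def test_run_ensemble_contracts(self):
        def one(seed):
            rng = np.random.default_rng(seed)
            return FPTResult("transfer", float(rng.exponential()))

        a = run_ensemble(one, 20, master_seed=3)
        b = run_ensemble(one, 20, master_seed=3)
        assert [r.first_passage_time for r in a] == [r.first_passage_time for r in b]
        single = one(int(spawn_seeds(3, 1)[0]))
        assert a[0].first_passage_time == single.first_passage_time
        with pytest.raises(ValueError):
            run_ensemble(one, 0, master_seed=3)


class TestOUProcess:
    def test_stationary_variance(self, warm_kernels):
        """Overdamped harmonic well: Var(x) = kBT/k within 2%."""
        k, kbt, gamma = 2.0, 1.3, 0.7
        tau = gamma / k
        dt = 0.01 * tau
        samples = warm_kernels.harmonic_positions_1d(
            np.uint64(42), k, kbt, gamma, dt, 10_000, 40_000, 600
        )
        assert samples.var() == pytest.approx(kbt / k, rel=0.02)


class TestBoltzmannSampling:
    def test_single_well_histogram(self, warm_kernels):
        """Long-run position histogram in a closed well matches e^(−U/kBT)/Z
        (χ² test at α = 0.01, 1e7 samples).

        The histogram window excludes the reflecting walls at |x| = 2 where
        the rejection step distorts the density within one step-length.
        """
        u0, A, L, kbt, gamma = 3.0, 0.5, 2.0, 1.0, 1.0
        k_well = 2 * u0 / A**2
        dt = 0.02 * gamma / k_well
        edges = np.linspace(-1.8, 1.8, 41)
        counts = warm_kernels.boltzmann_histogram_1d(
            np.uint64(77), u0, A, L, kbt, gamma, dt, 20_000, 10_000_000, 250,
            edges,
        )

        def u(x):
            return u0 * ((1 - np.exp(-np.abs(x) / A)) ** 2 - 1)

        xs = np.linspace(edges[0], edges[-1], 8001)
        dens = np.exp(-u(xs) / kbt)
        cum = np.concatenate([[0], np.cumsum((dens[1:] + dens[:-1]) / 2)])
        cum /= cum[-1]
        idx = np.searchsorted(xs, edges)
        probs = np.diff(cum[idx])
        probs /= probs.sum()
        n = counts.sum()
        expected = n * probs
        chi2 = float(((counts - expected) ** 2 / expected).sum())
        threshold = stats.chi2.ppf(0.99, df=len(counts) - 1)
        assert chi2 < threshold, f"chi2 = {chi2:.1f} vs {threshold:.1f}"


def _mfpt_1d_quadrature(barrier, lo=-3.0, hi=1.0, start=-1.0, n=6001):
    """Exact MFPT from ``start`` to ``hi`` for U = ΔU·(x²−1)², reflecting at
    ``lo`` (kBT = γ = 1): T = ∫ₓ^hi dy e^{U(y)} ∫_lo^y dz e^{−U(z)}."""
    xs = np.linspace(lo, hi, n)
    h = xs[1] - xs[0]
    u = barrier * (xs**2 - 1) ** 2
    inner = np.concatenate(
        [[0], np.cumsum((np.exp(-u)[1:] + np.exp(-u)[:-1]) / 2) * h]
    )
    i0 = int(round((start - lo) / h))
    integrand = np.exp(u[i0:]) * inner[i0:]
    return float(np.trapezoid(integrand, dx=h))


class TestKramersEscape:
    def test_exact_mfpt_slope_is_thermal(self):
        """ln(MFPT) from the exact 1D quadrature is linear in the barrier
        height with slope 1/kBT ± 10% over 8-14 kBT."""
        barriers = np.arange(8.0, 14.5, 1.0)
        lnT = [math.log(_mfpt_1d_quadrature(b)) for b in barriers]
        slope = np.polyfit(barriers, lnT, 1)[0]
        assert 0.9 < slope < 1.1

    @pytest.mark.parametrize("barrier,n_rep", [(8.0, 40), (10.0, 25)])
    def test_bd_matches_quadrature(self, barrier, n_rep, warm_kernels):
        """Kernel escape times agree with the exact double-integral MFPT."""
        dt = 0.01 / (8 * barrier)
        max_steps = int(5e8)
        seeds = spawn_seeds(321, n_rep)
        times = np.array(
            [
                warm_kernels.double_well_fpt_1d(np.uint64(s), barrier, 1.0,
                                                1.0, dt, max_steps)
                for s in seeds
            ]
        )
        assert np.all(times > 0)
        exact = _mfpt_1d_quadrature(barrier)
        se = times.std() / math.sqrt(n_rep)
        assert abs(times.mean() - exact) < 2.5 * se


class TestSchemeAgreement:
    def test_em_and_srk2_agree(self, warm_kernels):
        """Both schemes give the same ensemble summaries within 2 s.e."""
        params = RigidModelParams(u0_kbt=8.0)
        n = 250
        summaries = {}
        for method in ("srk2", "euler_maruyama"):
            cfg = IntegratorConfig(seed=55, method=method, max_time=100.0)
            results = run_rigid_ensemble(params, n, cfg)
            summaries[method] = summarize(results, seed=1)
        a, b = summaries["srk2"], summaries["euler_maruyama"]
        se = math.sqrt(a.sem_fpt**2 + b.sem_fpt**2)
        assert abs(a.mean_fpt - b.mean_fpt) < 2 * se
        p_se = math.sqrt(
            a.p_transfer * (1 - a.p_transfer) / n
            + b.p_transfer * (1 - b.p_transfer) / n
        )
        assert abs(a.p_transfer - b.p_transfer) < 2.5 * max(p_se, 1e-3)

    def test_weak_convergence_in_dt(self, warm_kernels):
        """Halving dt moves the kernel's mean FPT by < 2 s.e."""
        barrier = 6.0
        n = 120
        means = []
        ses = []
        for dt in (0.01 / 48, 0.005 / 48):
            seeds = spawn_seeds(99, n)
            times = np.array(
                [
                    warm_kernels.double_well_fpt_1d(np.uint64(s), barrier, 1.0,
                                                    1.0, dt, int(5e8))
                    for s in seeds
                ]
            )
            means.append(times.mean())
            ses.append(times.std() / math.sqrt(n))
        assert abs(means[0] - means[1]) < 2 * math.hypot(*ses)
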