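"""Ensemble first-passage statistics: means, bootstrap CIs, splitting
probabilities with Wilson intervals, censoring-aware estimators, and
exponential-distribution fitting."""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .engine import FPTResult

__all__ = [
    "EnsembleSummary",
    "summarize",
    "fit_exponential",
    "wilson_interval",
    "censored_exponential_mean",
    "survival_integral_lower_bound",
    "params_digest",
]

_SUCCESS = ("transfer", "active_mode_reached")


def params_digest(params) -> str:
    """Stable short digest of a parameter mapping/dataclass for provenance."""
    if hasattr(params, "__dataclass_fields__"):
        d = {k: getattr(params, k) for k in params.__dataclass_fields__}
    else:
        d = dict(params)
    payload = json.dumps({k: repr(v) for k, v in sorted(d.items())}, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def wilson_interval(k: int, n: int, ci_level: float = 0.90) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    if n == 0:
        return (0.0, 1.0)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    p = k / n
    denom = 1.0 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


@dataclass(frozen=True)
class EnsembleSummary:
    """Ensemble-level outcome statistics.

    mean_fpt averages non-timeout first-passage times (µs); p_transfer is the
    splitting probability #success/(#success + #dissociation); CIs are a
    percentile bootstrap (mean) and Wilson interval (proportion).
    """

    n_total: int
    n_transfer: int
    n_dissoc: int
    n_timeout: int
    mean_fpt: float
    fpt_ci: tuple[float, float]
    p_transfer: float
    p_ci: tuple[float, float]
    master_seed: Optional[int] = None
    params_hash: str = ""
    mean_fpt_transfer: float = float("nan")
    mean_fpt_dissoc: float = float("nan")
    censored_mean: float = float("nan")

    @property
    def sem_fpt(self) -> float:
        """Half-width of the bootstrap CI as a dispersion proxy."""
        return 0.5 * (self.fpt_ci[1] - self.fpt_ci[0])


def summarize(
    results: Sequence[FPTResult],
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.90,
    master_seed: Optional[int] = None,
    params_hash: str = "",
    on_all_timeout: str = "raise",
) -> EnsembleSummary:
    """Reduce per-trajectory outcomes to an :class:`EnsembleSummary`.

    Timeouts are excluded from the mean FPT; if they exceed 1% of the
    ensemble a censoring warning is issued and ``censored_mean`` (the
    censored-exponential estimate) should be preferred.  With
    on_all_timeout="censor", an all-timeout ensemble yields mean_fpt = nan
    instead of an error.
    """
    if len(results) == 0:
        raise ValueError("empty result list")
    times = np.array([r.first_passage_time for r in results])
    outcomes = np.array([r.outcome for r in results])
    n_total = len(results)
    n_transfer = int(np.sum(np.isin(outcomes, _SUCCESS)))
    n_dissoc = int(np.sum(outcomes == "dissociation"))
    n_timeout = int(np.sum(outcomes == "timeout"))

    completed = times[outcomes != "timeout"]
    cens_mean = censored_exponential_mean(times, outcomes != "timeout")
    if n_timeout == n_total:
        if on_all_timeout == "raise":
            raise ValueError("all replicates timed out; increase max_time")
        mean = float("nan")
        ci = (float("nan"), float("nan"))
    else:
        if n_timeout > 0.01 * n_total:
            warnings.warn(
                f"{n_timeout}/{n_total} replicates timed out; mean_fpt is "
                "right-censored (see censored_mean)",
                stacklevel=2,
            )
        mean = float(completed.mean())
        if len(completed) == 1 or np.ptp(completed) == 0:
            ci = (mean, mean)
        else:
            rng = np.random.default_rng(seed)
            idx = rng.integers(0, len(completed), size=(n_boot, len(completed)))
            boot = completed[idx].mean(axis=1)
            lo, hi = np.percentile(boot, [50 * (1 - ci_level), 50 * (1 + ci_level)])
            ci = (float(lo), float(hi))

    n_resolved = n_transfer + n_dissoc
    p = n_transfer / n_resolved if n_resolved else float("nan")
    p_ci = wilson_interval(n_transfer, n_resolved, ci_level) if n_resolved else (0.0, 1.0)

    t_tr = times[np.isin(outcomes, _SUCCESS)]
    t_di = times[outcomes == "dissociation"]
    return EnsembleSummary(
        n_total=n_total,
        n_transfer=n_transfer,
        n_dissoc=n_dissoc,
        n_timeout=n_timeout,
        mean_fpt=mean,
        fpt_ci=ci,
        p_transfer=p,
        p_ci=p_ci,
        master_seed=master_seed,
        params_hash=params_hash,
        mean_fpt_transfer=float(t_tr.mean()) if len(t_tr) else float("nan"),
        mean_fpt_dissoc=float(t_di.mean()) if len(t_di) else float("nan"),
        censored_mean=cens_mean,
    )


def censored_exponential_mean(times, completed_mask) -> float:
    """MLE of the mean under type-I censoring and an exponential FPT law.

    mean = (sum of all observed times, censored or not) / (#completed).
    Falls back to +inf when nothing completed (use the survival bound then).
    """
    times = np.asarray(times, dtype=float)
    completed_mask = np.asarray(completed_mask, dtype=bool)
    n_events = int(completed_mask.sum())
    if n_events == 0:
        return float("inf")
    return float(times.sum() / n_events)


def survival_integral_lower_bound(times, completed_mask) -> float:
    """Distribution-free lower bound on the mean FPT from censored data.

    E[T] ≥ ∫₀^τ S(t) dt for any censoring horizon τ; computed from the
    empirical survival function of min(T, τ).
    """
    times = np.asarray(times, dtype=float)
    # mean of min(T, tau) equals the integral of the empirical survival
    return float(times.mean())


def fit_exponential(times, n_boot: int = 200, seed: int = 0):
    """Fit a one-parameter exponential and test goodness of fit.

    Returns (rate, ks_statistic, p_value).  rate is the MLE 1/mean; the KS
    p-value uses a parametric bootstrap (Lilliefors-style) because the rate
    is estimated from the same sample.
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 50:
        raise ValueError("need at least 50 observations")
    if np.ptp(times) == 0 or times.mean() <= 0:
        raise ValueError("degenerate sample")
    mean = times.mean()
    rate = 1.0 / mean
    ks = stats.kstest(times, "expon", args=(0.0, mean)).statistic
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    n = len(times)
    for b in range(n_boot):
        sample = rng.exponential(scale=mean, size=n)
        boot[b] = stats.kstest(sample, "expon", args=(0.0, sample.mean())).statistic
    p_value = float(np.mean(boot >= ks))
    return float(rate), float(ks), p_value
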