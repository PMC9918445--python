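"""Parameter learning from detection-mode counts.

Two routes share one likelihood: a derivative-free maximum-likelihood
fit (Nelder-Mead on log-rates / logit-sensitivities) and a Bayesian
random-walk Metropolis sampler targeting likelihood x prior, with
inverse-gamma(0.001, 0.001) priors on the transition intensities and
uniform(0, 1) priors on the sensitivities.  Proposal scales adapt during
burn-in only, so detailed balance holds for the retained draws; chains
are bitwise-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .natural_history import ModelSpec, MortalitySchedule, RateParameters
from .screening_likelihood import (
    PARTICIPANT_MODES,
    REFUSER_MODES,
    DetectionModeCounts,
    ScreeningDesign,
    log_likelihood,
    mode_probabilities,
)

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSummary",
    "FitResult",
    "McmcResult",
    "param_names",
    "fit_mle",
    "fit_mcmc",
    "credible_interval",
]


@dataclass(frozen=True)
class PriorSpec:
    """Priors: inverse-gamma(shape, scale) on rates, uniform(0,1) on sensitivities."""

    rate_shape: float = 0.001
    rate_scale: float = 0.001

    def __post_init__(self) -> None:
        if self.rate_shape <= 0 or self.rate_scale <= 0:
            raise ValueError("inverse-gamma shape and scale must be > 0")

    def log_rate_prior(self, rate: float) -> float:
        # inverse-gamma density, written out (hot path of the sampler);
        # identical to scipy.stats.invgamma.logpdf(rate, a=shape, scale=scale)
        a, s = self.rate_shape, self.rate_scale
        if rate <= 0:
            return -np.inf
        return a * np.log(s) - math.lgamma(a) - (a + 1.0) * np.log(rate) - s / rate


@dataclass(frozen=True)
class McmcConfig:
    """Random-walk Metropolis settings; seeds are echoed into outputs."""

    n_iterations: int = 6000
    n_burnin: int = 2000
    n_chains: int = 2
    seed: int = 0
    initial_scale: float = 0.15
    target_acceptance: float = 0.30

    def __post_init__(self) -> None:
        if not (self.n_iterations > self.n_burnin >= 0):
            raise ValueError("need n_iterations > n_burnin >= 0")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass(frozen=True)
class FitResult:
    rates: RateParameters
    log_likelihood: float
    converged: bool
    n_evaluations: int


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean/median/2.5%/97.5%, ESS and acceptance rate."""

    table: pd.DataFrame
    acceptance_rate: float

    def __post_init__(self) -> None:
        q = self.table
        if not ((q["q2.5"] <= q["median"]) & (q["median"] <= q["q97.5"])).all():
            raise ValueError("posterior quantiles out of order")
        if (q["ess"] <= 0).any():
            raise ValueError("effective sample size must be > 0")


@dataclass
class McmcResult:
    draws: pd.DataFrame  # columns: iteration, chain, <parameters>
    summary: PosteriorSummary
    config: McmcConfig

    def rates_at(self, row) -> RateParameters:
        names = param_names_from_frame(self.draws)
        return _to_rates(
            [row[n] for n in names], names, nonprog_fraction=0.0
        )


def param_names(spec: ModelSpec) -> list[str]:
    if spec.has_adenoma:
        return ["lambda1a", "lambda1b", "lambda2", "sens_adenoma", "sens_crc"]
    return ["lambda1", "lambda2", "sens_crc"]


def param_names_from_frame(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in ("iteration", "chain")]


_RATE_NAMES = {"lambda1", "lambda1a", "lambda1b", "lambda2"}


def _to_rates(values: Sequence[float], names: Sequence[str], nonprog_fraction=0.0) -> RateParameters:
    kw = dict(zip(names, values))
    kw["nonprog_fraction"] = nonprog_fraction
    return RateParameters(**kw)


def _transform(values: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Natural parameters -> unconstrained (log rates, logit sensitivities)."""
    out = np.empty_like(values, dtype=float)
    for i, n in enumerate(names):
        out[i] = np.log(values[i]) if n in _RATE_NAMES else logit(values[i])
    return out


def _untransform(theta: np.ndarray, names: Sequence[str]) -> np.ndarray:
    out = np.empty_like(theta, dtype=float)
    for i, n in enumerate(names):
        out[i] = np.exp(theta[i]) if n in _RATE_NAMES else expit(theta[i])
    return out


def _check_identifiable(counts: DetectionModeCounts, n_free: int) -> None:
    informative = len(counts.present(PARTICIPANT_MODES)) + len(
        counts.present(REFUSER_MODES)
    )
    if informative < n_free:
        raise ValueError(
            f"unidentifiable: {informative} informative detection modes for "
            f"{n_free} free parameters"
        )


def make_loglik(
    counts: DetectionModeCounts,
    design: ScreeningDesign,
    spec: ModelSpec,
    mort: MortalitySchedule,
) -> tuple[Callable[[np.ndarray], float], list[str]]:
    """Log-likelihood over the natural parameter vector of the variant."""
    names = param_names(spec)
    _check_identifiable(counts, len(names))

    def loglik(values: np.ndarray) -> float:
        try:
            rates = _to_rates(values, names)
            probs = mode_probabilities(spec, rates, mort, design)
        except (ValueError, FloatingPointError):
            return -np.inf
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return log_likelihood(counts, probs)

    return loglik, names


_DEFAULT_START = {
    "lambda1": 2e-3,
    "lambda1a": 2e-3,
    "lambda1b": 0.1,
    "lambda2": 0.4,
    "sens_crc": 0.6,
    "sens_adenoma": 0.5,
}


def fit_mle(
    counts: DetectionModeCounts,
    design: ScreeningDesign,
    spec: ModelSpec,
    mort: MortalitySchedule,
    start: RateParameters | None = None,
) -> FitResult:
    """Maximum-likelihood point estimate on transformed parameters."""
    loglik, names = make_loglik(counts, design, spec, mort)
    if start is not None:
        x0 = np.array([getattr(start, n) for n in names], dtype=float)
    else:
        x0 = np.array([_DEFAULT_START[n] for n in names])
    theta0 = _transform(x0, names)

    def nll(theta: np.ndarray) -> float:
        return -loglik(_untransform(theta, names))

    res = minimize(
        nll,
        theta0,
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-9, "adaptive": True},
    )
    if not res.success:
        warnings.warn(
            f"MLE did not converge: {res.message}", RuntimeWarning, stacklevel=2
        )
    values = _untransform(res.x, names)
    return FitResult(
        rates=_to_rates(values, names),
        log_likelihood=-float(res.fun),
        converged=bool(res.success),
        n_evaluations=int(res.nfev),
    )


def _log_posterior(
    theta: np.ndarray,
    loglik: Callable[[np.ndarray], float],
    names: Sequence[str],
    prior: PriorSpec,
) -> float:
    values = _untransform(theta, names)
    lp = 0.0
    for v, n in zip(values, names):
        if n in _RATE_NAMES:
            # inverse-gamma prior on the rate + Jacobian of the log transform
            lp += prior.log_rate_prior(v) + np.log(v)
        else:
            # uniform(0,1) prior + Jacobian of the logit transform
            lp += np.log(v) + np.log1p(-v)
    if not np.isfinite(lp):
        return -np.inf
    ll = loglik(values)
    return lp + ll


def fit_mcmc(
    counts: DetectionModeCounts,
    design: ScreeningDesign,
    spec: ModelSpec,
    mort: MortalitySchedule,
    prior: PriorSpec | None = None,
    config: McmcConfig | None = None,
    start: RateParameters | None = None,
) -> McmcResult:
    """Random-walk Metropolis on log-rates / logit-sensitivities.

    Per-parameter proposal scales adapt toward the target acceptance rate
    during burn-in only; the retained chain is a fixed-kernel Metropolis
    sample.  Identical seed and config give bitwise-identical chains.
    """
    import arviz as az

    prior = prior or PriorSpec()
    config = config or McmcConfig()
    loglik, names = make_loglik(counts, design, spec, mort)
    k = len(names)

    if start is not None:
        x0 = np.array([getattr(start, n) for n in names], dtype=float)
    else:
        x0 = np.array([_DEFAULT_START[n] for n in names])

    kept_per_chain = config.n_iterations - config.n_burnin
    all_draws = np.empty((config.n_chains, kept_per_chain, k))
    n_acc_total = 0
    n_prop_total = 0

    for chain in range(config.n_chains):
        rng = np.random.default_rng([config.seed, chain])
        theta = _transform(x0, names) + 0.05 * rng.standard_normal(k)
        lp = _log_posterior(theta, loglik, names, prior)
        scales = np.full(k, config.initial_scale)
        acc_window = np.zeros(k)
        n_window = 0
        for it in range(config.n_iterations):
            # single-site updates in fixed scan order
            for j in range(k):
                prop = theta.copy()
                prop[j] += scales[j] * rng.standard_normal()
                lp_prop = _log_posterior(prop, loglik, names, prior)
                if np.log(rng.random()) < lp_prop - lp:
                    theta, lp = prop, lp_prop
                    acc_window[j] += 1
                    if it >= config.n_burnin:
                        n_acc_total += 1
                if it >= config.n_burnin:
                    n_prop_total += 1
            n_window += 1
            if it < config.n_burnin and n_window == 50:
                # Robbins-Monro-style scale adaptation, burn-in only
                rate = acc_window / n_window
                scales *= np.exp((rate - config.target_acceptance) * 1.0)
                scales = np.clip(scales, 1e-4, 10.0)
                acc_window[:] = 0.0
                n_window = 0
            if it >= config.n_burnin:
                all_draws[chain, it - config.n_burnin] = _untransform(theta, names)

    acc_rate = n_acc_total / max(n_prop_total, 1)
    if not (0.05 <= acc_rate <= 0.8):
        warnings.warn(
            f"post-burn-in acceptance rate {acc_rate:.3f} outside [0.05, 0.8]; "
            "consider adjusting initial_scale or lengthening burn-in",
            RuntimeWarning,
            stacklevel=2,
        )

    flat = all_draws.reshape(-1, k)
    rows = {
        "iteration": np.tile(np.arange(kept_per_chain), config.n_chains),
        "chain": np.repeat(np.arange(config.n_chains), kept_per_chain),
    }
    for j, n in enumerate(names):
        rows[n] = flat[:, j]
    draws = pd.DataFrame(rows)

    records = []
    for j, n in enumerate(names):
        x = all_draws[:, :, j]
        lo, hi = np.quantile(x, [0.025, 0.975])
        ess = float(az.ess(x))
        records.append(
            {
                "parameter": n,
                "mean": float(x.mean()),
                "median": float(np.median(x)),
                "q2.5": float(lo),
                "q97.5": float(hi),
                "ess": max(ess, 1e-12),
            }
        )
    summary = PosteriorSummary(
        table=pd.DataFrame(records).set_index("parameter"),
        acceptance_rate=float(acc_rate),
    )
    return McmcResult(draws=draws, summary=summary, config=config)


def credible_interval(
    samples: np.ndarray | pd.Series | Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Equal-tailed quantile interval (type-7 / linear interpolation)."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 100:
        raise ValueError("need at least 100 draws for a credible interval")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
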