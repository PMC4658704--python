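"""Marginal likelihoods by path sampling / stepping-stone, and Bayes factors.

Both estimators run Metropolis–Hastings chains over the power posteriors
prior x likelihood^beta along a schedule of beta values concentrated near
0 (quantiles of Beta(shape, 1), the spacing recommended for
stepping-stone sampling).  Path sampling integrates the per-step mean
log-likelihood over beta by the trapezoid rule; stepping-stone telescopes
the ratios of consecutive power-posterior normalisers with a log-sum-exp
estimate from the samples at the lower beta of each rung.  Chains are
warm-started from the previous step's final state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .coalsim import Genealogy
from .demography import PriorSpec, mh_sample

__all__ = [
    "PowerSchedule",
    "MarginalLikelihoodEstimate",
    "power_schedule",
    "estimate_marginal",
    "bayes_factor",
    "constant_model_log_marginal",
]


@dataclass
class PowerSchedule:
    betas: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.betas, dtype=float)
        if b[0] != 0.0 or b[-1] != 1.0 or np.any(np.diff(b) <= 0):
            raise ValueError("schedule must increase strictly from 0 to 1")
        self.betas = b

    @property
    def k(self) -> int:
        return len(self.betas) - 1


@dataclass
class MarginalLikelihoodEstimate:
    log_ml: float
    method: str                  # "PS" | "SS"
    schedule: PowerSchedule
    per_step_mean_lnl: np.ndarray
    seed: int
    per_step_ess: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"beta": self.schedule.betas, "mean_lnL": self.per_step_mean_lnl})
        if self.per_step_ess is not None:
            df["ess"] = self.per_step_ess
        return df


def power_schedule(k: int = 100, shape: float = 0.3) -> PowerSchedule:
    """beta_j = (j/K)^(1/shape), j = 0..K: Beta(shape, 1) quantile spacing."""
    if k < 2:
        raise ValueError("need K >= 2 steps")
    if shape <= 0:
        raise ValueError("shape must be positive")
    j = np.arange(k + 1)
    return PowerSchedule((j / k) ** (1.0 / shape))


def estimate_marginal(
    g: Genealogy,
    model_kind: str,
    priors: PriorSpec,
    schedule: PowerSchedule | None = None,
    iterations_per_step: int = 20_000,
    thin: int = 10,
    seed: int = 0,
    min_ess_warn: float = 50.0,
) -> tuple[MarginalLikelihoodEstimate, MarginalLikelihoodEstimate]:
    """(PS estimate, SS estimate) from one pass of power-posterior chains.

    Per-step burn-in is 10% of the step's iterations; each chain starts
    from the final state of the previous beta.
    """
    from .demography import ess as ess_fn

    if schedule is None:
        schedule = power_schedule()
    rng = np.random.default_rng(seed)
    betas = schedule.betas
    mean_lnl = np.empty(len(betas))
    step_ess = np.empty(len(betas))
    lnl_samples: list[np.ndarray] = []
    state = None
    for si, beta in enumerate(betas):
        trace = mh_sample(
            g,
            model_kind,
            priors,
            iterations=iterations_per_step,
            thin=thin,
            seed=int(rng.integers(2**31 - 1)),
            beta=float(beta),
            burn_in=0.10,
            init=state,
        )
        state = trace.final_state
        lnl = trace.loglik
        if not np.all(np.isfinite(lnl)):
            raise RuntimeError(f"non-finite log-likelihood at beta = {beta:.6g}")
        lnl_samples.append(lnl)
        mean_lnl[si] = float(lnl.mean())
        try:
            step_ess[si] = ess_fn(lnl)
        except ValueError:
            step_ess[si] = float(len(lnl))
        if step_ess[si] < min_ess_warn:
            import warnings

            warnings.warn(f"ESS {step_ess[si]:.0f} < {min_ess_warn:.0f} at beta={beta:.4g}")

    ps = float(np.trapezoid(mean_lnl, betas))
    ss = 0.0
    for si in range(len(betas) - 1):
        db = betas[si + 1] - betas[si]
        lnl = lnl_samples[si]
        ss += float(logsumexp(db * lnl) - math.log(len(lnl)))
    common = dict(schedule=schedule, per_step_mean_lnl=mean_lnl, seed=seed, per_step_ess=step_ess)
    return (
        MarginalLikelihoodEstimate(log_ml=ps, method="PS", **common),
        MarginalLikelihoodEstimate(log_ml=ss, method="SS", **common),
    )


def bayes_factor(log_ml_a: float, log_ml_b: float) -> dict:
    """2 ln BF of model a over model b, with the Kass–Raftery band annotation."""
    if not (np.isfinite(log_ml_a) and np.isfinite(log_ml_b)):
        raise ValueError("marginal likelihoods must be finite")
    two_ln_bf = 2.0 * (log_ml_a - log_ml_b)
    mag = abs(two_ln_bf)
    if mag < 2:
        band = "not worth more than a bare mention"
    elif mag < 6:
        band = "positive"
    elif mag < 10:
        band = "strong"
    else:
        band = "very strong"
    return {"two_ln_bf": two_ln_bf, "interpretation": band}


def constant_model_log_marginal(g: Genealogy, prior) -> float:
    """Analytic log marginal likelihood of the constant model with a truncated 1/x prior.

    With e coalescent events, A = sum C(k,2) dt and prior 1/(N ln(b/a)) on
    (a, b), the marginal is (prod C) / ln(b/a) * A^-e * [gamma(e, A/a) - gamma(e, A/b)]
    via the substitution u = A/N.  Used as the closed-form oracle for
    path-sampling / stepping-stone validation.
    """
    from scipy.special import gammainc, gammaln

    from .demography import Prior, _coal_data

    if not isinstance(prior, Prior) or prior.kind != "one_over_x":
        raise ValueError("oracle requires a truncated 1/x prior")
    h, s, cc, logc = _coal_data(g)
    e = len(h)
    a_stat = float(np.sum(cc * (h - s)))
    lo, hi = prior.lower, prior.upper
    frac = gammainc(e, a_stat / lo) - gammainc(e, a_stat / hi)
    if frac <= 0:
        raise ValueError("prior bounds exclude essentially all posterior mass")
    return (
        logc
        - math.log(math.log(hi / lo))
        - e * math.log(a_stat)
        + float(gammaln(e))
        + math.log(frac)
    )
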