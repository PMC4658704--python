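"""Fixed-genealogy Bayesian demographic inference.

The central approximation of this package: instead of jointly sampling
genealogies and demographic parameters, inference conditions on a single
clock-compatible genealogy (UPGMA on pairwise distances, ultrametric by
construction).  On that genealogy the coalescent likelihood of the
two-epoch model is exact, and a Metropolis–Hastings sampler with 1/x
priors on scaled sizes and uniform priors on the growth rate and
transition time draws the posterior.  Real-data posteriors are expected
to be narrower than a joint-sampling analysis would give, because
genealogical uncertainty is ignored.

Also here: a Bayesian skyline estimator (piecewise-constant sizes over
grouped coalescent intervals), effective sample size and HPD utilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .coalsim import Genealogy, TwoEpochModel
from .seqio import DistanceMatrix

__all__ = [
    "Prior",
    "PriorSpec",
    "PosteriorTrace",
    "SkylineEstimate",
    "upgma_genealogy",
    "coalescent_loglik",
    "mh_sample",
    "bayesian_skyline",
    "ess",
    "hpd",
    "default_priors",
]

TWO_EPOCH_PARAMS = ("N0", "N1", "r", "t_trans")
CONSTANT_PARAMS = ("N",)


@dataclass(frozen=True)
class Prior:
    """One-parameter prior: 'one_over_x' or 'uniform' on (lower, upper)."""

    kind: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in ("one_over_x", "uniform"):
            raise ValueError(f"unknown prior kind: {self.kind}")
        if not (0 <= self.lower < self.upper):
            raise ValueError("need 0 <= lower < upper")
        if self.kind == "one_over_x" and self.lower <= 0:
            raise ValueError("1/x prior needs lower > 0 to be normalisable")

    def logpdf(self, x: float) -> float:
        if not (self.lower <= x <= self.upper):
            return -math.inf
        if self.kind == "one_over_x":
            return -math.log(x) - math.log(math.log(self.upper / self.lower))
        return -math.log(self.upper - self.lower)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "one_over_x":
            return float(np.exp(rng.uniform(np.log(self.lower), np.log(self.upper))))
        return float(rng.uniform(self.lower, self.upper))


PriorSpec = dict  # parameter name -> Prior


@dataclass
class PosteriorTrace:
    names: list[str]
    samples: np.ndarray          # (n_samples, n_params), post burn-in
    loglik: np.ndarray
    logprior: np.ndarray
    thin: int
    seed: int
    acceptance: dict = field(default_factory=dict)
    final_state: np.ndarray | None = None
    beta: float = 1.0

    def __getitem__(self, name: str) -> np.ndarray:
        return self.samples[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.samples, columns=self.names)
        df.insert(0, "lnPrior", self.logprior)
        df.insert(0, "lnL", self.loglik)
        df.insert(0, "state", np.arange(len(df)) * self.thin)
        return df


@dataclass
class SkylineEstimate:
    times: np.ndarray
    median: np.ndarray
    hpd_lower: np.ndarray
    hpd_upper: np.ndarray
    m: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "median": self.median,
                "hpd_lower": self.hpd_lower,
                "hpd_upper": self.hpd_upper,
            }
        )


def upgma_genealogy(d: DistanceMatrix, quantum: float | None = None) -> Genealogy:
    """UPGMA (average-linkage) ultrametric genealogy from a distance matrix.

    Node height = merge distance / 2, so heights are in the units of the
    distance matrix (use p_distance or TN93 for substitutions/site).
    Zero-distance ties merge at height 0 in the clustering order.

    Finite-site distances are quantised (a p-distance is a multiple of
    1/L), so UPGMA piles nodes onto exactly tied heights — including
    clusters of identical sequences at height 0, where a coalescent
    density is degenerate.  Passing the distance ``quantum`` (1/L for
    p-distances) spreads each group of tied node heights evenly across
    the unresolved half-quantum above the observed value, in merge order
    so parents stay above children; use this when the genealogy feeds a
    coalescent likelihood.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    z = linkage(squareform(d.values, checks=False), method="average")
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=int)
    heights = np.zeros(total, dtype=float)
    for i in range(n - 1):
        a, b, dist, _ = z[i]
        node = n + i
        parent[int(a)] = parent[int(b)] = node
        heights[node] = dist / 2.0
    if quantum is not None:
        if quantum <= 0:
            raise ValueError("quantum must be positive")
        hq = quantum / 2.0  # height quantum: distances are twice the heights
        internal = heights[n:]
        groups: dict[float, list[int]] = {}
        for i, h in enumerate(internal):
            groups.setdefault(round(h / hq) * hq, []).append(i)
        for base, idx in groups.items():
            if len(idx) == 1 and base > 0:
                continue
            for j, i in enumerate(sorted(idx)):  # merge order = node order
                internal[i] = base + hq * (j + 1) / (len(idx) + 1)
        heights[n:] = internal
    return Genealogy(parent=parent, heights=heights, labels=list(d.ids))


def _coal_data(g: Genealogy):
    """(event heights, interval starts, C(k,2) per interval, sum log C(k,2))."""
    h = g.coalescent_times()
    n = g.n_tips
    k = np.arange(n, 1, -1, dtype=float)     # lineage count during each interval
    cc = k * (k - 1) / 2.0
    s = np.concatenate([[0.0], h[:-1]])
    return h, s, cc, float(np.sum(np.log(cc)))


def _cumulative_intensity(t: np.ndarray, model: TwoEpochModel) -> np.ndarray:
    """Lambda(0, t) for an array of times, vectorised over t."""
    tt, r, n1, n0 = model.t_trans, model.r, model.n1, model.n0
    tg = np.minimum(t, tt)
    if r == 0.0:
        growth = tg / n1
    else:
        with np.errstate(over="ignore"):
            growth = np.expm1(r * tg) / (r * n1)
    return growth + np.maximum(t - tt, 0.0) / n0


def _loglik_from_data(model: TwoEpochModel, h, s, cc, logc) -> float:
    tt, r, n1, n0 = model.t_trans, model.r, model.n1, model.n0
    with np.errstate(over="ignore"):
        log_n_at = np.where(h < tt, math.log(n1) - r * h, math.log(n0))
        lam = _cumulative_intensity(h, model) - _cumulative_intensity(s, model)
    val = logc - float(np.sum(log_n_at)) - float(np.sum(cc * lam))
    return val if np.isfinite(val) else -math.inf


def coalescent_loglik(g: Genealogy, model: TwoEpochModel | float) -> float:
    """Log density of the genealogy's coalescent times under the demography.

    A bare float is taken as a constant scaled size.
    """
    if isinstance(model, (int, float)):
        model = TwoEpochModel.constant(float(model))
    h, s, cc, logc = _coal_data(g)
    return _loglik_from_data(model, h, s, cc, logc)


def _params_to_model(kind: str, x: np.ndarray) -> TwoEpochModel:
    if kind == "constant":
        return TwoEpochModel.constant(float(x[0]))
    return TwoEpochModel(n0=float(x[0]), n1=float(x[1]), r=float(x[2]), t_trans=float(x[3]))


def default_priors(kind: str, skyline: SkylineEstimate | None = None,
                   root_height: float | None = None) -> PriorSpec:
    """Priors with bounds taken from a skyline's HPD envelope widened x3.

    Mirrors setting prior limits "using the skyline HPDs as guideline".
    Falls back to broad generic bounds when no skyline is supplied.
    """
    if skyline is not None:
        lo = max(float(np.min(skyline.hpd_lower)) / 3.0, 1e-8)
        hi = float(np.max(skyline.hpd_upper)) * 3.0
        root = float(skyline.times[-1]) if root_height is None else root_height
    else:
        lo, hi = 1e-6, 1.0
        root = 0.05 if root_height is None else root_height
    size_prior = Prior("one_over_x", lo, hi)
    if kind == "constant":
        return {"N": size_prior}
    # r bound: enough growth to traverse the size range three times over the
    # tree depth, capped so the prior's worst-case growth-epoch intensity
    # (~ e^{r t_trans}) stays small enough for path sampling to integrate
    r_max = min(3.0 * math.log(hi / lo), 15.0) / root
    return {
        "N0": size_prior,
        "N1": size_prior,
        "r": Prior("uniform", 0.0, r_max),
        "t_trans": Prior("uniform", 0.0, root),
    }


def _reflect(x: float, lo: float, hi: float) -> float:
    width = hi - lo
    if width <= 0:
        return lo
    y = (x - lo) % (2 * width)
    if y < 0:
        y += 2 * width
    return lo + (y if y <= width else 2 * width - y)


def mh_sample(
    g: Genealogy,
    model_kind: str,
    priors: PriorSpec,
    iterations: int = 200_000,
    thin: int = 100,
    seed: int = 0,
    beta: float = 1.0,
    burn_in: float = 0.25,
    size_step: float = 0.3,
    window_frac: float = 0.1,
    init: np.ndarray | None = None,
) -> PosteriorTrace:
    """Metropolis–Hastings on prior x likelihood^beta over the demography.

    Moves: multiplicative log-normal on size parameters (with the x'/x
    Hastings correction) and a reflected uniform window on r and t_trans.
    The first ``burn_in`` fraction of sampled states is discarded.  With
    beta < 1 the chain targets a power posterior (for marginal-likelihood
    estimation); beta = 0 samples the prior.
    """
    if model_kind not in ("constant", "two_epoch"):
        raise ValueError("model_kind must be 'constant' or 'two_epoch'")
    if iterations < 1000:
        raise ValueError("need iterations >= 1000")
    names = list(CONSTANT_PARAMS if model_kind == "constant" else TWO_EPOCH_PARAMS)
    for nm in names:
        if nm not in priors:
            raise ValueError(f"prior missing for parameter {nm}")
    rng = np.random.default_rng(seed)
    h, s, cc, logc = _coal_data(g)
    multiplicative = [nm in ("N", "N0", "N1") for nm in names]

    def logpost(x: np.ndarray) -> tuple[float, float]:
        lp = sum(priors[nm].logpdf(v) for nm, v in zip(names, x))
        if not np.isfinite(lp):
            return -math.inf, -math.inf
        ll = _loglik_from_data(_params_to_model(model_kind, x), h, s, cc, logc)
        return ll, lp

    if init is None:
        for _ in range(200):
            x = np.array([priors[nm].sample(rng) for nm in names])
            ll, lp = logpost(x)
            if np.isfinite(ll):
                break
        else:
            raise RuntimeError("could not find a starting point with finite likelihood")
    else:
        x = np.asarray(init, dtype=float).copy()
        ll, lp = logpost(x)
        if not np.isfinite(ll):
            raise ValueError("init state has non-finite likelihood")

    kept_states, kept_ll, kept_lp = [], [], []
    accepts = {nm: 0 for nm in names}
    proposals = {nm: 0 for nm in names}
    for it in range(iterations):
        for pi, nm in enumerate(names):
            proposals[nm] += 1
            prop = x.copy()
            if multiplicative[pi]:
                factor = math.exp(size_step * rng.standard_normal())
                prop[pi] = x[pi] * factor
                log_hastings = math.log(factor)  # q(x|x') / q(x'|x) = x'/x
            else:
                w = window_frac * (priors[nm].upper - priors[nm].lower)
                prop[pi] = _reflect(x[pi] + rng.uniform(-w, w), priors[nm].lower, priors[nm].upper)
                log_hastings = 0.0
            ll_p, lp_p = logpost(prop)
            log_alpha = beta * (ll_p - ll) + (lp_p - lp) + log_hastings
            if np.isfinite(ll_p) and math.log(rng.random()) < log_alpha:
                x, ll, lp = prop, ll_p, lp_p
                accepts[nm] += 1
        if (it + 1) % thin == 0:
            kept_states.append(x.copy())
            kept_ll.append(ll)
            kept_lp.append(lp)
    n_kept = len(kept_states)
    drop = int(burn_in * n_kept)
    samples = np.asarray(kept_states[drop:])
    if samples.size == 0:
        raise RuntimeError("no post burn-in samples; increase iterations or lower thin")
    if all(accepts[nm] == 0 for nm in names):
        raise RuntimeError("zero accepted moves; change proposal scales")
    return PosteriorTrace(
        names=names,
        samples=samples,
        loglik=np.asarray(kept_ll[drop:]),
        logprior=np.asarray(kept_lp[drop:]),
        thin=thin,
        seed=seed,
        acceptance={nm: accepts[nm] / proposals[nm] for nm in names},
        final_state=x.copy(),
        beta=beta,
    )


def bayesian_skyline(
    g: Genealogy,
    m: int = 10,
    iterations: int = 50_000,
    thin: int = 50,
    seed: int = 0,
    grid_points: int = 50,
    size_bounds: tuple[float, float] = (1e-8, 100.0),
    burn_in: float = 0.25,
) -> tuple[SkylineEstimate, PosteriorTrace]:
    """Piecewise-constant skyline over m groups of coalescent intervals.

    Intervals are grouped contiguously from the present with near-equal
    event counts.  The first group's size carries a 1/x prior; each later
    group is smoothed by an exponential prior with mean equal to its
    predecessor.  The estimate is reported on a regular time grid as the
    posterior median with 95% HPD bounds.
    """
    n = g.n_tips
    if m > n - 1:
        raise ValueError(f"m = {m} groups exceed the {n - 1} coalescent events")
    h, s, cc, _ = _coal_data(g)
    groups = np.concatenate([np.full(len(idx), gi) for gi, idx in
                             enumerate(np.array_split(np.arange(n - 1), m))])
    dt = h - s
    first_prior = Prior("one_over_x", *size_bounds)
    rng = np.random.default_rng(seed)

    # per-group sufficient statistics
    ev_count = np.array([np.sum(groups == gi) for gi in range(m)], dtype=float)
    a_g = np.array([np.sum((cc * dt)[groups == gi]) for gi in range(m)])

    def loglik(theta: np.ndarray) -> float:
        return float(-np.sum(ev_count * np.log(theta)) - np.sum(a_g / theta))

    def logprior(theta: np.ndarray) -> float:
        lp = first_prior.logpdf(theta[0])
        if not np.isfinite(lp):
            return -math.inf
        for gi in range(1, m):
            lp += -math.log(theta[gi - 1]) - theta[gi] / theta[gi - 1]
        return lp

    theta = np.full(m, max(np.sum(a_g) / max(n - 1, 1), size_bounds[0] * 10))
    ll, lp = loglik(theta), logprior(theta)
    kept, kept_ll, kept_lp = [], [], []
    accept = 0
    total = 0
    for it in range(iterations):
        for gi in range(m):
            total += 1
            prop = theta.copy()
            factor = math.exp(0.5 * rng.standard_normal())
            prop[gi] = theta[gi] * factor
            lp_p = logprior(prop)
            if not np.isfinite(lp_p):
                continue
            ll_p = loglik(prop)
            if math.log(rng.random()) < (ll_p - ll) + (lp_p - lp) + math.log(factor):
                theta, ll, lp = prop, ll_p, lp_p
                accept += 1
        if (it + 1) % thin == 0:
            kept.append(theta.copy())
            kept_ll.append(ll)
            kept_lp.append(lp)
    drop = int(burn_in * len(kept))
    samples = np.asarray(kept[drop:])
    trace = PosteriorTrace(
        names=[f"theta_{gi + 1}" for gi in range(m)],
        samples=samples,
        loglik=np.asarray(kept_ll[drop:]),
        logprior=np.asarray(kept_lp[drop:]),
        thin=thin,
        seed=seed,
        acceptance={"theta": accept / max(total, 1)},
    )
    # group end-times (last event height per group); grid time t maps to the
    # first group whose end time is >= t
    ends = np.array([h[groups == gi][-1] for gi in range(m)])
    times = np.linspace(0.0, g.root_height, grid_points)
    idx = np.searchsorted(ends, times, side="left").clip(max=m - 1)
    med = np.empty(grid_points)
    lo = np.empty(grid_points)
    hi = np.empty(grid_points)
    for gpt in range(grid_points):
        col = samples[:, idx[gpt]]
        med[gpt] = np.median(col)
        lo[gpt], hi[gpt] = hpd(col, 0.95)
    return SkylineEstimate(times=times, median=med, hpd_lower=lo, hpd_upper=hi, m=m), trace


def ess(series) -> float:
    """Effective sample size N / (1 + 2 sum rho_k), initial-positive-sequence cutoff."""
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need >= 10 samples")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0:
        raise ValueError("ESS undefined for a constant series")
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    if rho[1] <= 0:
        # antithetic chain: credit the (negative) lag-1 correlation only
        denom = max(1.0 + 2.0 * rho[1], 1.0 / n)
    else:
        total = 0.0
        for k in range(1, n):
            if rho[k] <= 0:
                break
            total += rho[k]
        denom = 1.0 + 2.0 * total
    return float(n / denom)


def hpd(samples, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(mass * N) sorted samples."""
    if not (0 < mass < 1):
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need >= 20 samples for an HPD interval")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])
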