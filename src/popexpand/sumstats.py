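"""Diversity indices and neutrality tests.

Haplotype diversity Hd, nucleotide diversity pi, segregating sites S and
mean pairwise differences k_bar; Tajima's D (Tajima 1989) and Fu's Fs
(Fu 1997), both signed so that recent population expansion drives them
negative; empirical p-values by constant-size neutral coalescent
simulation.

Fu's Fs is computed from the Ewens sampling formula.  The probability of
observing at least the sampled number of haplotypes,

    S' = sum_{k >= k_obs} |s(n, k)| theta^k / (theta)_n,

uses exact unsigned Stirling numbers of the first kind (Python big ints,
cached per n) evaluated in log space, so the statistic is stable up to
several hundred sequences without extended-precision libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import logsumexp

from .seqio import Alignment, collapse_haplotypes, pairwise_distance

__all__ = [
    "DiversityResult",
    "NeutralityResult",
    "diversity",
    "tajimas_d",
    "fus_fs",
    "fs_from_counts",
    "neutrality_pvalue",
]


@dataclass
class DiversityResult:
    hd: float       # haplotype diversity, in [0, 1]
    pi: float       # nucleotide diversity per site
    s: int          # segregating sites
    k_bar: float    # mean pairwise differences (sites)
    n: int
    length: int


@dataclass
class NeutralityResult:
    statistic: str       # "D" or "FS"
    value: float
    p_value: float | None = None
    method: str | None = None   # "coalescent_sim" | "beta_approx"
    n_replicates: int | None = None
    seed: int | None = None


def _k_bar(aln: Alignment) -> float:
    d = pairwise_distance(aln, "raw_differences").values
    n = aln.n
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def segregating_sites(aln: Alignment) -> int:
    """Number of columns with >= 2 distinct resolved bases (pairwise-deletion convention)."""
    arr = aln.to_array()
    present = np.stack([(arr == base).any(axis=0) for base in b"ACGT"])
    return int(np.sum(present.sum(axis=0) >= 2))


def diversity(aln: Alignment) -> DiversityResult:
    """Hd, pi, S and k_bar for an alignment of n >= 2 sequences.

    Hd = n/(n-1) (1 - sum p_i^2) over haplotype frequencies; pi = k_bar / L.
    """
    if aln.n < 2:
        raise ValueError("diversity requires n >= 2")
    ht = collapse_haplotypes(aln)
    p = ht.frequencies()
    n = aln.n
    hd = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    k_bar = _k_bar(aln)
    return DiversityResult(
        hd=hd, pi=k_bar / aln.length, s=segregating_sites(aln), k_bar=k_bar, n=n, length=aln.length
    )


def tajima_constants(n: int) -> dict[str, float]:
    """The a1..e2 constants of Tajima (1989) for sample size n."""
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(aln: Alignment) -> NeutralityResult:
    """Tajima's D: normalised difference of the pi- and S-based theta estimators."""
    if aln.n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    s = segregating_sites(aln)
    if s == 0:
        raise ValueError("statistic undefined: no segregating sites")
    c = tajima_constants(aln.n)
    k_bar = _k_bar(aln)
    var = c["e1"] * s + c["e2"] * s * (s - 1)
    d = (k_bar - s / c["a1"]) / math.sqrt(var)
    return NeutralityResult(statistic="D", value=d)


@lru_cache(maxsize=8)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n, k)| for k = 0..n via the exact big-int recurrence."""
    row = [1]  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (row[k - 1] if k - 1 < len(row) else 0) + (m - 1) * (
                row[k] if k < len(row) else 0
            )
        row = new
    return tuple(math.log(v) if v > 0 else -math.inf for v in row)


def fs_from_counts(n: int, k_obs: int, theta: float) -> float:
    """Fu's Fs from sample size, observed haplotype count and theta (= k_bar)."""
    if n < 2 or k_obs < 1:
        raise ValueError("need n >= 2 and k_obs >= 1")
    if theta <= 0:
        raise ValueError("theta must be positive (no pairwise differences observed)")
    log_poch = math.lgamma(theta + n) - math.lgamma(theta)  # log (theta)_n
    lrow = _log_stirling_row(n)
    log_terms = [lrow[k] + k * math.log(theta) - log_poch for k in range(k_obs, n + 1)]
    log_sp = float(logsumexp(log_terms))
    if log_sp >= 0.0:
        # S' = 1 exactly can only happen at k_obs = 1; treat tiny overshoot as boundary
        if log_sp > 1e-12:
            raise ValueError("S' > 1: numerical failure in Ewens formula")
        raise ValueError("S' at boundary 1: Fs undefined")
    # log(1 - S') stable for S' near 0 or 1
    log_one_minus = math.log(-math.expm1(log_sp))
    return log_sp - log_one_minus


def fus_fs(aln: Alignment) -> NeutralityResult:
    """Fu's Fs = ln(S'/(1-S')) with theta taken as the mean pairwise difference."""
    if aln.n < 2:
        raise ValueError("Fs requires n >= 2")
    ht = collapse_haplotypes(aln)
    if ht.k < 2:
        raise ValueError("Fs requires >= 2 observed haplotypes")
    theta = _k_bar(aln)
    return NeutralityResult(statistic="FS", value=fs_from_counts(aln.n, ht.k, theta))


def neutrality_pvalue(
    stat: str,
    observed: float,
    n: int,
    theta: float,
    reps: int = 1000,
    seed: int = 0,
    length: int = 352,
    sub_model=None,
) -> NeutralityResult:
    """Lower-tail empirical p-value for D or FS under the constant-size neutral null.

    Null datasets are simulated with the package's coalescent generator at
    scaled size N = theta / (2 L) so that E[k_bar] = theta, the statistic is
    recomputed on each, and p is the fraction of replicates <= observed.
    """
    from . import coalsim  # deferred: coalsim sits beside, not below, this module

    if stat not in ("D", "FS"):
        raise ValueError("stat must be 'D' or 'FS'")
    if reps < 100:
        raise ValueError("need reps >= 100 for a meaningful empirical p")
    if sub_model is None:
        sub_model = coalsim.SubstitutionModel()
    model = coalsim.TwoEpochModel.constant(theta / (2.0 * length))
    rng = np.random.default_rng(seed)
    values = []
    failed = 0
    for _ in range(reps):
        g = coalsim.simulate_genealogy(n, model, rng)
        sim = coalsim.simulate_sequences(g, length, sub_model, rng)
        try:
            if stat == "D":
                values.append(tajimas_d(sim).value)
            else:
                values.append(fus_fs(sim).value)
        except ValueError:
            failed += 1
    if failed > reps / 2:
        raise ValueError(f"statistic undefined in {failed}/{reps} null replicates")
    values_arr = np.asarray(values)
    p = float(np.mean(values_arr <= observed))
    return NeutralityResult(
        statistic=stat,
        value=observed,
        p_value=p,
        method="coalescent_sim",
        n_replicates=len(values),
        seed=seed,
    )
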