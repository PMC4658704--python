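"""Coalescent simulation under a two-epoch demography with HKY+I sequences.

This is the package's synthetic-data generator and the testbed for every
downstream stage.  Time and population size are both measured in expected
substitutions per site: the natural "size" unit is the female effective
population size scaled by the mutation rate (fNeμ), so no absolute years
enter simulation or inference — only the expansion-dating step converts
units.

The demography is, looking backwards from the present (t = 0):

    N(t) = N1 * exp(-r t)   for 0 <= t < t_trans   (recent exponential growth)
    N(t) = N0               for t >= t_trans       (ancient constant size)

with independent N0 and N1 (no continuity constraint at t_trans).
Genealogies are drawn by the standard time-rescaled coalescent: with k
lineages the next coalescence solves C(k,2) * Lambda(t_now, t) = u for
u ~ Exp(1), with closed-form inversion inside each epoch.

Sequence evolution is HKY with a proportion ``p_inv`` of invariant sites.
Branch lengths are expected substitutions per site averaged over ALL
sites; variable sites therefore evolve at rate 1/(1 - p_inv), which keeps
E[pi] = 2N independent of p_inv.  All randomness flows through one
``numpy.random.Generator`` (PCG64) per dataset, with draws consumed in a
documented, platform-stable order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .seqio import Alignment, SampleMetadata

import pandas as pd

__all__ = [
    "TwoEpochModel",
    "SubstitutionModel",
    "Genealogy",
    "SimulationConfig",
    "LocalityLayout",
    "demographic_intensity",
    "invert_intensity",
    "simulate_genealogy",
    "simulate_sequences",
    "generate_dataset",
    "study_config",
]

BASES = "ACGT"


@dataclass(frozen=True)
class TwoEpochModel:
    """Two-epoch demography: present scaled size N1 growing at rate r since
    t_trans, preceded by constant scaled size N0.  All quantities in
    substitutions/site units (sizes are fNeμ)."""

    n1: float
    r: float
    n0: float
    t_trans: float

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n0 <= 0:
            raise ValueError("population sizes must be positive")
        if self.t_trans < 0 or self.r < 0:
            raise ValueError("r and t_trans must be non-negative")

    @classmethod
    def constant(cls, n: float) -> "TwoEpochModel":
        """Constant-size demography of scaled size n (r = 0, t_trans = 0)."""
        return cls(n1=n, r=0.0, n0=n, t_trans=0.0)

    def size_at(self, t: float) -> float:
        """N(t) looking backwards from the present."""
        if t < self.t_trans:
            return self.n1 * math.exp(-self.r * t)
        return self.n0


def demographic_intensity(model: TwoEpochModel, a: float, b: float) -> float:
    """Coalescent intensity Lambda(a, b) = integral_a^b dt / N(t), 0 <= a <= b."""
    if a > b:
        raise ValueError("need a <= b")
    if a < 0:
        raise ValueError("times must be non-negative")
    tt, r, n1, n0 = model.t_trans, model.r, model.n1, model.n0
    total = 0.0
    ga, gb = min(a, tt), min(b, tt)  # portion inside the growth epoch
    if gb > ga:
        if r == 0.0:
            total += (gb - ga) / n1
        else:
            # e^{rb} - e^{ra} = e^{ra} expm1(r (b-a)): stable for small r
            total += math.exp(r * ga) * math.expm1(r * (gb - ga)) / (r * n1)
    ca, cb = max(a, tt), max(b, tt)  # portion inside the constant epoch
    if cb > ca:
        total += (cb - ca) / n0
    return total


def invert_intensity(model: TwoEpochModel, a: float, target: float) -> float:
    """Time b >= a with Lambda(a, b) = target (closed form within each epoch)."""
    if target < 0:
        raise ValueError("target intensity must be >= 0")
    if target == 0.0:
        return a
    tt, r, n1, n0 = model.t_trans, model.r, model.n1, model.n0
    if a < tt:
        if r == 0.0:
            cap = (tt - a) / n1
            if target <= cap:
                return a + target * n1
        else:
            # Lambda(a, b) = e^{ra} expm1(r (b-a)) / (r N1) within the growth
            # epoch, so b = a + log1p(target r N1 e^{-ra}) / r
            ra = r * a
            increment = target * r * n1 * math.exp(-ra)
            b = a + math.log1p(increment) / r
            if b <= tt:
                return b
            if r * (tt - a) > 700:
                return b  # epoch effectively never ends numerically
            cap = math.exp(ra) * math.expm1(r * (tt - a)) / (r * n1)
        target = target - cap
        a = tt
    return a + target * n0


def simulate_genealogy(n: int, model: TwoEpochModel, rng) -> "Genealogy":
    """Draw a coalescent genealogy for n tips under the two-epoch demography.

    Draw order per coalescence: one Exp(1) waiting intensity, then one
    unordered pair of lineages (without replacement).
    """
    if n < 2:
        raise ValueError("need n >= 2 tips")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    total = 2 * n - 1
    parent = np.full(total, -1, dtype=int)
    heights = np.zeros(total, dtype=float)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        pair_rate = k * (k - 1) / 2.0
        u = rng.exponential()
        t = invert_intensity(model, t, u / pair_rate)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        heights[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    labels = [f"S{i + 1:03d}" for i in range(n)]
    return Genealogy(parent=parent, heights=heights, labels=labels)


@dataclass
class Genealogy:
    """Rooted ultrametric binary genealogy.

    Nodes 0..n-1 are tips (height 0), nodes n..2n-2 internal; ``parent[i]``
    is -1 for the root.  Heights are in substitutions/site.
    """

    parent: np.ndarray
    heights: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.heights = np.asarray(self.heights, dtype=float)
        n = self.n_tips
        if np.max(np.abs(self.heights[:n])) > 1e-10:
            raise ValueError("tips must sit at height 0 (ultrametric genealogy)")
        for i, p in enumerate(self.parent):
            if p >= 0 and self.heights[p] < self.heights[i] - 1e-12:
                raise ValueError("parent below child: invalid node heights")

    @property
    def n_tips(self) -> int:
        return (len(self.parent) + 1) // 2

    @property
    def root(self) -> int:
        return int(np.where(self.parent < 0)[0][0])

    @property
    def root_height(self) -> float:
        return float(self.heights[self.root])

    def coalescent_times(self) -> np.ndarray:
        """Sorted internal-node heights (the n-1 coalescent event times)."""
        return np.sort(self.heights[self.n_tips:])

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in self.parent]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        return ch

    def to_newick(self) -> str:
        ch = self.children()

        def rec(i: int) -> str:
            if not ch[i]:
                name = self.labels[i]
            else:
                name = "(" + ",".join(rec(c) for c in ch[i]) + ")"
            if self.parent[i] < 0:
                return name
            bl = self.heights[self.parent[i]] - self.heights[i]
            return f"{name}:{bl:.10g}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Genealogy":
        """Parse a Newick string (branch lengths in substitutions/site)."""
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        tree.calc_node_root_distances()
        max_d = max(leaf.root_distance for leaf in tree.leaf_node_iter())
        nodes = list(tree.preorder_node_iter())
        leaves = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        index = {id(nd): i for i, nd in enumerate(leaves)}
        for j, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + j
        total = len(leaves) + len(internals)
        parent = np.full(total, -1, dtype=int)
        heights = np.zeros(total, dtype=float)
        for nd in nodes:
            i = index[id(nd)]
            d = nd.root_distance if nd.root_distance is not None else 0.0
            heights[i] = max(max_d - d, 0.0)
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
        heights[:len(leaves)] = 0.0
        labels = [nd.taxon.label if nd.taxon else f"S{i + 1:03d}" for i, nd in enumerate(leaves)]
        return cls(parent=parent, heights=heights, labels=labels)


@dataclass
class SubstitutionModel:
    """HKY+I: transition/transversion ratio kappa, base frequencies, invariant fraction."""

    kappa: float = 10.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    p_inv: float = 0.5

    def __post_init__(self) -> None:
        f = np.asarray(self.base_freqs, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must be positive and sum to 1")
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must be in [0, 1)")

    def rate_matrix(self) -> np.ndarray:
        """HKY rate matrix scaled to one expected substitution per unit time."""
        f = np.asarray(self.base_freqs, dtype=float)
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                transition = {i, j} in ({0, 2}, {1, 3})  # A<->G, C<->T
                q[i, j] = (self.kappa if transition else 1.0) * f[j]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.sum(f * np.diag(q)))
        return q / mu

    def _eigen(self):
        if not hasattr(self, "_eig_cache"):
            f = np.asarray(self.base_freqs, dtype=float)
            d = np.sqrt(f)
            q = self.rate_matrix()
            s = (d[:, None] * q) / d[None, :]  # similar symmetric matrix
            w, v = np.linalg.eigh((s + s.T) / 2.0)
            self._eig_cache = (w, v, d)
        return self._eig_cache

    def transition_probs(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows index the parent state (A, C, G, T)."""
        if t < 0:
            raise ValueError("branch length must be >= 0")
        w, v, d = self._eigen()
        p = (v * np.exp(w * t)) @ v.T
        p = p / d[:, None] * d[None, :]
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)


def simulate_sequences(g: Genealogy, length: int, sub: SubstitutionModel, rng) -> Alignment:
    """Evolve sequences of ``length`` sites down the genealogy under HKY+I.

    Draw order: invariant-site mask, root states, then per node in order of
    decreasing height one categorical draw block per parent base.
    """
    if length < 1:
        raise ValueError("need length >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    freqs = np.asarray(sub.base_freqs, dtype=float)
    invariant = rng.random(length) < sub.p_inv
    n_nodes = len(g.parent)
    states = np.empty((n_nodes, length), dtype=np.int8)
    root = g.root
    states[root] = rng.choice(4, size=length, p=freqs)
    rate = 1.0 / (1.0 - sub.p_inv)
    children = g.children()
    order: list[int] = []
    stack = [root]
    while stack:  # preorder: parents always precede children
        node = stack.pop()
        order.append(node)
        stack.extend(sorted(children[node], reverse=True))
    var_idx = np.where(~invariant)[0]
    for node in order:
        if node == root:
            continue
        par = g.parent[node]
        states[node] = states[par]
        if var_idx.size == 0:
            continue
        bl = (g.heights[par] - g.heights[node]) * rate
        cum = np.cumsum(sub.transition_probs(bl), axis=1)
        cum[:, -1] = 1.0
        parent_states = states[par, var_idx]
        u = rng.random(var_idx.size)
        child = np.empty(var_idx.size, dtype=np.int8)
        for a in range(4):
            mask = parent_states == a
            if mask.any():
                child[mask] = np.searchsorted(cum[a], u[mask], side="right")
        states[node, var_idx] = child
    base_arr = np.frombuffer(BASES.encode(), dtype="S1")
    seqs = [base_arr[states[i]].tobytes().decode() for i in range(g.n_tips)]
    return Alignment(ids=list(g.labels), seqs=seqs)


@dataclass
class LocalityLayout:
    """Named, georeferenced sampling localities with per-locality sample counts."""

    names: list[str]
    lats: list[float]
    lons: list[float]
    counts: list[int]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.lats) == len(self.lons) == len(self.counts)):
            raise ValueError("locality layout fields must have equal length")

    @property
    def n(self) -> int:
        return int(sum(self.counts))


@dataclass
class SimulationConfig:
    n: int
    length: int
    demography: TwoEpochModel
    substitution: SubstitutionModel
    localities: LocalityLayout
    mode: str = "panmictic"  # or "two_deme"
    stem: float = 0.0        # extra divergence joining the two deme roots
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("panmictic", "two_deme"):
            raise ValueError("mode must be 'panmictic' or 'two_deme'")
        if self.localities.n != self.n:
            raise ValueError(
                f"locality counts sum to {self.localities.n}, expected n = {self.n}"
            )

    def to_yaml(self, path) -> None:
        doc = {
            "n": self.n,
            "length": self.length,
            "demography": asdict(self.demography),
            "substitution": {
                "kappa": self.substitution.kappa,
                "base_freqs": list(self.substitution.base_freqs),
                "p_inv": self.substitution.p_inv,
            },
            "localities": asdict(self.localities),
            "mode": self.mode,
            "stem": self.stem,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        sub = doc.get("substitution", {})
        if "base_freqs" in sub:
            sub["base_freqs"] = tuple(sub["base_freqs"])
        return cls(
            n=int(doc["n"]),
            length=int(doc["length"]),
            demography=TwoEpochModel(**doc["demography"]),
            substitution=SubstitutionModel(**sub),
            localities=LocalityLayout(**doc["localities"]),
            mode=doc.get("mode", "panmictic"),
            stem=float(doc.get("stem", 0.0)),
            seed=int(doc.get("seed", 0)),
        )


def _join_genealogies(ga: Genealogy, gb: Genealogy, stem: float) -> Genealogy:
    """Join two genealogies under a common root ``stem`` above the higher root."""
    na, nb = ga.n_tips, gb.n_tips
    n = na + nb
    total = 2 * n - 1

    def remap(g: Genealogy, tip_off: int, int_off: int) -> np.ndarray:
        idx = np.empty(len(g.parent), dtype=int)
        idx[:g.n_tips] = np.arange(g.n_tips) + tip_off
        idx[g.n_tips:] = np.arange(g.n_tips - 1) + int_off
        return idx

    parent = np.full(total, -1, dtype=int)
    heights = np.zeros(total, dtype=float)
    ia = remap(ga, 0, n)
    ib = remap(gb, na, n + (na - 1))
    for g, idx in ((ga, ia), (gb, ib)):
        for i, p in enumerate(g.parent):
            heights[idx[i]] = g.heights[i]
            if p >= 0:
                parent[idx[i]] = idx[p]
    new_root = total - 1
    heights[new_root] = max(ga.root_height, gb.root_height) + stem
    parent[ia[ga.root]] = new_root
    parent[ib[gb.root]] = new_root
    labels = [f"S{i + 1:03d}" for i in range(n)]
    return Genealogy(parent=parent, heights=heights, labels=labels)


def generate_dataset(cfg: SimulationConfig):
    """Simulate (Alignment, SampleMetadata, truth dict) from a config.

    Panmictic mode draws one genealogy and assigns individuals to
    localities uniformly at random (counts respected).  Two-deme mode draws
    two independent genealogies joined by a divergence stem; the first half
    of the locality list forms deme A.  This is a pragmatic structure
    generator for landscape tests, not a structured coalescent.
    """
    rng = np.random.default_rng(cfg.seed)
    loc = cfg.localities
    if cfg.mode == "panmictic":
        g = simulate_genealogy(cfg.n, cfg.demography, rng)
        assignment_pool = np.repeat(np.arange(len(loc.names)), loc.counts)
        assignment = rng.permutation(assignment_pool)
    else:
        half = len(loc.names) // 2
        n_a = int(sum(loc.counts[:half]))
        n_b = cfg.n - n_a
        if n_a < 2 or n_b < 2:
            raise ValueError("two_deme mode needs >= 2 samples per deme")
        ga = simulate_genealogy(n_a, cfg.demography, rng)
        gb = simulate_genealogy(n_b, cfg.demography, rng)
        g = _join_genealogies(ga, gb, cfg.stem)
        pool_a = np.repeat(np.arange(half), loc.counts[:half])
        pool_b = np.repeat(np.arange(half, len(loc.names)), loc.counts[half:])
        assignment = np.concatenate([rng.permutation(pool_a), rng.permutation(pool_b)])
    aln = simulate_sequences(g, cfg.length, cfg.substitution, rng)
    rows = [
        {
            "id": aln.ids[i],
            "locality": loc.names[assignment[i]],
            "lat": loc.lats[assignment[i]],
            "lon": loc.lons[assignment[i]],
        }
        for i in range(cfg.n)
    ]
    meta = SampleMetadata(pd.DataFrame(rows))
    truth = {
        "seed": cfg.seed,
        "mode": cfg.mode,
        "n": cfg.n,
        "length": cfg.length,
        "demography": asdict(cfg.demography),
        "substitution": {
            "kappa": cfg.substitution.kappa,
            "base_freqs": list(cfg.substitution.base_freqs),
            "p_inv": cfg.substitution.p_inv,
        },
        "stem": cfg.stem,
        "genealogy_newick": g.to_newick(),
        "root_height": g.root_height,
    }
    return aln, meta, truth


# Default study-scale conditions: 84 haploid control-region sequences of
# 352 sites from 10 localities along the eastern Adriatic coast, recent
# tenfold expansion starting t_trans = 4.6974e-4 substitutions/site ago.
STUDY_DEMOGRAPHY = TwoEpochModel(
    n1=0.01,
    r=math.log(10.0) / 4.6974e-4,  # growth decays N1 onto N0 at t_trans
    n0=0.001,
    t_trans=4.6974e-4,
)

STUDY_LOCALITIES = LocalityLayout(
    names=[
        "Cres", "Losinj", "Rab", "Pag", "Silba",
        "Ugljan", "Dugi Otok", "Murter", "Rogoznica", "Hvar",
    ],
    lats=[44.96, 44.53, 44.76, 44.44, 44.38, 44.07, 43.95, 43.80, 43.53, 43.17],
    lons=[14.41, 14.47, 14.76, 15.05, 14.70, 15.22, 15.06, 15.59, 15.97, 16.44],
    counts=[12, 10, 9, 9, 8, 8, 8, 7, 7, 6],
)


def study_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default simulated study: n = 84, L = 352, 10 Adriatic localities."""
    kwargs = dict(
        n=84,
        length=352,
        demography=STUDY_DEMOGRAPHY,
        substitution=SubstitutionModel(),
        localities=STUDY_LOCALITIES,
        mode="panmictic",
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
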