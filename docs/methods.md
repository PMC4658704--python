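# Methods

## Scope and units

`popexpand` reconstructs the demographic history of a single
non-recombining locus — the motivating system is a 352-bp fragment of the
mitochondrial control region sampled from 84 black-faced blennies
(*Tripterygion delaisi*) at 10 localities in the north-eastern Adriatic —
and converts the inferred onset of population growth into a
substitution-rate estimate ("expansion dating").

Everything runs in mutation-scaled units: time is measured in expected
substitutions per site, and population size is the female effective size
multiplied by the per-site mutation rate (fNeμ).  No absolute years enter
simulation or inference; only the final dating step divides a scaled time
by a calibration age in years.

## The two-epoch demography

Looking backwards from the present (t = 0):

    N(t) = N1 · exp(−r t)   for 0 ≤ t < t_trans     (recent exponential growth)
    N(t) = N0               for t ≥ t_trans          (ancient constant size)

with four free parameters: present scaled size `N1`, intrinsic growth
rate `r` (per scaled-time unit), ancient scaled size `N0`, and the
transition time `t_trans`.  `N0` and `N1` are independent — no continuity
is imposed at the transition.  The coalescent intensity
Λ(a, b) = ∫ dt / N(t) has a closed form in each epoch
((e^{rb} − e^{ra})/(r N1) during growth, Δt/N0 in the constant epoch),
evaluated with `expm1`/`log1p` so that small `r` does not lose precision;
the r → 0 limit is taken explicitly.  Both the simulator and the
likelihood are built on this one function, and it is checked against
adaptive quadrature in the tests.

## Synthetic-data generator

Genealogies are drawn by the standard time-rescaled coalescent: with k
lineages, u ~ Exp(1) and the next coalescence at the time solving
C(k,2)·Λ(t_now, t) = u (closed-form inversion per epoch), merging a
uniformly chosen pair.  Sequences evolve under HKY+I down the genealogy:
a fraction `p_inv` of sites is flagged invariant, root states come from
the stationary base frequencies, and each branch applies the HKY
transition matrix P(t) obtained by symmetric eigendecomposition of the
rate matrix (scaled to one expected substitution per unit time at
stationarity).

Rate convention for +I: branch lengths are expected substitutions per
site averaged over *all* sites, so variable sites evolve at rate
1/(1 − p_inv).  Consequently E[π] = 2N independently of `p_inv` — the
convention under which +I likelihood programs interpret branch lengths —
and the calibration tests assert exactly this.

Default study conditions (the `study_config` generator): n = 84 sequences
of L = 352 sites at 10 georeferenced Adriatic localities (sample sizes
6–12 per locality, totalling 84); truth demography N1 = 0.01, N0 = 0.001,
t_trans = 4.6974 × 10⁻⁴, r = ln(10)/t_trans (so the growth epoch decays
N1 onto N0 at the transition, matching a skyline that bends from a long
constant plateau into recent tenfold growth); substitution model
kappa = 10, uniform base frequencies, p_inv = 0.5.  The fitted kappa and
p_inv of the original data were not published; these are plausible
control-region values, set once, and are configuration defaults rather
than estimates.  A `two_deme` mode joins two independent genealogies by a
divergence stem and maps the demes onto locality groups; it is a
pragmatic structure generator for landscape tests, not a structured
coalescent (no migration).

What the generator does not emulate: recombination (none in mtDNA, so
harmless), rate heterogeneity beyond +I, selection, geographically
structured coalescence within a deme, sequencing error/ambiguity codes.
Passing tests therefore demonstrate the statistical machinery is
calibrated under the stated model, not that real control-region data meet
that model.

All randomness flows through one `numpy.random.Generator` (PCG64) per
dataset; draws are consumed in a documented order (invariant mask, root
states, then per-branch categorical draws in preorder), so outputs are
bit-reproducible for a given seed and numpy version.

## Summary statistics

Haplotype diversity Hd = n/(n−1)(1 − Σ pᵢ²); nucleotide diversity
π = k̄/L with k̄ the mean pairwise raw difference under pairwise deletion
of N/−; S counts columns with ≥ 2 resolved bases.  Tajima's D uses the
1989 constants verbatim.  Fu's Fs evaluates the Ewens sampling formula
tail S′ = P(K ≥ k_obs) with θ = k̄: unsigned Stirling numbers of the
first kind are built once per n by the exact big-integer recurrence and
combined in log space with `lgamma` for the rising factorial, which is
stable to several hundred sequences; Fs = ln S′ − ln(1 − S′).  An exact
rational-arithmetic oracle validates small cases.

Significance is empirical and lower-tailed: `neutrality_pvalue` simulates
constant-size neutral datasets with the scaled size set so E[k̄] = θ
(N = θ/2L), recomputes the statistic, and reports the fraction of
replicates ≤ observed, together with the replicate count and seed.  The
historical significance machinery of desktop programs is unspecified, so
only stochastic reproduction is attempted.

## Statistical-parsimony network

Exact TCS internals are out of scope; the connection limit uses a
documented per-step multiple-hit model: for a candidate distance of j
steps, the observed proportion p = j/L is Jukes–Cantor-corrected to an
expected per-site hit count λ, superimposed change is assessed as
P(≥2 hits | ≥1 hit) under Poisson(λ), and the limit is the largest j with
(1 − P_multi)^j ≥ 0.95 (computed in log space; search capped at 3L;
`--max-steps` overrides).  Construction is agglomerative over haplotype
pairs in order of increasing raw difference, preferring high-frequency
haplotypes within ties (the frequency criterion of ancestral likelihood)
and lexicographic ids thereafter, inserting difference−1 inferred
intermediates, and never joining pairs beyond the limit.  The default
pass creates no homoplasy loops.  The star score — maximum node degree
over the edge count of its component — quantifies the star-likeness that
indicates recent expansion (1 for a perfect star).

## Genetic landscape interpolation

Localities are triangulated (Delaunay, via Qhull on lon/lat); each edge
carries the mean pairwise genetic distance between the individuals of its
endpoint localities (raw differences by default) and the great-circle
distance in km (the study area spans ~2° of latitude, so planar degrees
would distort; a `planar` flag restores the original tool's convention).
Genetic distance is regressed on geographic distance by OLS — recommended
when connected localities differ strongly in separation — and the
residuals, attached at great-circle edge midpoints, are interpolated by
inverse-distance weighting (weights 1/dᵅ, default α = 1) onto a
0.05° × 0.05° grid anchored at the minimum lat/lon, masked to the convex
hull of the localities.  No coastline masking is attempted.  Surfaces at
α = 0.3 and α = 3 are rank-correlated ≥ 0.8 on simulated data, matching
the reported insensitivity to the weighting parameter.

## Fixed-genealogy Bayesian inference

The central approximation: instead of jointly sampling genealogies and
parameters, inference conditions on one clock-compatible genealogy
(UPGMA on p-distances; node height = merge distance / 2).  Posteriors on
real data are therefore too narrow (genealogical uncertainty is ignored)
and node heights inherit finite-site quantisation: a p-distance is a
multiple of 1/L, so UPGMA piles nodes onto tied heights — including
height 0 for identical sequences, where the coalescent density is
degenerate (the likelihood grows without bound as N1 → 0, t_trans → 0).
`upgma_genealogy(..., quantum=1/L)` therefore spreads each group of tied
heights evenly across the unresolved half-quantum above the observed
value, in merge order so parents stay above children; the pipeline uses
this whenever a UPGMA tree feeds the coalescent likelihood.  Even so,
reconstructed transition times overshoot: in the worked simulated
analysis the UPGMA-based posterior mean of t_trans is ~3× the truth while
the generating-genealogy posterior brackets it.  The calibration suite
accordingly conditions on the generating genealogy — it validates the
likelihood, sampler and dating arithmetic, with genealogy-reconstruction
bias quantified separately and openly.

Sampling is random-walk Metropolis–Hastings on prior × likelihood^β:
multiplicative log-normal moves (sd 0.3, Hastings factor x′/x) for sizes,
reflected uniform windows (10% of the prior width) for `r` and `t_trans`;
one sweep over all parameters per iteration; first 25% of sampled states
discarded.  Priors follow the original analysis in form — truncated 1/x
on sizes, uniform on `r` and `t_trans` — with bounds sized from the data
as that analysis did ("skyline HPDs as guideline"): by default sizes on
the skyline HPD envelope widened ×3, `t_trans` supported up to the root
height, and `r` capped at min(3 ln(hi/lo), 15)/root.  The r cap matters
twice: it keeps the prior's worst-case growth-epoch intensity (~e^{r·t})
finite enough for path sampling to integrate, and it keeps the uniform
prior from dominating weakly informed posteriors.  Default chain settings
scale the original run length proportionally to desk size (200 000
iterations, thinning 100, burn-in 25%, target ESS > 200).

The Bayesian skyline groups the n−1 coalescent intervals into m
contiguous groups (default 10) with near-equal event counts,
piecewise-constant sizes, a 1/x prior on the first group and an
exponential smoothing prior chaining each group's size to its
predecessor's; output is the posterior median and 95% HPD on a regular
time grid.

ESS uses N/(1 + 2Σρ_k) with the autocorrelation sum truncated at the
first non-positive lag; a chain whose lag-1 autocorrelation is already
negative gets the antithetic credit 1 + 2ρ₁ (floored at 1/N), so
super-efficient alternating chains report ESS > N.  HPD intervals are the
shortest contiguous window containing ⌈mass·N⌉ sorted samples.

## Marginal likelihoods and Bayes factors

Path sampling and stepping-stone sampling share one pass over a power
schedule β_k = (k/K)^{1/0.3} (quantiles of Beta(0.3, 1), concentrated
near 0; default K = 100 path steps), each chain warm-started from the
previous step's end state with 10% per-step burn-in.  PS integrates the
per-step mean log-likelihood over β by the trapezoid rule; SS telescopes
log-sum-exp estimates of E_{β_k}[L^{β_{k+1}−β_k}] from the same samples.
Both are validated against the closed-form marginal likelihood of the
constant-size model under a truncated 1/x prior (a ratio of incomplete
gamma functions), agreeing to well under 0.2 nats at K = 32 with 20 000
iterations per step.  PS is the fragile one: with a diffuse uniform
growth-rate prior its β ≈ 0 integrand is dominated by astronomically
negative likelihood tails — hence the r cap above and the dense schedule.
Bayes factors are reported as 2 ln BF with the conventional
interpretation bands attached as annotation only (> 6 strong).

## Expansion dating

Given posterior draws of `t_trans` and a calibration age c in years,
μ = t_trans/c per site per year, reported as % per site per MY (×10⁸).
For the post-glacial window — sea-level rise at ~18 ka BP to Adriatic
surface-water warming at ~13 ka BP — rates are computed at both
endpoints and combined into the envelope [HPD lower at 18 ka, HPD upper
at 13 ka].  The published interval's construction was not fully specified,
so both per-endpoint HPDs and the envelope are always reported; c is
treated as exact (no prior on the calibration age).

## Problem sizes in the shipped checks

The calibration suite runs at the study scale where it matters and desk
scale elsewhere: 50 recovery replicates (n = 84, L = 352; 20 000 MCMC
iterations each), 500 constant-size null replicates for Tajima's D,
150 + 150 growth/constant replicates for Fs, 2000 pairwise-TMRCA draws,
1000 diversity-calibration replicates (n = 20, L = 1000), K = 32 with
20 000 iterations per step for the marginal-likelihood oracle, 20
two-deme landscape replicates.  The numbered analysis drivers use 60 000
iterations for the demographic fits and K = 100 for model comparison.

## Known limitations

* Fixed-genealogy conditioning understates real-data uncertainty and
  biases UPGMA-based transition times upward; treat pipeline posteriors
  on real data as approximate and prefer the reported calibrations for
  method validation.
* The connection limit is a documented approximation, not TCS parity.
* The skyline smoothing prior and group count are this package's
  choices; the original tool's internals differ in unpublished details.
* Ambiguity handling (pairwise deletion; string-identity collapsing) may
  differ from desktop programs' internals on data containing many Ns.
* The two-deme generator is not a structured coalescent; between-deme
  distances are driven by the stem length only.
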