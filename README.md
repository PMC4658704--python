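# popexpand

Phylogeographic and demographic analysis of single-locus (mitochondrial)
alignments, built around **expansion dating**: inferring the onset of a
recent population expansion in mutation-scaled time and converting it
into a substitution-rate estimate by anchoring it to a dated
environmental event.

The motivating system is the black-faced blenny *Tripterygion delaisi*
in the Adriatic Sea: 84 control-region sequences (352 bp) from 10
Croatian localities show the classic signatures of post-glacial
expansion — negative Tajima's D and Fu's Fs, a star-shaped haplotype
network, a Bayesian skyline bending from a long constant plateau into
recent growth.  Equating the growth onset with the post-glacial window
(sea-level rise ~18 ka BP to surface-water warming ~13 ka BP) turns the
transition-time posterior into a control-region rate, μ = t_trans/c.

## What is in the box

* `popexpand.seqio` — FASTA alignments, metadata, haplotype collapsing,
  raw / p-distance / TN93 pairwise distances (pairwise deletion).
* `popexpand.sumstats` — Hd, π, S, k̄; Tajima's D; Fu's Fs via exact
  big-integer Stirling numbers in log space; coalescent-simulation
  p-values.
* `popexpand.network` — TCS-style statistical-parsimony haplotype
  network with a 95% connection limit and a star score.
* `popexpand.landscape` — genetic landscape shape interpolation:
  Delaunay connectivity, residuals from genetic-on-geographic
  regression, inverse-distance-weighted surface (0.05° grid, α = 1).
* `popexpand.coalsim` — synthetic-data generator: time-rescaled
  coalescent under a two-epoch demography
  (`N(t) = N1·e^{−rt}` for `t < t_trans`, else `N0`; all quantities in
  substitutions/site, sizes are fNeμ), HKY+I sequence evolution,
  georeferenced locality assignment.
* `popexpand.demography` — fixed-genealogy Bayesian inference: UPGMA
  genealogy, exact two-epoch coalescent likelihood,
  Metropolis–Hastings with 1/x priors on sizes and uniform priors on
  `r` and `t_trans`, Bayesian skyline, ESS and HPD diagnostics.
* `popexpand.model_selection` — path-sampling and stepping-stone
  marginal likelihoods over Beta(0.3,1)-spaced power posteriors;
  2 ln BF model comparison.
* `popexpand.dating` — `μ = t_trans/c` calibration, per-endpoint HPDs
  and the envelope over a calibration window.
* `popexpand.pipeline` / `popexpand.cli` — end-to-end orchestration
  (`popexpand pipeline --config cfg.yml`) with a manifest recording
  inputs, parameters and per-stage seeds.

The `analysis/` directory holds numbered drivers that run the whole
chain on a simulated study-scale dataset and write their tables under
`results/`.

## Worked example

```bash
python analysis/01_simulate_dataset.py
python analysis/02_summary_statistics.py
python analysis/05_demographic_inference.py
python analysis/07_expansion_dating.py
```

prints, for the bundled seed:

```
simulated 84 sequences x 352 sites at 10 localities -> results/simulated_study
distinct haplotypes: 9; root height of the generating genealogy: 0.00168 subs/site

Tajima's D = -0.5934 (p = 0.3233), Fu's Fs = -2.3544 (p = 0.1153)

t_trans posterior mean: UPGMA 0.00138, generating genealogy 0.00064, truth 0.00047

generating_genealogy: mean rate 3.58-4.96 %/site/MY, envelope [1.61, 10.83]
upgma_genealogy: mean rate 7.65-10.60 %/site/MY, envelope [5.40, 15.10]
```

Reading this: the dataset was simulated with a true transition time of
4.6974 × 10⁻⁴ substitutions/site.  Conditioning on the generating
genealogy, the posterior brackets the truth and the calibrated rate
window (13–18 ka) spans the generating rate (~3.0 %/site/MY).  The
UPGMA-reconstructed genealogy overshoots the transition time — the
documented cost of fixing an estimated genealogy — which is why the
calibration studies condition on the generating tree (see
`docs/methods.md`).  As a pure-arithmetic anchor, a transition time of
4.6974 × 10⁻⁴ maps to 2.61 %/site/MY at the 18 ka calibration and
3.61 %/site/MY at 13 ka:

```python
>>> from popexpand.dating import calibrate_rate
>>> round(calibrate_rate(4.6974e-4, 18_000).mean, 2), round(calibrate_rate(4.6974e-4, 13_000).mean, 2)
(2.61, 3.61)
```

`analysis/06_model_selection.py` compares the two-epoch and
constant-size demographies on the same genealogy; on the growth-simulated
dataset both estimators agree and favour the two-epoch model
(2 ln BF ≈ 75, "very strong").

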