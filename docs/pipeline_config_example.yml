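# Full annotated pipeline configuration emulating the study conditions:
# 84 sequences, 352 sites, 10 Adriatic localities.  Run with
#   popexpand pipeline --config docs/pipeline_config_example.yml
#
# Exactly one of `fasta` (+ optional `metadata`) or `simulation` must be
# set.  For real data, replace the simulation block with
#   fasta: data/alignment.fasta        # pre-aligned, equal lengths
#   metadata: data/metadata.csv        # header: id,locality,lat,lon

outdir: results/pipeline_run
seed: 1                                # global seed; each stage derives its
                                       # own via sha256(stage-name || seed)

simulation:
  n: 84                                # haploid sequences
  length: 352                          # alignment columns
  demography:                          # two-epoch truth, subs/site units
    n1: 0.01                           # present scaled size fNe-mu
    r: 4901.828869148989               # growth rate; ln(10)/t_trans here
    n0: 0.001                          # ancient scaled size
    t_trans: 0.00046974                # transition time before present
  substitution:
    kappa: 10.0                        # HKY transition/transversion ratio
    base_freqs: [0.25, 0.25, 0.25, 0.25]
    p_inv: 0.5                         # invariant-site fraction (+I)
  localities:                          # 10 sampling sites, counts sum to n
    names: [Cres, Losinj, Rab, Pag, Silba, Ugljan, Dugi Otok, Murter, Rogoznica, Hvar]
    lats: [44.96, 44.53, 44.76, 44.44, 44.38, 44.07, 43.95, 43.80, 43.53, 43.17]
    lons: [14.41, 14.47, 14.76, 15.05, 14.70, 15.22, 15.06, 15.59, 15.97, 16.44]
    counts: [12, 10, 9, 9, 8, 8, 8, 7, 7, 6]
  mode: panmictic                      # or two_deme (with `stem`)

stages:                                # every stage defaults to on
  neutrality: true
  network: true
  landscape: true
  skyline: true
  fit: true
  model_selection: true
  dating: true

params:
  neutrality:
    reps: 1000                         # null-coalescent replicates for p-values
  network:
    # max_steps: 8                     # override the 95% connection limit
  landscape:
    cell: 0.05                         # grid cell, degrees
    alpha: 1.0                         # IDW weighting exponent
  skyline:
    m: 10                              # interval groups
    iterations: 50000
  fit:
    iterations: 200000                 # MCMC length per model
    thin: 100
  model_selection:
    steps: 100                         # power-posterior path steps
    iterations_per_step: 4000
  dating:
    c_low: 13000                       # surface-water warming, yr BP
    c_high: 18000                      # post-glacial sea-level rise, yr BP
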