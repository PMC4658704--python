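"""End-to-end pipeline: from an alignment (real or simulated) to a dated rate.

Stage order: haplotype collapsing -> diversity / neutrality tests ->
statistical-parsimony network -> genetic landscape (when coordinates are
available) -> UPGMA genealogy -> Bayesian skyline -> constant and
two-epoch fits -> path-sampling / stepping-stone model comparison ->
expansion dating.  Every stage writes its artefact into the output
directory and is logged in a manifest (inputs, parameters, seeds,
package version) sufficient to reproduce the run.

All randomness flows from one global seed; each stage derives its own
seed as sha256(stage-name || global seed) mod 2^31, so stages can be
re-run independently yet reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path


from . import __version__
from . import coalsim, dating, demography, landscape, model_selection, network, seqio, sumstats

log = logging.getLogger("popexpand")

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Exactly one of (fasta [, metadata]) or simulation must be set."""

    outdir: str | Path
    seed: int = 0
    fasta: str | Path | None = None
    metadata: str | Path | None = None
    simulation: coalsim.SimulationConfig | None = None
    stages: dict = field(default_factory=dict)   # stage name -> bool toggle
    params: dict = field(default_factory=dict)   # per-stage parameter overrides

    def __post_init__(self) -> None:
        if (self.fasta is None) == (self.simulation is None):
            raise ValueError("set exactly one of an input FASTA or a simulation config")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        sim = None
        if "simulation" in doc and doc["simulation"]:
            simdoc = doc["simulation"]
            sub = simdoc.get("substitution", {})
            if "base_freqs" in sub:
                sub["base_freqs"] = tuple(sub["base_freqs"])
            sim = coalsim.SimulationConfig(
                n=int(simdoc["n"]),
                length=int(simdoc["length"]),
                demography=coalsim.TwoEpochModel(**simdoc["demography"]),
                substitution=coalsim.SubstitutionModel(**sub),
                localities=coalsim.LocalityLayout(**simdoc["localities"]),
                mode=simdoc.get("mode", "panmictic"),
                stem=float(simdoc.get("stem", 0.0)),
                seed=int(simdoc.get("seed", doc.get("seed", 0))),
            )
        return cls(
            outdir=doc["outdir"],
            seed=int(doc.get("seed", 0)),
            fasta=doc.get("fasta"),
            metadata=doc.get("metadata"),
            simulation=sim,
            stages=doc.get("stages", {}) or {},
            params=doc.get("params", {}) or {},
        )


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis chain; returns the manifest dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "inputs": {
            "fasta": str(cfg.fasta) if cfg.fasta else None,
            "metadata": str(cfg.metadata) if cfg.metadata else None,
            "simulated": cfg.simulation is not None,
        },
    }
    p = cfg.params
    current = {"stage": "input"}

    def record(stage: str, started: float, **info) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - started, 3), **info}
        _write_json(out / "manifest.json", manifest)
        log.info("stage %-14s done in %.2fs", stage, time.time() - started)

    try:
        # --- input -----------------------------------------------------
        t0 = time.time()
        if cfg.simulation is not None:
            sim = cfg.simulation
            aln, meta, truth = coalsim.generate_dataset(sim)
            seqio.write_alignment(aln, out / "alignment.fasta")
            meta.table.to_csv(out / "metadata.csv", index=False)
            _write_json(out / "truth.json", truth)
            record("input", t0, n=aln.n, length=aln.length, simulated=True,
                   sim_seed=sim.seed)
        else:
            aln = seqio.read_alignment(cfg.fasta)
            meta = seqio.read_metadata(cfg.metadata) if cfg.metadata else None
            record("input", t0, n=aln.n, length=aln.length, simulated=False)

        # --- haplotypes + diversity + neutrality ----------------------
        current["stage"] = "sumstats"
        t0 = time.time()
        ht = seqio.collapse_haplotypes(aln, meta)
        ht.to_frame().to_csv(out / "haplotypes.csv", index=False)
        div = sumstats.diversity(aln)
        rows = [
            {"stat": "Hd", "value": div.hd}, {"stat": "pi", "value": div.pi},
            {"stat": "S", "value": div.s}, {"stat": "k_bar", "value": div.k_bar},
        ]
        if cfg.enabled("neutrality"):
            reps = int(p.get("neutrality", {}).get("reps", 200))
            sseed = stage_seed(cfg.seed, "neutrality")
            d_res = sumstats.tajimas_d(aln)
            fs_res = sumstats.fus_fs(aln)
            d_p = sumstats.neutrality_pvalue(
                "D", d_res.value, aln.n, div.k_bar, reps=reps, seed=sseed, length=aln.length
            )
            fs_p = sumstats.neutrality_pvalue(
                "FS", fs_res.value, aln.n, div.k_bar, reps=reps, seed=sseed + 1,
                length=aln.length
            )
            for res in (d_p, fs_p):
                rows.append({
                    "stat": res.statistic, "value": res.value, "p": res.p_value,
                    "method": res.method, "reps": res.n_replicates, "seed": res.seed,
                })
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "sumstats.csv", index=False)
        record("sumstats", t0, haplotypes=ht.k)

        # --- parsimony network ----------------------------------------
        if cfg.enabled("network"):
            current["stage"] = "network"
            t0 = time.time()
            reps_aln = ht.representative_alignment()
            d_raw = seqio.pairwise_distance(reps_aln, "raw_differences")
            limit = int(p.get("network", {}).get(
                "max_steps", network.connection_limit(aln.length)
            ))
            net = network.build_network(ht, d_raw, limit)
            edges, nodes = network.network_tables(net)
            edges.to_csv(out / "network_edges.csv", index=False)
            nodes.to_csv(out / "network_nodes.csv", index=False)
            record("network", t0, limit=limit, star_score=network.star_score(net))

        # --- landscape -------------------------------------------------
        if cfg.enabled("landscape") and meta is not None:
            current["stage"] = "landscape"
            t0 = time.time()
            d_ind = seqio.pairwise_distance(aln, "raw_differences")
            conn = landscape.build_connectivity(meta, d_ind)
            edges = landscape.residual_distances(conn)
            edges.to_csv(out / "landscape_edges.csv", index=False)
            lp = p.get("landscape", {})
            surface = landscape.interpolate_surface(
                edges["mid_lat"], edges["mid_lon"], edges["residual"],
                cell=float(lp.get("cell", 0.05)), alpha=float(lp.get("alpha", 1.0)),
                hull_points=conn.localities[["lat", "lon"]].to_numpy(),
            )
            surface.to_frame().to_csv(out / "landscape_surface.csv", index=False)
            surface.to_ascii_grid(out / "landscape_surface.asc")
            record("landscape", t0, edges=len(edges))

        # --- genealogy -------------------------------------------------
        current["stage"] = "genealogy"
        t0 = time.time()
        d_p = seqio.pairwise_distance(aln, "p_distance")
        gen = demography.upgma_genealogy(d_p, quantum=1.0 / aln.length)
        (out / "genealogy.nwk").write_text(gen.to_newick() + "\n")
        record("genealogy", t0, root_height=gen.root_height)

        # --- skyline ---------------------------------------------------
        sky = None
        if cfg.enabled("skyline"):
            current["stage"] = "skyline"
            t0 = time.time()
            sp = p.get("skyline", {})
            sky, sky_trace = demography.bayesian_skyline(
                gen,
                m=int(sp.get("m", 10)),
                iterations=int(sp.get("iterations", 50_000)),
                thin=int(sp.get("thin", 50)),
                seed=stage_seed(cfg.seed, "skyline"),
            )
            sky.to_frame().to_csv(out / "skyline.csv", index=False)
            record("skyline", t0, m=sky.m)

        # --- demographic fits ------------------------------------------
        fp = p.get("fit", {})
        iterations = int(fp.get("iterations", 200_000))
        thin = int(fp.get("thin", 100))
        priors2 = fp.get("priors") or demography.default_priors(
            "two_epoch", sky, root_height=gen.root_height
        )
        priors1 = fp.get("priors_constant") or {"N": priors2["N0"]}
        trace2 = None
        if cfg.enabled("fit"):
            current["stage"] = "fit"
            t0 = time.time()
            trace2 = demography.mh_sample(
                gen, "two_epoch", priors2, iterations=iterations, thin=thin,
                seed=stage_seed(cfg.seed, "fit_two_epoch"),
            )
            trace2.to_frame().to_csv(out / "trace_two_epoch.tsv", sep="\t", index=False)
            trace1 = demography.mh_sample(
                gen, "constant", priors1, iterations=iterations, thin=thin,
                seed=stage_seed(cfg.seed, "fit_constant"),
            )
            trace1.to_frame().to_csv(out / "trace_constant.tsv", sep="\t", index=False)
            summary = {}
            for trace, label in ((trace2, "two_epoch"), (trace1, "constant")):
                for nm in trace.names:
                    col = trace[nm]
                    lo, hi = demography.hpd(col, 0.95)
                    summary[f"{label}.{nm}"] = {
                        "mean": float(col.mean()), "hpd_lower": lo, "hpd_upper": hi,
                        "ess": float(demography.ess(col)),
                    }
            _write_json(out / "fit_summary.json", summary)
            record("fit", t0, iterations=iterations)

        # --- model selection -------------------------------------------
        if cfg.enabled("model_selection"):
            current["stage"] = "model_selection"
            t0 = time.time()
            mp = p.get("model_selection", {})
            schedule = model_selection.power_schedule(int(mp.get("steps", 100)))
            its = int(mp.get("iterations_per_step", 4000))
            res = {}
            for kind, priors in (("two_epoch", priors2), ("constant", priors1)):
                ps, ss = model_selection.estimate_marginal(
                    gen, kind, priors, schedule=schedule, iterations_per_step=its,
                    thin=int(mp.get("thin", 10)),
                    seed=stage_seed(cfg.seed, f"marginal_{kind}"),
                )
                ps.to_frame().to_csv(out / f"power_posterior_{kind}.csv", index=False)
                res[kind] = {"PS": ps.log_ml, "SS": ss.log_ml}
            bf = {
                meth: model_selection.bayes_factor(
                    res["two_epoch"][meth], res["constant"][meth]
                )
                for meth in ("PS", "SS")
            }
            _write_json(out / "model_selection.json", {"log_ml": res, "two_ln_bf": bf})
            record("model_selection", t0, **{m: bf[m]["two_ln_bf"] for m in bf})

        # --- expansion dating ------------------------------------------
        if cfg.enabled("dating") and trace2 is not None:
            current["stage"] = "dating"
            t0 = time.time()
            dp = p.get("dating", {})
            draws = trace2["t_trans"]
            draws = draws[draws > 0]
            hi_est, lo_est, env = dating.rate_window(
                draws, c_low=float(dp.get("c_low", 13_000)),
                c_high=float(dp.get("c_high", 18_000)),
            )
            report = {
                "t_trans_mean": float(trace2["t_trans"].mean()),
                "at_c_high": vars(hi_est),
                "at_c_low": vars(lo_est),
                "combined_interval_pct_per_my": list(env),
            }
            _write_json(out / "expansion_dating.json", report)
            record("dating", t0, mean_rate_slow=hi_est.mean, mean_rate_fast=lo_est.mean)
    except Exception as err:  # partial manifest for post-mortem, then re-raise
        manifest["failed_stage"] = current["stage"]
        manifest["error"] = f"{type(err).__name__}: {err}"
        _write_json(out / "manifest.json", manifest)
        raise RuntimeError(f"pipeline stage '{current['stage']}' failed: {err}") from err

    _write_json(out / "manifest.json", manifest)
    return manifest
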