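"""End-to-end orchestration of the analysis chain.

Stage order mirrors a typical dominant-marker landscape-genetics
workflow: simulate or load data -> diversity -> cluster labels ->
AMOVA -> distance matrices -> mixed model with bootstrap tests ->
matrix regressions (genetic and phenotypic) -> selection scans ->
consensus -> locus-trait correlations.  Each stage writes its artifact
under the output directory; a combined JSON report collects the
summaries.  Reruns with ``resume=True`` skip stages whose artifacts
already exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from .amova import amova, pairwise_phist
from .clusters import assign_clusters
from .datatypes import BandMatrix
from .diversity import percent_polymorphic, unbiased_heterozygosity, upgma_with_bootstrap
from .estimators import band_frequencies, genotyping_error_rate
from .landscape import (
    build_distance_set, environment_pca, fit_distance_lmm,
    parametric_bootstrap_lrt,
)
from .matrixreg import cluster_distance_matrix, forward_stepwise, mrm, partial_mantel
from .scans import (
    ScanConfig, bayescan_scan, consensus_outliers, dominant_fst, fdist_scan,
    locus_trait_correlation, sam_scan,
)
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("aflpscape")

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

ENV_VARIABLES = [
    "altitude", "mean_temp", "rainfall", "slope", "aspect",
    "EC", "pH", "CaCO3", "HMC", "SSA", "LOI", "stoniness",
]
CLIMATE_VARIABLES = ["altitude", "mean_temp", "rainfall", "slope", "aspect"]
EDAPHIC_VARIABLES = ["EC", "pH", "CaCO3", "HMC", "SSA", "LOI", "stoniness"]


@dataclasses.dataclass
class PipelineConfig:
    # either simulate (a SimulationConfig) or explicit input paths
    simulate: SimulationConfig | None = None
    band_matrix_path: str | None = None
    site_table_path: str | None = None
    phenotype_paths: dict[str, str] = dataclasses.field(default_factory=dict)
    cluster_labels_path: str | None = None
    # stage toggles
    run_diversity: bool = True
    run_tree: bool = True
    run_amova: bool = True
    run_lmm: bool = True
    run_mrm: bool = True
    run_scans: bool = True
    run_trait_correlation: bool = True
    # per-stage parameters
    n_perm: int = 999
    bootstrap_B: int = 199
    tree_bootstrap: int = 500
    k_axes: int = 4
    p_enter: float = 0.05
    scan: ScanConfig = dataclasses.field(
        default_factory=lambda: ScanConfig(n_sim=10_000, chain_length=20_000, burn_in=5_000)
    )
    seed: int = 0
    outdir: str = "aflpscape_out"


def load_pipeline_config(path) -> PipelineConfig:
    """Read a flat YAML config; the ``simulate`` and ``scan`` blocks map
    onto their dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "simulate" in raw and raw["simulate"] is not None:
        sim = raw["simulate"]
        if isinstance(sim.get("ancestral_freq_prior"), list):
            sim["ancestral_freq_prior"] = tuple(sim["ancestral_freq_prior"])
        raw["simulate"] = SimulationConfig(**sim)
    if "scan" in raw and raw["scan"] is not None:
        raw["scan"] = ScanConfig(**raw["scan"])
    return PipelineConfig(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _write_matrix_csv(mat: np.ndarray, labels: list[str], path: Path) -> None:
    pd.DataFrame(mat, index=labels, columns=labels).to_csv(path)


class _StageRunner:
    def __init__(self, outdir: Path, resume: bool, report: dict):
        self.outdir = outdir
        self.resume = resume
        self.report = report

    def run(self, name: str, artifact: str, fn):
        path = self.outdir / artifact
        marker = self.outdir / f"{name}.done.json"
        if self.resume and marker.exists():
            log.info("stage %s: artifact exists, skipping (resume)", name)
            with open(marker) as fh:
                self.report[name] = json.load(fh)
            return self.report[name]
        t0 = time.time()
        try:
            summary = fn(path)
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        summary = _jsonable(summary or {})
        summary["_runtime_s"] = round(time.time() - t0, 3)
        with open(marker, "w") as fh:
            json.dump(summary, fh, indent=2)
        self.report[name] = summary
        log.info("stage %s done in %.1fs", name, summary["_runtime_s"])
        return summary


def run_pipeline(cfg: PipelineConfig, resume: bool = False) -> dict:
    """Run the configured stages; returns the combined report dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "version": _version()}
    runner = _StageRunner(outdir, resume, report)
    rng = np.random.default_rng(cfg.seed)

    # ---- inputs ------------------------------------------------------
    if cfg.simulate is not None:
        def stage_sim(path):
            ds = simulate_dataset(cfg.simulate)
            aio.write_band_matrix(ds.band_matrix, outdir / "band_matrix.csv")
            aio.write_table(ds.site_table, outdir / "site_table.csv")
            for exp, t in ds.phenotypes.items():
                aio.write_table(t, outdir / f"phenotypes_{exp}.csv")
            aio.write_truth(ds.truth, outdir / "truth.json")
            return {"n_individuals": ds.band_matrix.n_individuals,
                    "n_loci": ds.band_matrix.n_loci,
                    "seed": cfg.simulate.seed}
        runner.run("simulate", "band_matrix.csv", stage_sim)
        m = aio.read_band_matrix(outdir / "band_matrix.csv")
        site = aio.read_table(outdir / "site_table.csv")
        phenos = {
            exp: aio.read_table(outdir / f"phenotypes_{exp}.csv")
            for exp in ("net_house", "common_garden")
        }
        truth = aio.read_truth(outdir / "truth.json")
    else:
        if not cfg.band_matrix_path or not cfg.site_table_path:
            raise ValueError("either a simulate block or input paths are required")
        m = aio.read_band_matrix(cfg.band_matrix_path)
        site = aio.read_table(cfg.site_table_path)
        phenos = {k: aio.read_table(v) for k, v in cfg.phenotype_paths.items()}
        truth = None

    freqs = band_frequencies(m)
    env_vars = [v for v in ENV_VARIABLES if v in site.columns]

    # ---- diversity ---------------------------------------------------
    if cfg.run_diversity:
        def stage_div(path):
            p = percent_polymorphic(freqs)
            uhe = unbiased_heterozygosity(freqs)
            try:
                err = genotyping_error_rate(m)
            except ValueError:
                err = None
            df = pd.DataFrame({
                "population": list(p),
                "percent_polymorphic": [p[k] for k in p],
                "uHe": [uhe[k] for k in p],
            })
            df.to_csv(path, index=False)
            return {"percent_polymorphic": p, "uHe": uhe,
                    "genotyping_error_rate": err}
        runner.run("diversity", "diversity.csv", stage_div)

    # ---- clusters ----------------------------------------------------
    if cfg.cluster_labels_path:
        lab = pd.read_csv(cfg.cluster_labels_path)
        clusters = dict(zip(lab["population"], lab["cluster"]))
        admixed = set(lab.loc[lab.get("admixed", False) == True, "population"]) \
            if "admixed" in lab.columns else set()
        method = "user"
    elif truth is not None:
        clusters = truth["clusters"]
        admixed = set(truth["admixed"])
        method = "truth"
    else:
        def stage_clu(path):
            ca = assign_clusters(freqs, seed=cfg.seed)
            pd.DataFrame({
                "population": list(ca.labels),
                "cluster": [ca.labels[p] for p in ca.labels],
                "admixed": [p in ca.admixed for p in ca.labels],
            }).to_csv(path, index=False)
            return {"K": ca.K, "labels": ca.labels,
                    "admixed": sorted(ca.admixed)}
        s = runner.run("clusters", "clusters.csv", stage_clu)
        clusters, admixed, method = s["labels"], set(s["admixed"]), "surrogate"
    report["cluster_source"] = method

    # ---- tree --------------------------------------------------------
    if cfg.run_tree:
        def stage_tree(path):
            tr = upgma_with_bootstrap(m, B=cfg.tree_bootstrap, seed=cfg.seed + 11)
            path.write_text(tr.newick + "\n")
            return {"newick": tr.newick, "n_bootstrap": tr.n_bootstrap}
        runner.run("tree", "upgma.nwk", stage_tree)

    # ---- amova -------------------------------------------------------
    if cfg.run_amova:
        def stage_amova(path):
            res2 = amova(m, n_perm=cfg.n_perm, seed=cfg.seed + 21)
            res3 = amova(m, groups=clusters, n_perm=cfg.n_perm, seed=cfg.seed + 22)
            out = {
                "two_level": {"percent": res2.percent, "phi": res2.phi,
                              "p": res2.p_values},
                "three_level": {"percent": res3.percent, "phi": res3.phi,
                                "p": res3.p_values},
            }
            path.write_text(json.dumps(_jsonable(out), indent=2))
            return out
        runner.run("amova", "amova.json", stage_amova)

    # ---- distance matrices + LMM ------------------------------------
    phist, pops = pairwise_phist(m)
    pca_all = environment_pca(site, env_vars)
    dset = build_distance_set(
        phist, pops, site, pca_all, clusters, admixed, k_axes=cfg.k_axes
    )
    _write_matrix_csv(dset.genetic, pops, outdir / "dist_genetic.csv")
    _write_matrix_csv(dset.geographic, pops, outdir / "dist_geographic.csv")
    _write_matrix_csv(dset.environmental, pops, outdir / "dist_environmental.csv")

    if cfg.run_lmm:
        def stage_lmm(path):
            rows = []
            base = fit_distance_lmm(dset, fixed=())
            rows.append({"reduced": "-", "added": "cluster categories",
                         "r2": base.r2, "p": None})
            geo = fit_distance_lmm(dset, fixed=("geo",))
            t_geo = parametric_bootstrap_lrt(dset, ("geo",), (), B=cfg.bootstrap_B,
                                             seed=cfg.seed + 31)
            rows.append({"reduced": "cluster", "added": "geographic distance",
                         "r2": geo.r2, "p": t_geo.p_value})
            both = fit_distance_lmm(dset, fixed=("geo", "env"))
            t_env = parametric_bootstrap_lrt(dset, ("geo", "env"), ("geo",),
                                             B=cfg.bootstrap_B, seed=cfg.seed + 32)
            rows.append({"reduced": "cluster + geographic",
                         "added": "environmental distance",
                         "r2": both.r2, "p": t_env.p_value})
            path.write_text(json.dumps(_jsonable(rows), indent=2))
            return {"table": rows}
        runner.run("lmm", "lmm.json", stage_lmm)

    # ---- matrix regression ------------------------------------------
    if cfg.run_mrm:
        def stage_mrm(path):
            out = {}
            preds = {"env": dset.environmental, "geo": dset.geographic}
            res = mrm(dset.genetic, list(preds.values()), list(preds),
                      n_perm=cfg.n_perm, seed=cfg.seed + 41)
            out["genetic"] = {
                "coefficients": dict(zip(["intercept"] + res.predictor_names,
                                         res.coefficients)),
                "r2": res.r2, "p_r2": res.p_r2,
            }
            cdm = cluster_distance_matrix(pops, clusters, admixed)
            for exp, table in phenos.items():
                ptab = table.set_index("population").loc[pops]
                traits = [c for c in ptab.columns
                          if c != "experiment" and np.issubdtype(ptab[c].dtype, np.number)]
                ppca = environment_pca(ptab.reset_index(), traits)
                k = min(cfg.k_axes, ppca.scores.shape[1])
                pd_mat = np.linalg.norm(
                    ppca.scores[:, None, :k] - ppca.scores[None, :, :k], axis=2
                )
                steps, final = forward_stepwise(
                    pd_mat, preds, p_enter=cfg.p_enter,
                    n_perm=cfg.n_perm, seed=cfg.seed + 42,
                )
                res_p = mrm(pd_mat, list(preds.values()), list(preds),
                            n_perm=cfg.n_perm, seed=cfg.seed + 43)
                # climatic vs edaphic partial Mantel, controlling geography+cluster
                partial = {}
                for name, vs in (("climatic", CLIMATE_VARIABLES),
                                 ("edaphic", EDAPHIC_VARIABLES)):
                    use = [v for v in vs if v in site.columns]
                    if len(use) < 2:
                        continue
                    sub_pca = environment_pca(site, use)
                    ks = min(cfg.k_axes, sub_pca.scores.shape[1])
                    dm = np.linalg.norm(
                        sub_pca.scores[:, None, :ks] - sub_pca.scores[None, :, :ks],
                        axis=2,
                    )
                    mt = partial_mantel(
                        pd_mat, dm, [dset.geographic, cdm],
                        ["geo", "cluster"], n_perm=cfg.n_perm,
                        seed=cfg.seed + 44,
                    )
                    partial[name] = {"r": mt.r, "p": mt.p_value}
                out[exp] = {
                    "mrm_r2": res_p.r2, "mrm_p_r2": res_p.p_r2,
                    "coefficients": dict(zip(["intercept"] + res_p.predictor_names,
                                             res_p.coefficients)),
                    "stepwise": steps,
                    "selected": final.predictor_names if final else [],
                    "partial_mantel": partial,
                }
            path.write_text(json.dumps(_jsonable(out), indent=2))
            return out
        runner.run("mrm", "mrm.json", stage_mrm)

    # ---- selection scans --------------------------------------------
    consensus = None
    if cfg.run_scans:
        def stage_scans(path):
            fd = fdist_scan(m, cfg.scan, seed=cfg.seed + 51)
            bs = bayescan_scan(m, cfg.scan, seed=cfg.seed + 52)
            preds = pd.DataFrame({
                "population": list(site["population"]),
                "PC1": pca_all.scores[:, 0],
                "PC2": pca_all.scores[:, 1],
            })
            sam = sam_scan(m, preds, alpha=cfg.scan.sam_alpha,
                           level=cfg.scan.polymorphism_level)
            cons = consensus_outliers({"fdist": fd, "bayescan": bs, "sam": sam})
            fd.to_csv(outdir / "scan_fdist.csv", index=False)
            bs.to_csv(outdir / "scan_bayescan.csv", index=False)
            sam.to_csv(outdir / "scan_sam.csv", index=False)
            cons.to_csv(path, index=False)
            return {
                "mean_fst": fd.attrs["mean_fst"],
                "n_polymorphic": len(fd),
                "sam_models": sam.attrs["n_models"],
                "sam_threshold": sam.attrs["bonferroni_threshold"],
                "candidates": cons.to_dict("records"),
                "percent_detected": cons.attrs["percent_detected"],
            }
        s = runner.run("scans", "scan_consensus.csv", stage_scans)
        consensus = s["candidates"]

    # ---- trait correlation ------------------------------------------
    if cfg.run_trait_correlation and consensus and phenos:
        def stage_corr(path):
            cand = [c["locus"] for c in consensus]
            rep = locus_trait_correlation(freqs, cand, phenos)
            rep.to_csv(path, index=False)
            sig = rep.loc[rep["significant"]] if "significant" in rep else rep.iloc[:0]
            return {"n_tested": len(rep),
                    "significant": sig.to_dict("records")}
        runner.run("trait_correlation", "trait_correlation.csv", stage_corr)

    with open(outdir / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
    return report


def _version() -> str:
    from . import __version__
    return __version__
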