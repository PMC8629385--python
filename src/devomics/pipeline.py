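"""Configuration-driven orchestration of all analysis stages.

A :class:`RunConfig` (loadable from YAML) carries every stage threshold
and the seed; :func:`run_pipeline` executes requested stages in dependency
order on files under the output directory and returns a manifest listing
every file written, the resolved config and its hash.  Identical config +
seed reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cerna, coexpression, differential, popgen, stagemap
from .errors import MissingUpstreamError
from .expression import ExpressionMatrix, PhaseScheme, gene_stats, load_expression, classical_mds
from .simulate import ExprSimConfig, GenoSimConfig, simulate_cerna_layer, simulate_expression, simulate_genotypes

STAGES = ["simulate", "stats", "mds", "de", "phase-specific", "trajectory-de",
          "stage-map", "cerna", "coexpress", "sweep", "ld", "pca", "tree"]

_EXPR_STAGES = {"stats", "mds", "de", "phase-specific", "trajectory-de",
                "stage-map", "coexpress", "cerna"}
_GENO_STAGES = {"sweep", "ld", "pca", "tree"}


@dataclass
class RunConfig:
    """All stage thresholds, input paths and the seed."""

    out_dir: str = "devomics_out"
    seed: int = 1
    # expression simulation
    n_genes: int = 2000
    n_mirnas: int = 90
    lag_steps: int = 2
    frac_lagged: float = 0.6
    noise_sd: float = 0.2
    # genotype simulation
    n_snps: int = 20000
    n_individuals_per_pop: int = 20
    chrom_length: int = 20_000_000
    fst_target: float = 0.2
    sweep_intervals: list = field(default_factory=lambda: [[8_000_000, 8_300_000, "B"]])
    # thresholds
    expressed_threshold: float = 0.1
    rpkm_min: float = 1.0
    z_min: float = 1.5
    cv_min: float = 0.5
    r_cut: float = 0.5
    p_cut: float = 0.05
    rho_min: float = 0.3
    lfc_cut: float = 1.0
    fdr_cut: float = 0.05
    window: int = 50_000
    step: int = 10_000
    min_snps: int = 10
    fst_quantile: float = 0.95
    ratio_tail: float = 0.05
    max_dist: int = 300_000
    bin_bp: int = 100
    k: int = 0              # 0 => choose by figure of merit
    k_range: list = field(default_factory=lambda: [2, 3, 4, 5, 6, 7, 8])
    bootstrap: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)


def _need(path: Path, stage: str, producer: str) -> Path:
    if not path.exists():
        raise MissingUpstreamError(
            f"stage {stage!r} needs {path.name}; run {producer!r} first")
    return path


class _Run:
    def __init__(self, cfg: RunConfig):
        self.cfg = cfg
        self.out = Path(cfg.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict[str, list[str]] = {}

    def emit(self, stage: str, name: str, writer) -> Path:
        path = self.out / name
        writer(path)
        self.manifest.setdefault(stage, []).append(name)
        return path

    # ---- inputs -------------------------------------------------------
    def expr(self, cond: str) -> ExpressionMatrix:
        p = _need(self.out / f"expr_{cond}.tsv", "expression stages", "simulate")
        return load_expression(p, _need(self.out / "timepoints.tsv",
                                        "expression stages", "simulate"))

    def mirna(self, cond: str) -> ExpressionMatrix:
        p = _need(self.out / f"mirna_{cond}.tsv", "cerna", "simulate")
        return load_expression(p, self.out / "timepoints.tsv")

    def geno(self) -> popgen.GenotypeMatrix:
        p = _need(self.out / "genotypes.vcf", "genome stages", "simulate")
        m = self.cfg.n_individuals_per_pop
        pops = {pop: [f"{pop}_{i+1}" for i in range(m)] for pop in ("A", "B")}
        return popgen.load_and_filter(p, pops)

    # ---- stages -------------------------------------------------------
    def stage_simulate(self):
        cfg = self.cfg
        ecfg = ExprSimConfig(n_genes=cfg.n_genes, n_mirnas=cfg.n_mirnas,
                             lag_steps=cfg.lag_steps, frac_lagged=cfg.frac_lagged,
                             noise_sd=cfg.noise_sd, seed=cfg.seed)
        ma, mb, truth = simulate_expression(ecfg)
        mir_a, mir_b, pairs, truth = simulate_cerna_layer(ecfg, ma, mb, truth)
        self.emit("simulate", "timepoints.tsv",
                  lambda p: ma.meta.to_csv(p, sep="\t"))
        for m, name in ((ma, "expr_A.tsv"), (mb, "expr_B.tsv"),
                        (mir_a, "mirna_A.tsv"), (mir_b, "mirna_B.tsv")):
            self.emit("simulate", name, lambda p, m=m: m.to_tsv(p))
        self.emit("simulate", "target_pairs.tsv",
                  lambda p: pairs.to_csv(p, sep="\t", index=False))
        self.emit("simulate", "truth_expression.tsv",
                  lambda p: truth.expression_sidecar().to_csv(p, sep="\t"))
        self.emit("simulate", "truth_targets.tsv",
                  lambda p: truth.target_sidecar().to_csv(p, sep="\t", index=False))
        gcfg = GenoSimConfig(n_snps=cfg.n_snps,
                             n_individuals_per_pop=cfg.n_individuals_per_pop,
                             chrom_length=cfg.chrom_length,
                             fst_target=cfg.fst_target,
                             sweep_intervals=[tuple(x) for x in cfg.sweep_intervals],
                             seed=cfg.seed)
        self.emit("simulate", "genotypes.vcf",
                  lambda p: simulate_genotypes(gcfg, p))
        self.emit("simulate", "truth_sweeps.tsv", lambda p: pd.DataFrame(
            gcfg.sweep_intervals, columns=["start", "end", "population"]
        ).to_csv(p, sep="\t", index=False))

    def stage_stats(self):
        for cond in ("A", "B"):
            m = self.expr(cond)
            st = gene_stats(m, self.cfg.expressed_threshold)
            tab = pd.DataFrame({"mean": st.mean, "sd": st.sd, "cv": st.cv,
                                "expressed": st.expressed.astype(int)})
            self.emit("stats", f"gene_stats_{cond}.tsv",
                      lambda p, t=tab: t.to_csv(p, sep="\t"))

    def stage_mds(self):
        ma, mb = self.expr("A"), self.expr("B")
        coords, evals, distortion = classical_mds([ma, mb])
        coords.index.name = "sample"
        self.emit("mds", "mds_coords.tsv", lambda p: coords.to_csv(p, sep="\t"))

    def stage_de(self):
        ma, mb = self.expr("A"), self.expr("B")
        scheme = PhaseScheme(ma.meta["phase"])
        values = differential.pooled_values(ma, mb)
        frames = []
        for ph in scheme.mapping.unique():
            tps = scheme.timepoints_of(ph)
            res = differential.two_group_de(
                values, [f"A_{t}" for t in tps], [f"B_{t}" for t in tps],
                lfc_cut=self.cfg.lfc_cut, fdr_cut=self.cfg.fdr_cut,
                comparison=f"A_vs_B_{ph}")
            frames.append(res.reset_index())
        de = pd.concat(frames, ignore_index=True)
        self.emit("de", "de_between_conditions.tsv",
                  lambda p: de.to_csv(p, sep="\t", index=False))

    def stage_phase_specific(self):
        ma, mb = self.expr("A"), self.expr("B")
        res = differential.phase_specific_genes(ma, mb, lfc_cut=self.cfg.lfc_cut,
                                                fdr_cut=self.cfg.fdr_cut)
        tab = pd.concat([df.assign(phase=ph).reset_index() for ph, df in res.items()],
                        ignore_index=True)
        self.emit("phase-specific", "phase_specific_genes.tsv",
                  lambda p: tab.to_csv(p, sep="\t", index=False))

    def stage_trajectory_de(self):
        ma, mb = self.expr("A"), self.expr("B")
        res = differential.trajectory_interaction_test(ma, mb, self.cfg.fdr_cut)
        self.emit("trajectory-de", "trajectory_de.tsv",
                  lambda p: res.to_csv(p, sep="\t"))

    def stage_stage_map(self):
        ma, mb = self.expr("A"), self.expr("B")
        universe = stagemap.shared_universe(ma, mb)
        dags_a = stagemap.call_dags(ma, gene_stats(ma), self.cfg.rpkm_min,
                                    self.cfg.z_min, universe)
        dags_b = stagemap.call_dags(mb, gene_stats(mb), self.cfg.rpkm_min,
                                    self.cfg.z_min, universe)
        msm = stagemap.mapping_score_matrix(dags_a, dags_b, len(universe))
        trace = stagemap.maximum_trace(msm)
        summary = stagemap.summarize_mapping(trace)
        self.emit("stage-map", "mapping_scores.tsv",
                  lambda p: msm.score.to_csv(p, sep="\t"))
        self.emit("stage-map", "trace.tsv",
                  lambda p: trace.to_frame(msm.score).to_csv(p, sep="\t", index=False))
        self.emit("stage-map", "lag_summary.tsv",
                  lambda p: summary.to_csv(p, sep="\t", index=False))

    def stage_coexpress(self):
        ma, mb = self.expr("A"), self.expr("B")
        merged = differential.pooled_values(ma, mb)
        mu = merged.mean(axis=1)
        sd = merged.std(axis=1, ddof=1)
        cv = (sd / mu.replace(0, np.nan)).fillna(0.0)
        keep = cv.index[cv > self.cfg.cv_min]
        z = coexpression.zscore_profiles([ma, mb], keep)
        if self.cfg.k:
            k, curve = self.cfg.k, None
        else:
            curve, k = coexpression.figure_of_merit(z, self.cfg.k_range,
                                                    seed=self.cfg.seed)
        mods = coexpression.kmeans_modules(z, k, seed=self.cfg.seed,
                                           biotype=ma.biotype, is_tf=ma.is_tf,
                                           fom_curve=curve)
        self.emit("coexpress", "modules.tsv",
                  lambda p: mods.labels.to_csv(p, sep="\t"))
        self.emit("coexpress", "module_summary.tsv",
                  lambda p: mods.counts.to_csv(p, sep="\t"))
        if curve is not None:
            self.emit("coexpress", "fom_curve.tsv",
                      lambda p: curve.to_csv(p, sep="\t", index=False))

    def stage_cerna(self):
        ma, mb = self.expr("A"), self.expr("B")
        mir_a, mir_b = self.mirna("A"), self.mirna("B")
        pairs = pd.read_csv(_need(self.out / "target_pairs.tsv", "cerna",
                                  "simulate"), sep="\t")
        expr = cerna.concat_expression([ma, mb])
        mir = cerna.concat_expression([mir_a, mir_b])
        lookup = pd.concat([expr, mir])
        edges, kept = cerna.correlation_filter(pairs, lookup, self.cfg.r_cut,
                                               self.cfg.p_cut)
        lnc = kept[kept["target_class"] == "lincRNA"]
        mr = kept[kept["target_class"] == "mRNA"]
        trips = cerna.build_triplets(lnc, mr, lookup, self.cfg.r_cut, self.cfg.p_cut)
        trips, tally = cerna.partition_networks(trips, lookup,
                                                rho_min=self.cfg.rho_min)
        self.emit("cerna", "cerna_edges.tsv",
                  lambda p: edges.to_csv(p, sep="\t", index=False))
        self.emit("cerna", "cerna_triplets.tsv",
                  lambda p: trips.to_csv(p, sep="\t", index=False))
        self.emit("cerna", "cerna_network_tally.tsv",
                  lambda p: tally.to_csv(p, sep="\t", index=False))

    def stage_sweep(self):
        g = self.geno()
        cfg = self.cfg
        pi_a = popgen.windowed_pi(g, "A", cfg.window, cfg.step, cfg.chrom_length)
        pi_b = popgen.windowed_pi(g, "B", cfg.window, cfg.step, cfg.chrom_length)
        fst = popgen.windowed_fst(g, "A", "B", cfg.window, cfg.step,
                                  cfg.min_snps, cfg.chrom_length)
        w, regions = popgen.sweep_scan(pi_a, pi_b, fst, cfg.fst_quantile,
                                       cfg.ratio_tail)
        self.emit("sweep", "window_stats.tsv",
                  lambda p: w.to_csv(p, sep="\t", index=False))
        self.emit("sweep", "sweep_regions.bed", lambda p: pd.DataFrame({
            "chrom": regions["chrom"], "start": regions["start"] - 1,
            "end": regions["end"], "name": regions["population"],
        }).to_csv(p, sep="\t", index=False, header=False))

    def stage_ld(self):
        g = self.geno()
        for pop in ("A", "B"):
            bins = popgen.ld_decay(g, pop, self.cfg.max_dist, self.cfg.bin_bp)
            self.emit("ld", f"ld_decay_{pop}.tsv",
                      lambda p, b=bins: b.to_csv(p, sep="\t", index=False))

    def stage_pca(self):
        coords, evals = popgen.genotype_pca(self.geno())
        coords.index.name = "sample"
        self.emit("pca", "pca_coords.tsv", lambda p: coords.to_csv(p, sep="\t"))

    def stage_tree(self):
        nwk = popgen.nj_tree(self.geno(), bootstrap=self.cfg.bootstrap,
                             seed=self.cfg.seed)
        self.emit("tree", "nj_tree.nwk", lambda p: p.write_text(nwk + "\n"))


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute `stages` (default: all) in dependency order; return manifest."""
    if stages is None:
        stages = list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise MissingUpstreamError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    run = _Run(cfg)
    for stage in ordered:
        getattr(run, "stage_" + stage.replace("-", "_"))()
    resolved = cfg.to_yaml()
    (run.out / "config.yaml").write_text(resolved)
    manifest = {
        "stages": run.manifest,
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
    }
    (run.out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True) + "\n")
    return manifest
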