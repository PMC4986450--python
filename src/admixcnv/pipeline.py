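"""End-to-end pipeline: simulate -> filter -> CNVR map -> genotypes ->
structure -> admixture -> F_ST -> ancestry-informative CNVRs -> enrichment.

One YAML config drives every stage. Each stage writes plain-text artifacts
into the run directory and records SHA-256 checksums of its inputs and
outputs in a state file; a rerun skips stages whose inputs and outputs are
unchanged, and a corrupted intermediate raises an error naming the stage.
The global seed fans out to per-stage seeds through a CRC-32 hash of the
stage name, so any stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    read_gene_table,
    read_genome_table,
    read_gmt,
    read_manifest,
    read_segments,
    write_cnvr_bed,
    write_segments,
)
from .segment_filter import FilterPolicy, filter_segments, summarize_calls
from .cnvr_builder import build_cnvrs, cnvr_intervals
from .genotype_coding import code_biallelic, read_genotypes, write_genotypes
from .population_structure import classical_mds, fit_forest_proximity
from .admixture_em import align_components, fit_admixture, mean_ancestry_by_population
from .popgen_stats import aic_frequency_table, classify_aic, fst_matrix, og_specific_cnvrs
from .enrichment import hypergeom_enrich, map_cnvr_to_genes
from .synthetic_data import NoiseRates, SimConfig, emit_annotation, simulate_dataset

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "filter",
    "build_cnvr",
    "code_genotypes",
    "structure",
    "admix",
    "fst",
    "aic",
    "enrich",
)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run (see ``from_yaml`` for the file form)."""

    outdir: Path
    seed: int = 0
    simulate: dict = field(default_factory=dict)       # SimConfig overrides
    filter_policy: FilterPolicy = field(default_factory=FilterPolicy)
    min_freq: float = 0.05
    n_trees: int = 2_000
    mds_dims: int = 3
    admix_K: int = 3
    admix_restarts: int = 5
    admix_max_iter: int = 300
    admix_tol: float = 1e-5
    aic_delta: float = 0.2
    aic_rare: float = 0.05
    enrich_alpha: float = 0.05
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        policy = FilterPolicy(**raw.get("filter", {}))
        structure = raw.get("structure", {})
        admix = raw.get("admixture", {})
        aic = raw.get("aic", {})
        return cls(
            outdir=Path(raw["outdir"]),
            seed=int(raw.get("seed", 0)),
            simulate=raw.get("simulate", {}),
            filter_policy=policy,
            min_freq=float(raw.get("cnvr", {}).get("min_freq", 0.05)),
            n_trees=int(structure.get("n_trees", 2_000)),
            mds_dims=int(structure.get("dims", 3)),
            admix_K=int(admix.get("K", 3)),
            admix_restarts=int(admix.get("restarts", 5)),
            admix_max_iter=int(admix.get("max_iter", 300)),
            admix_tol=float(admix.get("tol", 1e-5)),
            aic_delta=float(aic.get("delta", 0.2)),
            aic_rare=float(aic.get("rare", 0.05)),
            enrich_alpha=float(raw.get("enrichment", {}).get("alpha", 0.05)),
            make_plots=bool(raw.get("make_plots", False)),
        )


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: CRC-32 of "<seed>:<stage>", kept below 2**31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunReport:
    counts: dict[str, dict] = field(default_factory=dict)
    wall_seconds: dict[str, float] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        payload["config"] = {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in payload["config"].items()
        }
        path.write_text(json.dumps(payload, indent=1, default=str))


class _State:
    """Per-run checksum ledger backing skip/resume."""

    def __init__(self, path: Path):
        self.path = path
        self.data: dict = {}
        if path.exists():
            self.data = json.loads(path.read_text())

    def can_skip(self, stage: str, inputs: list[Path], outputs: list[Path]) -> bool:
        rec = self.data.get(stage)
        if rec is None:
            return False
        if not all(p.exists() for p in inputs + outputs):
            return False
        if any(_sha256(p) != rec["inputs"].get(str(p)) for p in inputs):
            return False
        for p in outputs:
            recorded = rec["outputs"].get(str(p))
            if recorded is None:
                return False
            if _sha256(p) != recorded:
                raise PipelineError(
                    f"stage {stage!r}: checksum mismatch for intermediate "
                    f"{p} (file modified outside the pipeline)"
                )
        return True

    def record(self, stage: str, inputs: list[Path], outputs: list[Path]) -> None:
        self.data[stage] = {
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
        }
        self.path.write_text(json.dumps(self.data, indent=1))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in dependency order, resuming where possible."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    state = _State(out / ".admixcnv_state.json")
    report = RunReport(config=dataclasses.asdict(config))

    paths = {
        "segments": out / "sim" / "segments.tsv",
        "manifest": out / "sim" / "manifest.tsv",
        "genome": out / "sim" / "genome.tsv",
        "truth": out / "sim" / "truth.json",
        "genes": out / "sim" / "genes.tsv",
        "gmt": out / "sim" / "genesets.gmt",
        "kept": out / "kept.tsv",
        "filter_report": out / "filter_report.json",
        "cnvr_bed": out / "cnvr.bed",
        "states": out / "states.tsv",
        "del_freq": out / "del_freq.tsv",
        "dup_freq": out / "dup_freq.tsv",
        "geno": out / "genotypes.tsv",
        "mds": out / "mds.tsv",
        "confusion": out / "confusion.tsv",
        "Q": out / "Q.tsv",
        "fst": out / "fst.tsv",
        "aic": out / "aic.tsv",
        "og_specific": out / "og_specific.json",
        "enrich": out / "enrichment.tsv",
    }

    def run_stage(name, inputs, outputs, fn):
        t0 = time.perf_counter()
        try:
            skippable = state.can_skip(name, inputs, outputs)
        except PipelineError:
            report.to_json(out / "report.json")
            raise
        if skippable:
            logger.info("stage %s: up to date, skipped", name)
            report.skipped.append(name)
            report.counts[name] = state.data[name].get("counts", {})
            return
        try:
            counts = fn() or {}
        except Exception:
            report.to_json(out / "report.json")
            raise
        state.record(name, inputs, outputs)
        state.data[name]["counts"] = counts
        state.path.write_text(json.dumps(state.data, indent=1))
        report.counts[name] = counts
        report.wall_seconds[name] = round(time.perf_counter() - t0, 3)

    # -- simulate ----------------------------------------------------------
    def do_simulate():
        sim_kwargs = dict(config.simulate)
        noise = sim_kwargs.pop("noise_rates", None)
        if noise is not None:
            sim_kwargs["noise_rates"] = NoiseRates(**noise)
        if "populations" in sim_kwargs:
            sim_kwargs["populations"] = [
                tuple(p) for p in sim_kwargs["populations"]
            ]
        sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
        sim_cfg = SimConfig(**sim_kwargs)
        ds = simulate_dataset(sim_cfg, out / "sim")
        emit_annotation(
            ds.truth, ds.genome,
            seed=stage_seed(config.seed, "annotation"),
            outdir=out / "sim",
        )
        return {
            "n_segments": len(ds.segments),
            "n_decoys": len(ds.truth.decoy_labels),
            "n_samples": len(ds.manifest),
            "n_loci": sim_cfg.n_loci,
        }

    run_stage(
        "simulate", [],
        [paths[k] for k in ("segments", "manifest", "genome", "truth",
                            "genes", "gmt")],
        do_simulate,
    )

    # -- filter ------------------------------------------------------------
    def do_filter():
        genome = read_genome_table(paths["genome"])
        segments = read_segments(paths["segments"], genome)
        rep = filter_segments(segments, config.filter_policy, genome)
        write_segments(rep.kept, paths["kept"])
        manifest = read_manifest(paths["manifest"])
        per_sample, per_pop = summarize_calls(rep.kept, manifest, genome)
        paths["filter_report"].write_text(json.dumps({
            "policy": dataclasses.asdict(rep.policy),
            "n_input": rep.n_input,
            "n_kept": len(rep.kept),
            "rejected_by_rule": rep.stage_counts,
            "per_population": json.loads(
                per_pop.to_json(orient="index")
            ),
        }, indent=1))
        return {"n_input": rep.n_input, "n_kept": len(rep.kept),
                "rejected_by_rule": rep.stage_counts}

    run_stage("filter",
              [paths[k] for k in ("segments", "genome", "manifest")],
              [paths["kept"], paths["filter_report"]],
              do_filter)

    # -- build CNVRs -------------------------------------------------------
    def do_cnvr():
        genome = read_genome_table(paths["genome"])
        manifest = read_manifest(paths["manifest"])
        kept = read_segments(paths["kept"], genome)
        cnvrs = build_cnvrs(kept, manifest, min_freq=config.min_freq)
        if len(cnvrs) == 0:
            raise PipelineError(
                "no CNVR survived the sample-frequency threshold"
            )
        write_cnvr_bed(cnvrs, paths["cnvr_bed"])
        sm = cnvrs.state_matrix()
        sm.index.name = "cnvr"
        sm.to_csv(paths["states"], sep="\t")
        cnvrs.del_freq.rename_axis("cnvr").to_csv(paths["del_freq"], sep="\t")
        cnvrs.dup_freq.rename_axis("cnvr").to_csv(paths["dup_freq"], sep="\t")
        return {"n_cnvrs": len(cnvrs),
                "classes": pd.Series(
                    [c.cnvr_class for c in cnvrs.cnvrs]
                ).value_counts().to_dict()}

    run_stage("build_cnvr",
              [paths[k] for k in ("kept", "manifest", "genome")],
              [paths[k] for k in ("cnvr_bed", "states", "del_freq", "dup_freq")],
              do_cnvr)

    # -- genotype coding ---------------------------------------------------
    def do_code():
        states = pd.read_csv(paths["states"], sep="\t", index_col=0)
        geno = code_biallelic(states)
        write_genotypes(geno, paths["geno"])
        return {"n_loci": geno.n_loci, "n_samples": geno.n_samples}

    run_stage("code_genotypes", [paths["states"]], [paths["geno"]], do_code)

    # -- population structure ---------------------------------------------
    def do_structure():
        states = pd.read_csv(paths["states"], sep="\t", index_col=0)
        manifest = read_manifest(paths["manifest"])
        labels = {s: manifest.population_of(s) for s in states.columns}
        prox, confusion = fit_forest_proximity(
            states, labels, n_trees=config.n_trees,
            seed=stage_seed(config.seed, "structure"),
        )
        mds = classical_mds(prox.to_distance(), dims=config.mds_dims)
        coords = mds.coordinates.copy()
        coords.insert(0, "population", [labels[s] for s in coords.index])
        coords.rename_axis("sample").to_csv(paths["mds"], sep="\t")
        confusion.counts.rename_axis("true").to_csv(paths["confusion"], sep="\t")
        if config.make_plots:
            _plot_mds(coords, out / "mds.png")
        return {"oob_accuracy": round(confusion.accuracy, 4),
                "positive_mass_fraction": round(mds.positive_mass_fraction, 4)}

    run_stage("structure", [paths["states"], paths["manifest"]],
              [paths["mds"], paths["confusion"]], do_structure)

    # -- admixture ---------------------------------------------------------
    def do_admix():
        geno = read_genotypes(paths["geno"])
        manifest = read_manifest(paths["manifest"])
        fit = fit_admixture(
            geno, K=config.admix_K, n_restarts=config.admix_restarts,
            max_iter=config.admix_max_iter, tol=config.admix_tol,
            seed=stage_seed(config.seed, "admix"),
        )
        refs = (manifest.populations_with_role("ancestral_indian")
                + manifest.populations_with_role("ancestral_african"))
        refs = refs[: config.admix_K]
        if refs:
            fit = align_components(fit, manifest, refs)
        Q = fit.Q.copy()
        Q.insert(0, "population",
                 [manifest.population_of(s) for s in Q.index])
        Q.rename_axis("sample").to_csv(paths["Q"], sep="\t")
        means = mean_ancestry_by_population(fit, manifest)
        if config.make_plots:
            _plot_q_barplot(fit.Q, Q["population"], out / "q_barplot.png")
        return {
            "loglik": round(fit.loglik, 3),
            "converged": fit.converged,
            "mean_ancestry": {
                pop: [round(v, 4) for v in row]
                for pop, row in means.iterrows()
            },
        }

    run_stage("admix", [paths["geno"], paths["manifest"]], [paths["Q"]],
              do_admix)

    # -- F_ST --------------------------------------------------------------
    def do_fst():
        geno = read_genotypes(paths["geno"])
        manifest = read_manifest(paths["manifest"])
        mat = fst_matrix(geno, manifest)
        mat.values.rename_axis("population").to_csv(paths["fst"], sep="\t")
        return {"pairs": {f"{a}~{b}": round(r.theta, 4)
                          for (a, b), r in mat.components.items()}}

    run_stage("fst", [paths["geno"], paths["manifest"]], [paths["fst"]],
              do_fst)

    # -- ancestry-informative CNVRs ---------------------------------------
    def do_aic():
        genome = read_genome_table(paths["genome"])
        manifest = read_manifest(paths["manifest"])
        kept = read_segments(paths["kept"], genome)
        cnvrs = build_cnvrs(kept, manifest, min_freq=config.min_freq)
        freq = aic_frequency_table(cnvrs, manifest)
        table = classify_aic(freq, delta=config.aic_delta, rare=config.aic_rare)
        table = table.join(freq["cnvr_class"])
        table.rename_axis("cnvr").to_csv(paths["aic"], sep="\t")
        target = manifest.populations_with_role("admixed")[0]
        specific, private = og_specific_cnvrs(cnvrs, manifest, target)
        paths["og_specific"].write_text(json.dumps(
            {"specific": specific, "strictly_private": private}, indent=1))
        return {
            "aic_classes": table["aic_class"].value_counts().to_dict(),
            "n_specific": len(specific),
            "n_strictly_private": len(private),
        }

    run_stage("aic",
              [paths[k] for k in ("kept", "manifest", "genome")],
              [paths["aic"], paths["og_specific"]],
              do_aic)

    # -- enrichment --------------------------------------------------------
    def do_enrich():
        genes = read_gene_table(paths["genes"])
        collection = read_gmt(paths["gmt"])
        cnvr_rows = pd.read_csv(paths["cnvr_bed"], sep="\t")
        regions = [
            (r["#chrom"], int(r["start"]), int(r["end"]))
            for _, r in cnvr_rows.iterrows()
        ]
        query = map_cnvr_to_genes(regions, genes)
        background = {g.gene_id for g in genes}
        result = hypergeom_enrich(query, collection, background,
                                  alpha=config.enrich_alpha)
        result.table.to_csv(paths["enrich"], sep="\t", index=False)
        return {
            "n_query_genes": len(query),
            "n_background": len(background),
            "n_significant": int(result.table["significant"].sum())
            if len(result.table) else 0,
        }

    run_stage("enrich",
              [paths[k] for k in ("cnvr_bed", "genes", "gmt")],
              [paths["enrich"]],
              do_enrich)

    report.to_json(out / "report.json")
    return report


# ---------------------------------------------------------------------------
# Plots (static summaries only)
# ---------------------------------------------------------------------------

def _plot_mds(coords: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for pop, grp in coords.groupby("population"):
        ax.scatter(grp["dim1"], grp["dim2"], label=pop, s=18)
    ax.set_xlabel("dim 1")
    ax.set_ylabel("dim 2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_q_barplot(Q: pd.DataFrame, populations: pd.Series, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = populations.sort_values(kind="mergesort").index
    data = Q.loc[order]
    fig, ax = plt.subplots(figsize=(8, 3))
    bottom = np.zeros(len(data))
    x = np.arange(len(data))
    for col in data.columns:
        ax.bar(x, data[col], bottom=bottom, width=1.0, label=col)
        bottom += data[col].to_numpy()
    ax.set_xticks([])
    ax.set_ylabel("ancestry proportion")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
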