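"""End-to-end orchestration: simulate → fit → score → cluster → enrich.

A run is driven by a :class:`RunConfig` and writes every stage's outputs
plus a ``manifest.json`` (seed, config hash, versions, per-stage row
counts) into a run directory. All randomness derives from the single run
seed: stage k uses ``SeedSequence([seed, k])``, so reruns with the same
config and seed are bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .cluster import filter_and_scale, hierarchical_cluster, treatment_separation_score
from .data import CrossDiffError, ExpressionMatrix
from .enrich import AnnotationMap, permutation_fdr, read_gmt, write_gmt
from .linmod import StrainContrastModel
from .scoring import proportion_test, summarize_overlap
from .simdata import SimConfig, generate_dataset, make_synthetic_annotation

STAGES = ("simulate", "fit", "score", "cluster", "enrich")


class StageError(CrossDiffError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    seed: int = 0
    alpha: float = 0.01
    var_threshold: float = 0.1
    n_perm: int = 1000
    per_strain_fit: bool = False
    stages: dict[str, bool] = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    sim: SimConfig = field(default_factory=SimConfig)
    matrix_path: str | None = None   # used instead of simulate when set
    samples_path: str | None = None
    gmt_path: str | None = None      # synthetic annotation when unset

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["sim"]["strains"] = [list(p) for p in self.sim.strains]
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, path, out_dir: str | None = None) -> "RunConfig":
        d = json.loads(pathlib.Path(path).read_text())
        if "sim" in d and d["sim"] is not None:
            sim = d["sim"]
            if "strains" in sim:
                sim["strains"] = tuple(tuple(p) for p in sim["strains"])
            d["sim"] = SimConfig(**sim)
        if out_dir is not None:
            d["out_dir"] = out_dir
        return cls(**d)


def _stage_seed(seed: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0]
               % 2**31)


def run_all(config: RunConfig) -> dict:
    """Execute all enabled stages in order; returns the manifest dict.

    A failing stage aborts with :class:`StageError` naming it; outputs of
    completed stages are retained.
    """
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    matrix = truth = results = scores = None

    def record(stage, **info):
        manifest["stages"][stage] = {"status": "done", **info}

    def skip(stage, reason="disabled"):
        manifest["stages"][stage] = {"status": "skipped", "reason": reason}

    try:
        stage = "simulate"
        if config.stages.get(stage, True) and config.matrix_path is None:
            sim = dataclasses.replace(config.sim,
                                      seed=_stage_seed(config.seed, 0))
            matrix, truth = generate_dataset(sim)
            matrix.to_tsv(out / "matrix.tsv", out / "samples.tsv")
            truth.to_tsv(out / "truth.tsv")
            sim.to_json(out / "sim_config.json")
            record(stage, n_genes=matrix.n_genes, n_samples=matrix.n_samples)
        elif config.matrix_path is not None:
            matrix = ExpressionMatrix.from_tsv(config.matrix_path,
                                               config.samples_path)
            if matrix.collectives is None:
                matrix.collectives = config.sim.collectives()
            skip(stage, "external matrix supplied")
        else:
            skip(stage)
    except CrossDiffError as err:
        raise StageError(f"stage 'simulate' failed: {err}") from err

    def need_matrix(stage):
        if matrix is None:
            raise StageError(f"stage {stage!r} needs expression data but none "
                             "was produced or supplied")

    try:
        stage = "fit"
        if config.stages.get(stage, True):
            need_matrix(stage)
            model = StrainContrastModel(matrix,
                                        per_strain_fit=config.per_strain_fit)
            results = model.fit()
            results.to_tsv(out / "contrasts")
            (out / "fit_summary.txt").write_text(results.summary(config.alpha)
                                                 + "\n")
            record(stage, n_genes=len(results.genes),
                   n_significant=results.n_significant(config.alpha))
        else:
            skip(stage)
    except CrossDiffError as err:
        raise StageError(f"stage 'fit' failed: {err}") from err

    try:
        stage = "score"
        if config.stages.get(stage, True) and results is not None:
            scores = results.score(alpha=config.alpha)
            scores.to_tsv(out / "scores.tsv")
            scores.two_way_table().to_tsv(out / "two_way_table.tsv")
            summary = scores.summarize()
            (out / "overlap_counts.json").write_text(
                json.dumps(summary, indent=2))
            sweep = results.threshold_sweep()
            sweep.to_csv(out / "threshold_sweep.tsv", sep="\t")
            record(stage, **{k: summary[k] for k in
                             ("responsive_any", "type_i", "type_ii",
                              "multi_strain")})
        else:
            skip(stage, "disabled" if not config.stages.get(stage, True)
                 else "fit not run")
    except CrossDiffError as err:
        raise StageError(f"stage 'score' failed: {err}") from err

    try:
        stage = "cluster"
        if config.stages.get(stage, True):
            need_matrix(stage)
            scaled = filter_and_scale(matrix.values, config.var_threshold)
            tree = hierarchical_cluster(scaled)
            tree.to_tsv(out / "linkage.tsv")
            (out / "leaf_order.txt").write_text(
                "\n".join(tree.leaf_order) + "\n")
            sep = treatment_separation_score(tree,
                                             matrix.samples["treatment"])
            record(stage, n_genes_kept=int(scaled.mask.sum()),
                   treatment_separation=sep)
        else:
            skip(stage)
    except CrossDiffError as err:
        raise StageError(f"stage 'cluster' failed: {err}") from err

    try:
        stage = "enrich"
        if config.stages.get(stage, True) and scores is not None:
            universe = set(scores.table.index)
            if config.gmt_path is not None:
                cats = read_gmt(config.gmt_path)
            elif truth is not None:
                cats = make_synthetic_annotation(
                    truth, seed=_stage_seed(config.seed, 4))
                write_gmt(cats, out / "annotation.gmt")
            else:
                raise StageError("stage 'enrich' needs a GMT file when no "
                                 "synthetic truth is available")
            ann = AnnotationMap(cats, universe)
            responsive = scores.table.index[scores.labels != "UNRESPONSIVE"]
            rows = permutation_fdr(responsive, ann, n_perm=config.n_perm,
                                   seed=_stage_seed(config.seed, 5))
            rows.to_csv(out / "enrichment.tsv", sep="\t")
            record(stage, n_categories=len(rows),
                   n_significant=int((rows["fdr"] < 0.05).sum()))
        else:
            skip(stage, "disabled" if not config.stages.get(stage, True)
                 else "score not run")
    except CrossDiffError as err:
        raise StageError(f"stage 'enrich' failed: {err}") from err

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def report(run_dir) -> str:
    """Human-readable run summary, recomputed from the stage outputs."""
    run = pathlib.Path(run_dir)
    lines = [f"run report: {run}"]
    scores_path = run / "scores.tsv"
    if not any(run.glob("*")):
        return f"run report: {run}\n  no stages completed"
    if scores_path.exists():
        records = pd.read_csv(scores_path, sep="\t", index_col=0)
        summary = summarize_overlap(records=records)
        table = pd.crosstab(records["R"], records["S"]).reindex(
            index=range(-2, 3), columns=range(-2, 3), fill_value=0)
        lines.append("\ntwo-way collective-score table "
                     "(rows: resistant, cols: sensitive):")
        lines.append(table.to_string())
        lines.append("")
        for key in ("universe", "responsive_any", "responsive_sensitive",
                    "responsive_resistant", "multi_strain", "type_i",
                    "type_i_up", "type_i_down", "type_ii",
                    "type_ii_sensitive", "type_ii_resistant"):
            lines.append(f"  {key:<24}{summary[key]}")
        x1 = summary["overlap_within_resistant"]
        n1 = summary["responsive_resistant"]
        x2 = summary["overlap_within_sensitive"]
        n2 = summary["responsive_sensitive"]
        if n1 > 0 and n2 > 0:
            p1, p2, p = proportion_test(x1, n1, x2, n2)
            lines.append(
                f"  within-collective overlap: resistant {x1}/{n1} "
                f"({100 * p1:.1f}%) vs sensitive {x2}/{n2} ({100 * p2:.1f}%), "
                f"proportion test p = {p:.2f}")
    else:
        lines.append("  scores: absent")
    sweep_path = run / "threshold_sweep.tsv"
    if sweep_path.exists():
        sweep = pd.read_csv(sweep_path, sep="\t", index_col=0)
        row = sweep.iloc[(np.abs(sweep.index - 2.0)).argmin()]
        lines.append("  responsive genes at adjusted p < 0.01, per strain: "
                     + ", ".join(f"{s}={int(v)}" for s, v in row.items()))
    else:
        lines.append("  threshold sweep: absent")
    enr_path = run / "enrichment.tsv"
    if enr_path.exists():
        rows = pd.read_csv(enr_path, sep="\t", index_col=0)
        lines.append(f"  enriched categories at 5% FDR: "
                     f"{int((rows['fdr'] < 0.05).sum())} of {len(rows)}")
    else:
        lines.append("  enrichment: absent")
    manifest_path = run / "manifest.json"
    if manifest_path.exists():
        m = json.loads(manifest_path.read_text())
        lines.append(f"  seed {m['seed']}, config hash {m['config_hash']}, "
                     f"version {m['package_version']}")
    return "\n".join(lines)
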