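"""Pipeline orchestration: simulate-or-load through the full analysis.

Stage order: load or simulate the cohort, preselect candidates per disease,
beta diversity + PCoA + PERMANOVA, bootstrap rounds per candidate block,
final-variable selection by the frequency rule, consensus isolated and
integrated models, and the comparison report.  Every artifact is written as
TSV/JSON/newick under the output directory together with a RunLog; reruns
with the same config are bit-identical.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import io as gio
from .bootstrap import ForestConfig, run_bootstrap_rounds
from .cohort import default_spec, generate_cohort
from .diversity import bray_curtis, jensen_shannon, pcoa, permanova, weighted_unifrac
from .evaluate import (build_comparison_report, consensus_fit_predict,
                       evaluate_scores, report_to_table, select_final_variables)
from .preselect import select_candidates

__all__ = ["PipelineConfig", "RunLog", "run_pipeline"]

log = logging.getLogger("gutpheno")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; file paths may be omitted in simulate mode."""

    output_dir: str
    simulate: bool = True
    counts_path: str | None = None
    phenotypes_path: str | None = None
    phenotype_schema: dict[str, str] | None = None
    labels_column: str = "group"
    labels_path: str | None = None
    tree_path: str | None = None
    control: str = "CT"
    alpha: float = 0.05
    min_prevalence: float = 0.1
    n_rounds: int = 50
    frequency_threshold: int = 25
    diversity_metric: str = "bray_curtis"
    n_permutations: int = 999
    seed: int = 0
    forest: ForestConfig = field(default_factory=ForestConfig)
    make_figures: bool = True

    def validate(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.frequency_threshold > self.n_rounds:
            raise ValueError("frequency_threshold cannot exceed n_rounds")
        if self.diversity_metric not in ("bray_curtis", "jensen_shannon",
                                         "weighted_unifrac"):
            raise ValueError(f"unknown diversity metric {self.diversity_metric!r}")
        if not self.simulate:
            for name in ("counts_path", "phenotypes_path", "labels_path"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when simulate=False")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
            if self.diversity_metric == "weighted_unifrac" and (
                self.tree_path is None or not Path(self.tree_path).exists()
            ):
                raise ValueError("weighted_unifrac requires tree_path")

    def to_json(self, path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        forest = d.pop("forest", {})
        return cls(forest=ForestConfig(**forest), **d)


@dataclass
class RunLog:
    """Timestamped stage records (seeds, versions, row/feature counts)."""

    records: list[dict] = field(default_factory=list)

    def stage(self, name: str, **info) -> None:
        rec = {"stage": name, "time": time.strftime("%Y-%m-%dT%H:%M:%S"), **info}
        self.records.append(rec)
        log.info("stage %s: %s", name,
                 " ".join(f"{k}={v}" for k, v in info.items()))

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.records, indent=2) + "\n")


def _setup_logging(out: Path) -> logging.Handler:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    file_handler = logging.FileHandler(out / "run.log")
    log.addHandler(file_handler)
    return file_handler


def _load_cohort(config: PipelineConfig, runlog: RunLog):
    from skbio import TreeNode

    if config.simulate:
        spec = default_spec(seed=config.seed)
        cohort = generate_cohort(spec)
        runlog.stage("simulate", n_samples=len(cohort.labels),
                     n_taxa=cohort.counts.shape[1], seed=config.seed)
        return cohort.counts, cohort.phenotypes, cohort.labels, cohort.tree, spec
    counts = gio.read_feature_table(config.counts_path)
    schema = config.phenotype_schema
    if schema is None:
        raw = pd.read_csv(config.phenotypes_path, sep="\t", index_col=0)
        schema = gio.phenotype_schema(raw)
    phenotypes = gio.read_phenotypes(config.phenotypes_path, schema)
    labels_df = pd.read_csv(config.labels_path, sep="\t", index_col=0)
    labels = labels_df[config.labels_column].astype(str)
    labels = labels.loc[counts.index]
    tree: TreeNode | None = None
    if config.tree_path:
        tree = gio.read_tree(config.tree_path)
    runlog.stage("load", n_samples=len(labels), n_taxa=counts.shape[1])
    return counts, phenotypes, labels, tree, None


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    runlog = RunLog()
    stage = "init"
    try:
        config.to_json(out / "config.json")
        stage = "load"
        counts, phenotypes, labels, tree, spec = _load_cohort(config, runlog)
        if spec is not None:
            gio.write_feature_table(counts, out / "counts.tsv")
            gio.write_phenotypes(phenotypes, out / "phenotypes.tsv")
            labels.to_frame().to_csv(out / "labels.tsv", sep="\t",
                                     index_label="sample")
            gio.write_tree(tree, out / "tree.nwk")
            gio.spec_to_json(spec, out / "synthetic_spec.json")

        stage = "diversity"
        metric = config.diversity_metric
        if metric == "bray_curtis":
            dm = bray_curtis(counts)
        elif metric == "jensen_shannon":
            dm = jensen_shannon(counts)
        else:
            dm = weighted_unifrac(counts, tree)
        gio.write_distance_matrix(dm, out / f"distance_{metric}.tsv")
        ordination = pcoa(dm)
        gio.write_ordination(ordination, out / "pcoa.tsv")
        perma = permanova(dm, labels, n_perm=config.n_permutations,
                          seed=config.seed)
        (out / "permanova.json").write_text(json.dumps({
            "metric": metric, "pseudo_F": perma.pseudo_f, "R2": perma.r2,
            "p_value": perma.p_value, "n_permutations": perma.n_permutations,
        }, indent=2) + "\n")
        runlog.stage("diversity", metric=metric,
                     permanova_R2=round(perma.r2, 4),
                     permanova_p=perma.p_value)

        stage = "preselect"
        diseases = sorted(set(labels.unique()) - {config.control})
        candidates = {}
        for disease in diseases:
            cs = select_candidates(counts, phenotypes, labels, disease,
                                   control=config.control, alpha=config.alpha,
                                   min_prevalence=config.min_prevalence)
            candidates[disease] = cs
            runlog.stage("preselect", disease=disease, taxa=len(cs.taxa),
                         quantitative=len(cs.quantitative),
                         qualitative=len(cs.qualitative))
        (out / "candidates.json").write_text(json.dumps(
            {d: cs.to_dict() for d, cs in candidates.items()}, indent=2) + "\n")

        stage = "bootstrap"
        freq_cols = {}
        blocks_map: dict[str, str] = {}
        isolated_rounds = {}
        for disease in diseases:
            cs = candidates[disease]
            if not cs.block("integrated"):
                runlog.stage("bootstrap", disease=disease, skipped="no candidates")
                continue
            rounds, freq = run_bootstrap_rounds(
                counts, phenotypes, labels, cs, block="integrated",
                control=config.control, n_rounds=config.n_rounds,
                config=config.forest, seed=config.seed,
            )
            freq_cols[disease] = freq
            isolated_rounds[disease] = rounds
            for t in cs.taxa:
                blocks_map[t] = "taxa"
            for q in cs.quantitative:
                blocks_map[q] = "quantitative"
            for q in cs.qualitative:
                blocks_map[q] = "qualitative"
            runlog.stage("bootstrap", disease=disease,
                         n_rounds=config.n_rounds,
                         mean_auc=round(float(pd.Series([r.auc for r in rounds]).mean()), 2))
        if not freq_cols:
            raise RuntimeError("no disease had a nonempty candidate set")
        freq_df = pd.DataFrame(freq_cols).fillna(0).astype(int)
        freq_df.to_csv(out / "importance_frequency.tsv", sep="\t",
                       index_label="variable")

        stage = "integrate"
        final = select_final_variables(freq_df, blocks_map,
                                       threshold=config.frequency_threshold,
                                       n_rounds=config.n_rounds)
        (out / "final_variables.json").write_text(json.dumps({
            "threshold": final.threshold,
            "variables": [
                {"name": v, "block": final.blocks[v],
                 "counts": {d: int(final.counts.loc[v, d])
                            for d in final.counts.columns}}
                for v in final.variables
            ],
        }, indent=2) + "\n")
        runlog.stage("integrate", n_selected=len(final.variables),
                     threshold=config.frequency_threshold)

        stage = "evaluate"
        isolated_perf = {}
        integrated_perf = {}
        top_vars = {}
        roc_rows = []
        for disease in sorted(freq_cols):
            taxa_final, quant_final, qual_final = final.split_blocks()
            from .preselect import CandidateSet

            if taxa_final:
                iso_vars = CandidateSet(disease=disease, taxa=taxa_final)
            else:  # no taxon survived the rule; fall back to candidate taxa
                iso_vars = CandidateSet(disease=disease,
                                        taxa=candidates[disease].taxa)
            if not iso_vars.taxa:
                runlog.stage("evaluate", disease=disease,
                             skipped="no taxa for isolated model")
                continue
            scores_iso, y_iso, _ = consensus_fit_predict(
                counts, phenotypes, labels, iso_vars, disease,
                control=config.control, n_resamples=config.n_rounds,
                config=config.forest, seed=config.seed,
            )
            scores_int, y_int, gini_int = consensus_fit_predict(
                counts, phenotypes, labels, final, disease,
                control=config.control, n_resamples=config.n_rounds,
                config=config.forest, seed=config.seed,
            )
            isolated_perf[disease] = evaluate_scores(
                scores_iso, y_iso, threshold=config.forest.threshold)
            integrated_perf[disease] = evaluate_scores(
                scores_int, y_int, threshold=config.forest.threshold)
            ranked = gini_int.sort_values(ascending=False)
            top_vars[disease] = [(v, final.blocks.get(v, "taxa"))
                                 for v in ranked.index[:10]]
            for kind, perf in (("isolated", isolated_perf[disease]),
                               ("integrated", integrated_perf[disease])):
                for f, t in zip(perf.fpr, perf.tpr):
                    roc_rows.append({"disease": disease, "model": kind,
                                     "fpr": f, "tpr": t})
            runlog.stage("evaluate", disease=disease,
                         isolated_auc=round(isolated_perf[disease].auc, 2),
                         integrated_auc=round(integrated_perf[disease].auc, 2))

        stage = "report"
        report = build_comparison_report(isolated_perf, integrated_perf, top_vars)
        (out / "comparison_report.json").write_text(
            json.dumps(report, indent=2) + "\n")
        report_to_table(report).to_csv(out / "comparison_report.tsv", sep="\t")
        pd.DataFrame(roc_rows).to_csv(out / "roc_points.tsv", sep="\t",
                                      index=False)
        if config.make_figures:
            _figures(out, freq_df, ordination, labels, isolated_perf,
                     integrated_perf)
        runlog.stage("report", diseases=len(report["diseases"]))
        runlog.write(out / "runlog.json")
        return out
    except Exception as exc:
        runlog.stage("abort", failed_stage=stage, error=str(exc))
        runlog.write(out / "runlog.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _figures(out, freq_df, ordination, labels, isolated, integrated):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(freq_df))))
    im = ax.imshow(freq_df.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(freq_df.shape[1]), freq_df.columns, rotation=45)
    ax.set_yticks(range(freq_df.shape[0]), freq_df.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="top-10 frequency")
    fig.tight_layout()
    fig.savefig(out / "frequency_heatmap.png", dpi=120)
    plt.close(fig)

    coords = ordination.coordinates
    if coords.shape[1] >= 2:
        fig, ax = plt.subplots(figsize=(5, 4))
        for g in sorted(labels.unique()):
            sel = labels.index[labels == g]
            ax.scatter(coords.loc[sel, coords.columns[0]],
                       coords.loc[sel, coords.columns[1]], s=12, label=g)
        ax.set_xlabel(f"PCo1 ({ordination.proportion_explained[0]:.1f}%)")
        ax.set_ylabel(f"PCo2 ({ordination.proportion_explained[1]:.1f}%)")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "pcoa.png", dpi=120)
        plt.close(fig)

    if isolated:
        fig, ax = plt.subplots(figsize=(5, 4))
        for disease in sorted(isolated):
            ax.plot(integrated[disease].fpr, integrated[disease].tpr,
                    label=f"{disease} ({integrated[disease].auc:.1f}%)")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=6)
        fig.tight_layout()
        fig.savefig(out / "roc_integrated.png", dpi=120)
        plt.close(fig)
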