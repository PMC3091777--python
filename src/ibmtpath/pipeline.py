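"""Config-driven orchestration of the five-comparison analysis.

For every configured comparison the pipeline runs, in order: per-gene
contrast fitting -> empirical-Bayes hyperparameter estimation -> moderated
t-test with BH FDR -> signed significance scores -> logistic-regression
enrichment -> parent/child redundancy collapse; then assembles the signed
terms x comparisons enrichment matrix, optionally computes array-vs-qPCR
concordance, and writes a machine-readable manifest recording versions, a
config hash, the estimated prior df per comparison and every effective
default.  Outputs are plain TSV/JSON at full double precision so repeated
runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .study_model import (
    Comparison,
    DEFAULT_COMPARISONS,
    ExpressionStudy,
    read_design_table,
    read_expression_table,
    quantile_normalize,
    log2p1,
)
from . import ibmt, lrpath, go_collapse, qpcr

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and comparison."""


@dataclass
class PipelineConfig:
    """Flat, fully-explicit pipeline configuration.

    ``comparisons`` is a list of records with keys ``name``, ``mode``,
    ``case`` and ``reference`` (design-column selectors); None selects the
    default five-comparison template.  All thresholds and knobs are recorded
    in the run manifest.
    """

    expression_path: str = ""
    design_path: str = ""
    gmt_path: str = ""
    dag_path: str | None = None
    ct_panel_path: str | None = None
    gene_map_path: str | None = None
    output_dir: str = "ibmtpath_run"
    comparisons: list[dict] | None = None
    quantile_normalization: bool = False
    log2_transform: bool = False
    span: float = 0.75
    min_set_size: int = 10
    max_set_size: int = 500
    directional: bool = True
    level: str = "gene"
    gene_fdr_threshold: float = 0.05
    set_fdr_threshold: float = 0.01
    overlap_threshold: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for thr in (self.gene_fdr_threshold, self.set_fdr_threshold,
                    self.overlap_threshold):
            if not (0.0 < thr <= 1.0):
                raise ValueError("thresholds must lie in (0, 1]")

    def comparison_objects(self) -> list[Comparison]:
        if self.comparisons is None:
            return list(DEFAULT_COMPARISONS)
        out = []
        for rec in self.comparisons:
            extra = set(rec) - {"name", "mode", "case", "reference"}
            if extra:
                raise ValueError(f"unknown comparison key(s) {sorted(extra)}")
            out.append(Comparison(rec["name"], rec["mode"], rec["case"], rec["reference"]))
        return out


def load_config(path) -> PipelineConfig:
    """Load a YAML config; unknown keys are errors, not warnings."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, sep="\t", index_label=index_label,
              float_format="%.17g", lineterminator="\n", encoding="utf-8")


def _stage(stage: str, comparison: str):
    """Context wrapper turning stage failures into labelled PipelineErrors."""
    class _Ctx:
        def __enter__(self):
            logger.info("[%s] stage %s", comparison, stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(
                    f"stage {stage!r} failed for comparison {comparison!r}: {exc}"
                ) from exc
            return False
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest (also written to disk)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("load_inputs", "-"):
        values = read_expression_table(config.expression_path)
        if config.log2_transform:
            values = log2p1(values)
        if config.quantile_normalization:
            values = quantile_normalize(values)
        design = read_design_table(config.design_path, expression=values)
        study = ExpressionStudy(values=values, design=design)
        gene_map = None
        if config.gene_map_path:
            gm = pd.read_csv(config.gene_map_path, sep="\t", dtype=str)
            gene_map = gm.set_index(gm.columns[0])[gm.columns[1]]
        sets = lrpath.read_gmt(config.gmt_path)
        dag = (go_collapse.read_dag(config.dag_path)
               if config.dag_path else go_collapse.TermDag.from_edges([]))

    comparisons = config.comparison_objects()
    enrichment_by_comparison: dict[str, pd.DataFrame] = {}
    gene_stats_by_comparison: dict[str, pd.DataFrame] = {}
    manifest_comparisons = {}

    for comp in comparisons:
        with _stage("fit_gene_stats", comp.name):
            stats_df = ibmt.fit_gene_stats(study, comp)
        with _stage("estimate_eb_hyperparameters", comp.name):
            hyper = ibmt.estimate_eb_hyperparameters(stats_df, span=config.span)
        with _stage("moderated_test", comp.name):
            mod = ibmt.moderated_test(stats_df, hyper)
        gene_table = pd.DataFrame(
            {
                "b": stats_df["b"], "a": stats_df["a"], "s2": stats_df["s2"],
                "d": stats_df["d"], "s0_2": hyper.s0_sq, "t_mod": mod["t"],
                "df": mod["df"], "p": mod["p"], "q": mod["q"],
                "sign": stats_df["sign"],
            },
            index=stats_df.index,
        )
        _write_tsv(gene_table, out_dir / f"gene_stats_{comp.name}.tsv", "probe_id")
        gene_stats_by_comparison[comp.name] = stats_df

        with _stage("build_significance_scores", comp.name):
            scores = lrpath.build_significance_scores(
                mod, stats_df, gene_map=gene_map, level=config.level
            )
        with _stage("run_lrpath", comp.name):
            enr = lrpath.run_lrpath(
                scores, sets,
                min_size=config.min_set_size, max_size=config.max_set_size,
                directional=config.directional,
                fdr_threshold=config.set_fdr_threshold,
            )
        _write_tsv(enr, out_dir / f"enrichment_{comp.name}.tsv", "set_id")
        enrichment_by_comparison[comp.name] = enr

        with _stage("collapse_significant_terms", comp.name):
            significant = list(enr.index[enr["enriched"]])
            universe_sets = sets.restricted_to(scores.index)
            retained, drop_log = go_collapse.collapse_significant_terms(
                significant, dag, universe_sets,
                overlap_threshold=config.overlap_threshold,
            )
        _write_tsv(enr.loc[retained], out_dir / f"collapsed_{comp.name}.tsv", "set_id")
        _write_tsv(drop_log.set_index("dropped_id"),
                   out_dir / f"droplog_{comp.name}.tsv", "dropped_id")
        logger.info("[%s] %d enriched term(s), collapsed to %d",
                    comp.name, len(significant), len(retained))

        m_tested = int(mod["ok"].sum())
        manifest_comparisons[comp.name] = {
            "mode": comp.mode,
            "d0": hyper.d0 if np.isfinite(hyper.d0) else "inf",
            "n_probes_tested": m_tested,
            "fdr_family_size_genes": m_tested,
            "n_genes_significant": int((mod["q"] < config.gene_fdr_threshold).sum()),
            "n_sets_tested": int((enr["status"] == "ok").sum()),
            "fdr_family_size_sets": int((enr["status"] == "ok").sum()),
            "n_sets_enriched": len(significant),
            "n_terms_retained_after_collapse": len(retained),
        }

    with _stage("enrichment_matrix", "-"):
        matrix = lrpath.enrichment_matrix(enrichment_by_comparison)
        enriched_any = sorted(
            {t for df in enrichment_by_comparison.values() for t in df.index[df["enriched"]]}
        )
        matrix = matrix.loc[[t for t in matrix.index if t in set(enriched_any)]]
        _write_tsv(matrix, out_dir / "enrichment_matrix.tsv", "set_id")

    concordance = None
    if config.ct_panel_path:
        with _stage("platform_concordance", "-"):
            panel = pd.read_csv(config.ct_panel_path, sep="\t")
            paired_stats = {
                c.name: gene_stats_by_comparison[c.name]
                for c in comparisons if c.mode == "paired"
            }
            result, pairs = qpcr.platform_concordance(paired_stats, panel, gene_map)
            with open(out_dir / "concordance.tsv", "w", encoding="utf-8",
                      newline="\n") as fh:
                fh.write(f"# spearman_rho={result.rho:.17g}\t"
                         f"p={result.p:.17g}\tn={result.n}\n")
                pairs.to_csv(fh, sep="\t", index=False,
                             float_format="%.17g", lineterminator="\n")
            concordance = {"rho": result.rho, "p": result.p, "n": result.n}

    manifest = {
        "package": "ibmtpath",
        "version": __version__,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": __import__("scipy").__version__,
            "statsmodels": __import__("statsmodels").__version__,
            "networkx": __import__("networkx").__version__,
        },
        "config": dataclasses.asdict(config),
        "config_sha256": _config_hash(config),
        "effective_defaults": {
            "span": config.span,
            "set_size_window": [config.min_set_size, config.max_set_size],
            "directional": config.directional,
            "enrichment_level": config.level,
            "score_log_base": "natural",
            "p_floor": lrpath.P_FLOOR,
            "irls_max_iter": lrpath.MAX_ITER,
            "irls_deviance_tol": lrpath.DEV_TOL,
            "irls_separation_bound": lrpath.SEPARATION_BOUND,
            "gene_fdr_threshold": config.gene_fdr_threshold,
            "set_fdr_threshold": config.set_fdr_threshold,
            "set_fdr_family": "all sets tested within one run, per comparison",
            "gene_fdr_family": "all probes tested within the comparison",
            "collapse_overlap_threshold": config.overlap_threshold,
            "d0_search_interval": [1e-2, 1e6],
            "quantile_normalization": config.quantile_normalization,
            "log2_transform": config.log2_transform,
            "qpcr_fold_averaging": "unweighted mean of per-subject log2 folds",
            "amplification_efficiency": 2.0,
        },
        "comparisons": manifest_comparisons,
        "concordance": concordance,
        "seed": config.seed,
    }
    with open(out_dir / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
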