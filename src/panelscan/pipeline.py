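"""End-to-end orchestration: align -> DE -> search -> evaluate -> adjust -> subtype.

:func:`run_analysis` executes the whole discovery workflow on in-memory
objects and returns a :class:`PipelineResult`; :func:`run_pipeline`
wraps it with file I/O, a YAML-configurable :class:`RunConfig`, logging
and a JSON manifest that records versions, seed, thresholds and the
sample/gene counts at every filter step (input counts minus exclusions
equal analyzed counts at each stage).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_io import (AlignedCohort, ClinicalTable, ExpressionMatrix,
                        ExpressionUnit, GeneSetCollection, align_cohort,
                        read_clinical, read_expression, read_gmt)
from .diffexpr import (DEResult, read_de_table, run_de, select_sde, to_frame,
                       write_de_table)
from .multivariate_adjust import AdjustedFit, AdjustedModelSpec, fit_adjusted
from .panel_search import (CombinationRanking, PanelDefinition, ScoreVector,
                           additive_search, evaluate_panel)
from .subtype_assoc import AnovaResult, subtype_association
from .survival_core import LogRankResult

logger = logging.getLogger("panelscan")

__all__ = ["RunConfig", "PipelineResult", "run_analysis", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for a full pipeline run (YAML-loadable)."""

    expression: str = ""
    clinical: str = ""
    gene_sets: str = ""              # GMT path; empty -> use all genes
    de_table: str = ""               # precomputed DE table (skips the NB engine)
    unit: str = "raw_counts"
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    use_adjusted_p: bool = True
    endpoint: str = "both"           # evaluation endpoints: os, pfs or both
    search_endpoint: str = "os"      # the screen itself runs on one endpoint
    criterion: str = "pval"
    hr_method: str = "mantel-haenszel"
    ties_method: str = "efron"
    seed: int = 0
    outdir: str = "panelscan_out"

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.endpoint not in ("os", "pfs", "both"):
            raise ValueError("endpoint must be os, pfs or both")
        if self.search_endpoint not in ("os", "pfs"):
            raise ValueError("search_endpoint must be os or pfs")

    @property
    def eval_endpoints(self) -> list[str]:
        return ["os", "pfs"] if self.endpoint == "both" else [self.endpoint]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class PipelineResult:
    """Everything a run produced, plus the manifest."""

    aligned: AlignedCohort
    de_results: list[DEResult]
    sde: list[DEResult]
    ranking: CombinationRanking
    panel: PanelDefinition
    evaluations: dict[str, LogRankResult]
    scores: ScoreVector | None
    adjusted: dict[str, AdjustedFit]
    anova: dict[str, AnovaResult]
    manifest: dict[str, Any]


def run_analysis(expr: ExpressionMatrix, clin: ClinicalTable,
                 gene_sets: GeneSetCollection | list[str] | None = None,
                 de_table: list[DEResult] | None = None,
                 config: RunConfig | None = None) -> PipelineResult:
    """Execute the full discovery workflow on in-memory objects.

    Stages: cohort alignment, differential expression + SDE filter (or an
    externally supplied DE table), exhaustive additive search on the
    search endpoint, panel evaluation on each requested endpoint,
    multivariate Cox adjustment, and subtype ANOVA where labels exist.
    Any stage failure raises with the stage named.
    """
    cfg = config or RunConfig()
    manifest: dict[str, Any] = {
        "versions": {"panelscan": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "python": platform.python_version()},
        "seed": cfg.seed,
        "thresholds": {"lfc": cfg.lfc_threshold, "p": cfg.p_threshold,
                       "use_adjusted_p": cfg.use_adjusted_p},
        "stages": {},
    }

    # --- stage 1: alignment -------------------------------------------------
    universe = gene_sets if gene_sets is not None else list(expr.gene_ids)
    try:
        aligned = align_cohort(expr, clin, universe)
    except Exception as exc:
        raise RuntimeError(f"stage 'align' failed: {exc}") from exc
    n_universe = (len(universe.union()) if isinstance(universe, GeneSetCollection)
                  else len(universe))
    manifest["stages"]["align"] = {
        "candidate_universe": n_universe,
        "genes_retained": aligned.expression.n_genes,
        "genes_dropped": len(aligned.dropped_genes),
        "dropped_gene_ids": aligned.dropped_genes,
        "samples_shared": aligned.expression.n_samples,
        "samples_dropped": len(aligned.dropped_samples),
    }
    logger.info("align: %d/%d candidate genes retained, %d samples",
                aligned.expression.n_genes, n_universe, aligned.expression.n_samples)

    # --- stage 2: differential expression + SDE filter ----------------------
    try:
        if de_table is not None:
            de_results = list(de_table)
            sde = select_sde(de_results, cfg.lfc_threshold, cfg.p_threshold,
                             cfg.use_adjusted_p)
            engine = "external"
        else:
            cond = aligned.clinical.df["condition"].to_numpy()
            de_results, sde = run_de(aligned.expression, cond, cfg.lfc_threshold,
                                     cfg.p_threshold, cfg.use_adjusted_p)
            engine = "nb_wald"
    except Exception as exc:
        raise RuntimeError(f"stage 'diffexpr' failed: {exc}") from exc
    if not sde:
        raise RuntimeError("stage 'diffexpr' failed: no SDE candidate passed the filter")
    manifest["stages"]["diffexpr"] = {
        "engine": engine, "genes_tested": len(de_results),
        "sde_selected": len(sde),
        "sde_genes": {r.gene_id: {"log2FC": r.log2fc, "sign": r.sign} for r in sde},
    }
    logger.info("diffexpr (%s): %d/%d genes pass the SDE filter",
                engine, len(sde), len(de_results))

    # --- stage 3: exhaustive additive search --------------------------------
    candidates = [r.gene_id for r in sde]
    signs = [r.sign for r in sde]
    try:
        ranking = additive_search(aligned.expression, aligned.clinical,
                                  candidates, signs, cfg.search_endpoint,
                                  cfg.criterion, cfg.hr_method)
    except Exception as exc:
        raise RuntimeError(f"stage 'search' failed: {exc}") from exc
    winner = ranking.selected
    manifest["stages"]["search"] = {
        "endpoint": cfg.search_endpoint, "criterion": cfg.criterion,
        "candidates": len(candidates),
        "subsets_screened": ranking.n_screened,
        "bonferroni_alpha": ranking.bonferroni_alpha,
        "selected_panel": winner,
        "selected_p": float(ranking.table.iloc[0]["logrank_p"]),
        "selected_hr": float(ranking.table.iloc[0]["hr"]),
        "note": ("winner p-value is the minimum over "
                 f"{ranking.n_screened} correlated tests; interpret with the "
                 "screen size in mind"),
    }
    logger.info("search: %d subsets screened, winner %s",
                ranking.n_screened, ",".join(winner))
    sign_by_gene = {r.gene_id: r.sign for r in sde}
    panel = PanelDefinition(winner, [sign_by_gene[g] for g in winner])

    # --- stage 4: panel evaluation on each endpoint -------------------------
    evaluations: dict[str, LogRankResult] = {}
    scores: ScoreVector | None = None
    manifest["stages"]["evaluate"] = {}
    for ep in cfg.eval_endpoints:
        try:
            _, res, sv = evaluate_panel(aligned.expression, aligned.clinical,
                                        panel, ep, cfg.hr_method)
        except Exception as exc:
            raise RuntimeError(f"stage 'evaluate[{ep}]' failed: {exc}") from exc
        evaluations[ep] = res
        if ep == cfg.search_endpoint or scores is None:
            scores = sv
        manifest["stages"]["evaluate"][ep] = {
            "n": sum(res.n_per_group), "hr": res.hr, "ci95": list(res.ci95),
            "p": res.p,
        }

    # --- stage 5: multivariate Cox adjustment -------------------------------
    adjusted: dict[str, AdjustedFit] = {}
    manifest["stages"]["adjust"] = {}
    for ep in cfg.eval_endpoints:
        try:
            afit = fit_adjusted(aligned.clinical, scores,
                                AdjustedModelSpec(endpoint=ep,
                                                  ties_method=cfg.ties_method))
        except Exception as exc:
            raise RuntimeError(f"stage 'adjust[{ep}]' failed: {exc}") from exc
        adjusted[ep] = afit
        manifest["stages"]["adjust"][ep] = {
            "n_used": afit.n_used, "n_excluded_missing": afit.n_excluded_missing,
            "converged": afit.fit.converged,
            "panel_hr": float(afit.fit.hr[0]),
            "panel_ci95": list(afit.fit.ci95[0]),
            "panel_p": float(afit.fit.wald_p[0]),
        }

    # --- stage 6: subtype association (if labels present) -------------------
    anova: dict[str, AnovaResult] = {}
    manifest["stages"]["subtype"] = {}
    for scheme in ("pam50", "pcs"):
        labels = aligned.clinical.df.loc[scores.sample_ids, scheme]
        if labels.notna().sum() < 4:
            manifest["stages"]["subtype"][scheme] = "skipped: no labels"
            continue
        try:
            anova[scheme] = subtype_association(scores, aligned.clinical, scheme)
        except Exception as exc:
            raise RuntimeError(f"stage 'subtype[{scheme}]' failed: {exc}") from exc
        a = anova[scheme]
        manifest["stages"]["subtype"][scheme] = {
            "f_value": a.f_value, "p": a.p, "df": [a.df_between, a.df_within],
            "group_n": a.group_n, "group_mean": a.group_mean,
            "n_unlabelled_excluded": int(labels.isna().sum()),
        }

    return PipelineResult(aligned, de_results, sde, ranking, panel, evaluations,
                          scores, adjusted, anova, manifest)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """File-based pipeline run: read inputs, analyze, write all outputs.

    Writes into ``config.outdir``: de_table.tsv, ranking_<endpoint>.tsv,
    panel.json, adjusted_<endpoint>.tsv, anova.json and manifest.json.
    Partial outputs are retained if a later stage fails.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")

    expr = read_expression(config.expression, ExpressionUnit(config.unit))
    clin = read_clinical(config.clinical)
    gene_sets = read_gmt(config.gene_sets) if config.gene_sets else None
    de_tab = read_de_table(config.de_table) if config.de_table else None

    result = None
    try:
        result = run_analysis(expr, clin, gene_sets, de_tab, config)
    finally:
        if result is not None:
            _write_outputs(result, config, outdir)
    return result


def _write_outputs(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    write_de_table(result.de_results, outdir / "de_table.tsv")
    result.ranking.table.to_csv(outdir / f"ranking_{config.search_endpoint}.tsv",
                                sep="\t", index=False)
    panel_blob = {
        "genes": result.panel.genes, "signs": result.panel.signs,
        "subsets_screened": result.ranking.n_screened,
        "evaluations": {ep: {"hr": r.hr, "ci95": list(r.ci95), "p": r.p}
                        for ep, r in result.evaluations.items()},
    }
    (outdir / "panel.json").write_text(json.dumps(panel_blob, indent=2))
    for ep, afit in result.adjusted.items():
        afit.report().to_csv(outdir / f"adjusted_{ep}.tsv", sep="\t")
    if result.anova:
        (outdir / "anova.json").write_text(json.dumps(
            {scheme: asdict(a) for scheme, a in result.anova.items()}, indent=2))
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, default=_json_default))
    logger.info("outputs written to %s", outdir)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _setup_logging(logfile: Path) -> None:
    if not logger.handlers:
        logger.setLevel(logging.INFO)
        sh = logging.StreamHandler()
        sh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(sh)
    fh = logging.FileHandler(logfile)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    logger.addHandler(fh)
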