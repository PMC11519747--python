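"""End-to-end orchestration: simulate/load -> select -> fit -> summarize.

The default :class:`RunConfig` reproduces the reference analysis profile:
p < 0.01 edge screen, |r| >= 0.8 collinearity pruning, 6-fold x 4-repeat
top-60% MI consensus, 8 quantile bins, stratified 10-fold OLS evaluation.

Evaluation modes
----------------
Non-nested (default): selection runs once on the full cohort before model
cross-validation, mirroring the reference pipeline order. Because the test
folds then contribute to feature selection, its CV estimates carry optimism
on null data. ``nested=True`` re-runs the entire selection inside each
training fold, giving leakage-free estimates; its per-fold feature sets
differ, so the network summary always derives from the full-cohort
selection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ConnectomeCohort
from .errors import CtcpmError
from .io import write_edge_report
from .model import CVResult, FoldFit, metric_mae, metric_r2, metric_rmse, ols_fit, quantile_bins, run_cv, stratified_folds, _predict
from .selection import SelectionResult, select_features
from .summary import NetworkSummary, build_network_summary
from scipy import stats as _stats


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters of one pipeline run."""

    alpha: float = 0.01
    collinearity_threshold: float = 0.8
    select_k_folds: int = 6
    select_repeats: int = 4
    top_fraction: float = 0.6
    mi_bins: int = 8
    n_folds: int = 10
    n_bins: int = 8
    seed: int = 0
    nested: bool = False


@dataclass
class PipelineResult:
    config: RunConfig
    selection: SelectionResult
    cv: CVResult
    summary: NetworkSummary
    nested_cv: CVResult | None = None
    stage_log: dict | None = None


def _subset_cohort(cohort: ConnectomeCohort, idx: np.ndarray) -> ConnectomeCohort:
    return ConnectomeCohort(
        subjects=[cohort.subjects[i] for i in idx],
        X=cohort.X[idx],
        y=cohort.y[idx],
        edge_index=cohort.edge_index,
        atlas=cohort.atlas,
    )


def _nested_cv(cohort: ConnectomeCohort, config: RunConfig, plan, rng) -> CVResult:
    """Re-run the full selection inside each training fold; predict held-out."""
    rows, metrics = [], {"mae": [], "rmse": [], "r2": []}
    fold_fits = []
    for k, (train, test) in enumerate(plan.split()):
        sub = _subset_cohort(cohort, train)
        sel = select_features(
            sub,
            alpha=config.alpha,
            collinearity_threshold=config.collinearity_threshold,
            k_folds=config.select_k_folds,
            repeats=config.select_repeats,
            top_fraction=config.top_fraction,
            n_bins=config.mi_bins,
            seed=int(rng.integers(2**31)),
        )
        feats = sel.consensus_edges
        beta, se, t = ols_fit(cohort.X[np.ix_(train, feats)], cohort.y[train])
        pred = _predict(beta, cohort.X[np.ix_(test, feats)])
        fold_fits.append(
            FoldFit(
                fold=k, feature_ids=feats, beta=beta, se=se, t=t,
                train_ids=train, test_ids=test, test_predictions=pred,
            )
        )
        metrics["mae"].append(metric_mae(cohort.y[test], pred))
        metrics["rmse"].append(metric_rmse(cohort.y[test], pred))
        metrics["r2"].append(metric_r2(cohort.y[test], pred))
        for idx, p in zip(test, pred):
            rows.append((cohort.subjects[idx], k, cohort.y[idx], float(p)))
    preds = pd.DataFrame(rows, columns=["subject_id", "fold", "observed", "predicted"])
    preds = preds.sort_values("subject_id", kind="stable").reset_index(drop=True)
    fold_metrics = pd.DataFrame(metrics)
    obs, pre = preds["observed"].to_numpy(), preds["predicted"].to_numpy()
    pooled_r = float(_stats.pearsonr(obs, pre)[0]) if np.std(pre) > 0 else float("nan")
    return CVResult(
        fold_fits=fold_fits,
        fold_metrics=fold_metrics,
        metric_means={m: float(fold_metrics[m].mean()) for m in metrics},
        metric_sds={m: float(fold_metrics[m].std(ddof=1)) for m in metrics},
        predictions=preds,
        pooled_r=pooled_r,
        pooled_r2=metric_r2(obs, pre),
    )


def run_pipeline(
    cohort: ConnectomeCohort,
    config: RunConfig = RunConfig(),
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute select -> fit -> summarize on a cohort.

    Writes, when ``outdir`` is given: the selection table and provenance,
    CV metrics and pooled predictions, the edge/degree/macroscale report,
    and a run log with stage-wise feature counts.
    """
    rng = np.random.default_rng(config.seed)
    select_seed = int(rng.integers(2**31))
    fold_seed = int(rng.integers(2**31))
    nested_seed = int(rng.integers(2**31))

    try:
        selection = select_features(
            cohort,
            alpha=config.alpha,
            collinearity_threshold=config.collinearity_threshold,
            k_folds=config.select_k_folds,
            repeats=config.select_repeats,
            top_fraction=config.top_fraction,
            n_bins=config.mi_bins,
            seed=select_seed,
        )
    except CtcpmError as exc:
        raise type(exc)(f"stage 'select': {exc}") from exc

    try:
        bins = quantile_bins(cohort.y, n_bins=config.n_bins)
        plan = stratified_folds(bins, n_folds=config.n_folds, seed=fold_seed)
        cv = run_cv(
            cohort.X[:, selection.consensus_edges],
            cohort.y,
            plan,
            feature_ids=selection.consensus_edges,
            subjects=cohort.subjects,
        )
    except CtcpmError as exc:
        raise type(exc)(f"stage 'fit': {exc}") from exc

    nested_cv = None
    if config.nested:
        try:
            nested_cv = _nested_cv(cohort, config, plan, np.random.default_rng(nested_seed))
        except CtcpmError as exc:
            raise type(exc)(f"stage 'fit-nested': {exc}") from exc

    try:
        summary = build_network_summary(cv, selection, cohort.atlas, cohort.edge_index)
    except CtcpmError as exc:
        raise type(exc)(f"stage 'summarize': {exc}") from exc

    stage_log = {
        "n_subjects": cohort.n_subjects,
        "n_nodes": cohort.edge_index.n_nodes,
        "n_edges": cohort.n_edges,
        "n_passing_screen": int(selection.screen.passing_edges.size),
        "n_after_collinearity": int(selection.retained_after_collinearity.size),
        "n_consensus": int(selection.n_consensus),
        "n_positive": int(np.sum(selection.screen.sign_of(selection.consensus_edges) > 0))
        if selection.n_consensus else 0,
        "n_negative": int(np.sum(selection.screen.sign_of(selection.consensus_edges) < 0))
        if selection.n_consensus else 0,
        "version": __version__,
    }
    result = PipelineResult(
        config=config, selection=selection, cv=cv, summary=summary,
        nested_cv=nested_cv, stage_log=stage_log,
    )
    if outdir is not None:
        write_pipeline_outputs(result, cohort, Path(outdir))
    return result


def selection_table(selection: SelectionResult, cohort: ConnectomeCohort) -> pd.DataFrame:
    """Screened-edge table: edge_id, node pair, r, p, sign, selected flag."""
    eids = selection.screen.passing_edges
    pairs = cohort.edge_index.pairs[eids] if eids.size else np.empty((0, 2), dtype=int)
    sel = set(selection.consensus_edges.tolist())
    return pd.DataFrame(
        {
            "edge_id": eids,
            "node_i": pairs[:, 0] if eids.size else [],
            "node_j": pairs[:, 1] if eids.size else [],
            "r": selection.screen.r[eids],
            "p": selection.screen.p[eids],
            "sign": selection.screen.sign[eids],
            "selected": [int(e in sel) for e in eids],
        }
    )


def _cv_payload(cv: CVResult) -> dict:
    return {
        "fold_metrics": {m: [float(v) for v in cv.fold_metrics[m]] for m in cv.fold_metrics},
        "metric_means": cv.metric_means,
        "metric_sds": cv.metric_sds,
        "pooled_r": cv.pooled_r,
        "pooled_r2": cv.pooled_r2,
    }


def write_pipeline_outputs(result: PipelineResult, cohort: ConnectomeCohort, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    selection_table(result.selection, cohort).to_csv(outdir / "selection.csv", index=False)
    prov = {"config": asdict(result.config), "parameters": result.selection.parameters,
            "stage_log": result.stage_log}
    (outdir / "selection.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
    payload = {"cv": _cv_payload(result.cv)}
    if result.nested_cv is not None:
        payload["nested_cv"] = _cv_payload(result.nested_cv)
    (outdir / "cv_metrics.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    result.cv.predictions.to_csv(outdir / "predictions.csv", index=False)
    fold_t = pd.DataFrame(
        [ff.t[1:] for ff in result.cv.fold_fits],
        columns=[str(e) for e in result.cv.fold_fits[0].feature_ids],
    )
    fold_t.insert(0, "fold", range(len(result.cv.fold_fits)))
    fold_t.to_csv(outdir / "fold_t.csv", index=False)
    write_edge_report(result.summary, cohort.atlas, outdir)
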