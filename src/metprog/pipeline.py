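"""End-to-end orchestration of the prognostic-index workflow.

restrict -> differential expression -> RWR prioritization -> univariate
Cox screening -> lasso-Cox risk model -> median-split stratification ->
Kaplan-Meier / log-rank / time-dependent AUC.  Every stage writes its
table under the output directory and a run manifest records seeds,
thresholds, stage gene counts and output file hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, io, netprop, signature, surveval
from .netprop import DEFAULT_SEEDS, RWRConfig

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    expression: str = ""
    annotation: str = ""
    network: str = ""
    gene_sets: str = ""
    out_dir: str = "metprog_out"
    alpha_de: float = 0.05
    lfc: float = 1.0
    alpha_cox: float = 0.05
    rwr_b: float = 0.7
    rwr_max_iter: int = 100_000
    rwr_tol: float = 1e-10
    rwr_k: int = 200
    seed_genes: tuple[str, ...] = DEFAULT_SEEDS
    restrict_rwr_to_de: bool = True
    cv_folds: int = 10
    roc_horizons: tuple[float, ...] = (1.0, 3.0, 5.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("seed_genes", "roc_horizons"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full workflow and return the result bundle.

    The bundle holds the DE table, the ranked RWR candidates, univariate
    Cox fits, the fitted risk model, per-sample scores and risk groups,
    and the survival evaluation (log-rank + AUC per horizon).  Partial
    outputs are retained on stage failure.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    counts: dict[str, int] = {}

    expr, ann, net, gene_sets = _load_inputs(cfg)
    counts["input_genes"] = expr.shape[0]

    expr_mrg = _restrict(expr, gene_sets)
    counts["restricted_genes"] = expr_mrg.shape[0]

    de_table, de_genes = _diffexpr(cfg, expr_mrg, ann, out)
    bundle["de_table"] = de_table
    counts["de_genes"] = len(de_genes)

    ranked = _rwr(cfg, net, de_genes, out)
    bundle["rwr_ranking"] = ranked
    counts["rwr_candidates"] = len(ranked)

    candidates = [g for g, _ in ranked if g in expr_mrg.index]
    dropped = len(ranked) - len(candidates)
    if dropped:
        log.info("%d ranked genes lack expression and are dropped", dropped)

    tumour = ann.index[ann["group"] == "tumour"]
    tumour = [s for s in tumour if s in expr_mrg.columns]
    surv = ann.loc[tumour, ["time", "event"]].astype(float)
    # log2 covariates for the hazard models (FPKM is heavy-tailed)
    X = np.log2(expr_mrg.loc[candidates, tumour] + 1.0)

    fits, screened = _screen(cfg, X, surv, out)
    bundle["cox_fits"] = fits
    counts["screened_genes"] = len(screened)

    model = _lasso(cfg, X.loc[screened], surv, out)
    bundle["risk_model"] = model
    counts["model_genes"] = len(model.active_genes)

    scores, groups, evaluation = _evaluate(cfg, X, model, surv, out)
    bundle["risk_scores"] = scores
    bundle["risk_groups"] = groups
    bundle["evaluation"] = evaluation

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "stage_gene_counts": counts,
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    bundle["manifest"] = manifest
    return bundle


@_stage("load-inputs")
def _load_inputs(cfg):
    expr = io.read_expression(cfg.expression)
    ann = io.read_annotation(cfg.annotation)
    net = io.read_network(cfg.network)
    gene_sets = io.read_gmt(cfg.gene_sets)
    return expr, ann, net, gene_sets


@_stage("restrict")
def _restrict(expr, gene_sets):
    universe = sorted(set().union(*gene_sets.values()))
    return diffexpr.restrict_to_gene_set(expr, universe)


@_stage("diffexpr")
def _diffexpr(cfg, expr, ann, out):
    results = diffexpr.differential_test(
        expr, ann["group"], alpha=cfg.alpha_de, lfc=cfg.lfc
    )
    up, down = diffexpr.de_filter(results, alpha=cfg.alpha_de, lfc=cfg.lfc)
    table = diffexpr.results_frame(results)
    table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    return table, up + down


@_stage("rwr")
def _rwr(cfg, net, de_genes, out):
    seeds = [s for s in cfg.seed_genes if s in net]
    if not seeds:
        raise ValueError("no seed genes present in the network")
    if cfg.restrict_rwr_to_de:
        keep = (set(de_genes) | set(seeds)) & set(net.nodes)
        net = net.subgraph(keep).copy()
    missing_de = len(set(de_genes) - set(net.nodes))
    if missing_de:
        log.info("%d differential genes absent from the network", missing_de)
    tm = netprop.build_transition_matrix(net)
    rcfg = RWRConfig(b=cfg.rwr_b, max_iter=cfg.rwr_max_iter, tol=cfg.rwr_tol, k=cfg.rwr_k)
    p, n_iter = netprop.rwr(tm, seeds, rcfg)
    log.info("RWR converged after %d iterations", n_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ranked = netprop.rank_top_k(p, tm, seeds, rcfg)
    pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "gene": [g for g, _ in ranked],
            "probability": [v for _, v in ranked],
        }
    ).to_csv(out / "rwr_ranking.tsv", sep="\t", index=False)
    return ranked


@_stage("cox-screen")
def _screen(cfg, X, surv, out):
    fits = [
        signature.univariate_cox(X.loc[g], surv["time"], surv["event"], gene=g)
        for g in X.index
    ]
    screened = signature.screen_genes(fits, alpha=cfg.alpha_cox)
    pd.DataFrame(
        {
            "gene": [f.gene for f in fits],
            "beta": [f.beta for f in fits],
            "hr": [f.hr for f in fits],
            "ci_low": [f.ci_low for f in fits],
            "ci_high": [f.ci_high for f in fits],
            "p_value": [f.p_value for f in fits],
        }
    ).to_csv(out / "univariate_cox.tsv", sep="\t", index=False)
    return fits, screened


@_stage("lasso")
def _lasso(cfg, X, surv, out):
    model = signature.lasso_cox(
        X, surv["time"], surv["event"], cv_folds=cfg.cv_folds, seed=cfg.seed
    )
    (out / "risk_model.json").write_text(
        json.dumps(
            {
                "genes": list(model.genes),
                "coefficients": model.coefficients,
                "lambda": model.lambda_,
                "cutoff": model.cutoff,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return model


@_stage("evaluate")
def _evaluate(cfg, X, model, surv, out):
    scores = signature.risk_score(X, model)
    groups, cutoff = signature.stratify_median(scores)
    pd.DataFrame({"risk_score": scores, "risk_group": groups}).to_csv(
        out / "risk_scores.tsv", sep="\t", index_label="sample"
    )
    hi = groups == "high"
    lr = surveval.log_rank(
        surv.loc[hi.index[hi], "time"],
        surv.loc[hi.index[hi], "event"],
        surv.loc[hi.index[~hi], "time"],
        surv.loc[hi.index[~hi], "event"],
    )
    aucs = {}
    for t in cfg.roc_horizons:
        try:
            roc = surveval.time_dependent_auc(
                scores.to_numpy(), surv["time"], surv["event"], t
            )
            aucs[t] = roc.auc
        except ValueError as exc:
            log.warning("AUC horizon %s skipped: %s", t, exc)
    pd.DataFrame(
        {"horizon": list(aucs), "auc": list(aucs.values())}
    ).to_csv(out / "time_auc.tsv", sep="\t", index=False)
    evaluation = {
        "cutoff": cutoff,
        "log_rank_chi_square": lr.chi_square,
        "log_rank_p": lr.p_value,
        "auc": aucs,
        "n_high": int(hi.sum()),
        "n_low": int((~hi).sum()),
    }
    pd.DataFrame(
        [
            {
                "chi_square": lr.chi_square,
                "p_value": lr.p_value,
                "n_high": int(hi.sum()),
                "n_low": int((~hi).sum()),
            }
        ]
    ).to_csv(out / "log_rank.tsv", sep="\t", index=False)
    return scores, groups, evaluation
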