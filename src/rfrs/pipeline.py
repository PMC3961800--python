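"""End-to-end pipeline: assemble -> status -> filter -> split -> train
-> compact -> calibrate -> validate, with every intermediate written as
TSV plus a JSON run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly import (NO_RELAPSE, RELAPSE, binarize_ten_year, deduplicate,
                       detect_duplicates, filter_eligibility, stratified_split)
from .calibration import RiskCalibrator, assign_groups
from .containers import ClinicalTable, ExpressionMatrix, InputError
from .filtering import FilterConfig, filter_features
from .forest import RfrsClassifier, roc_auc
from .markers import call_status
from .signature import Signature, compact, deduplicate_features, eight_gene_variant
from .simulate import ER_FEATURE, HER2_FEATURES, SimulationConfig, generate_cohort
from .survival import logrank_trend

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and knobs for a full run.

    Either ``expression_path``/``clinical_path`` (tab-delimited, see
    containers) or ``simulate`` must be provided.
    """

    expression_path: str | None = None
    gene_map_path: str | None = None
    clinical_path: str | None = None
    simulate: SimulationConfig | None = None
    er_feature: str = ER_FEATURE
    her2_features: tuple = HER2_FEATURES
    n_trees: int = 100001
    train_fraction: float = 2.0 / 3.0
    filter: FilterConfig = field(default_factory=FilterConfig)
    top_n: int = 100
    k_large: int = 20
    k_small: int = 8
    exclusions: tuple = ()
    target_prevalence: float = 0.15
    n_iterations: int = 1000
    seed: int = 0


@dataclass
class PipelineResult:
    split: object
    model: RfrsClassifier
    signature_large: Signature
    signature_small: Signature
    calibrator: RiskCalibrator
    metrics: dict
    manifest: dict


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    def stage(name):
        timings[name] = time.perf_counter()
        logger.info("stage %s", name)

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    # ---- load / simulate --------------------------------------------
    stage("load")
    if config.simulate is not None:
        cohort = generate_cohort(config.simulate)
        expr, clinical = cohort.expression, cohort.clinical
    elif config.expression_path and config.clinical_path:
        expr = ExpressionMatrix.from_tsv(config.expression_path, config.gene_map_path)
        clinical = ClinicalTable.from_tsv(config.clinical_path)
    else:
        raise InputError("config must provide input paths or a simulation config")
    counts["input_samples"] = expr.n_samples
    done("load")

    # ---- duplicates --------------------------------------------------
    stage("assemble")
    groups = detect_duplicates(expr, clinical)
    expr, clinical = deduplicate(expr, clinical, groups)
    counts["duplicate_groups"] = len(groups)
    counts["after_dedup"] = expr.n_samples
    done("assemble")

    # ---- marker status ----------------------------------------------
    stage("status")
    status = call_status(expr, config.er_feature, config.her2_features, seed=config.seed)
    status.reset_index(names="sample_id").to_csv(out / "status.tsv", sep="\t", index=False)
    done("status")

    # ---- eligibility + outcome --------------------------------------
    stage("eligibility")
    eligible, reasons = filter_eligibility(clinical, status)
    _write(reasons, out / "eligibility.tsv")
    counts["eligible"] = len(eligible)
    if len(eligible) < 40:
        raise InputError(f"only {len(eligible)} eligible samples; cohort too small")
    expr = expr.subset(samples=eligible)
    clinical = clinical.loc(eligible)
    labels = binarize_ten_year(clinical)
    counts["ten_year_relapse"] = int((labels == RELAPSE).sum())
    counts["ten_year_no_relapse"] = int((labels == NO_RELAPSE).sum())
    done("eligibility")

    # ---- split -------------------------------------------------------
    stage("split")
    strata = pd.DataFrame({
        "sample_id": clinical.data["sample_id"],
        "study_id": clinical.data["study_id"],
        "class": labels.loc[clinical.data["sample_id"]].to_numpy(),
    })
    split = stratified_split(strata, config.train_fraction, seed=config.seed)
    _write(pd.DataFrame({
        "sample_id": split.train_ids + split.test_ids,
        "partition": ["train"] * len(split.train_ids) + ["test"] * len(split.test_ids),
    }), out / "split.tsv")
    _write(split.report, out / "split_report.tsv")
    counts["train"], counts["test"] = len(split.train_ids), len(split.test_ids)
    done("split")

    # ---- feature filtering (training samples only) -------------------
    stage("filter")
    train_expr = expr.subset(samples=split.train_ids)
    retained = filter_features(train_expr, config.filter)
    counts["retained_features"] = len(retained)
    pd.DataFrame({"feature_id": retained}).to_csv(out / "retained_features.tsv",
                                                  sep="\t", index=False)
    done("filter")

    # ---- train -------------------------------------------------------
    stage("train")
    train_cls = [s for s in split.train_ids if labels[s] in (RELAPSE, NO_RELAPSE)]
    test_cls = [s for s in split.test_ids if labels[s] in (RELAPSE, NO_RELAPSE)]
    X_train = expr.subset(samples=train_cls, features=retained).values
    y_train = labels.loc[train_cls].to_numpy()
    model = RfrsClassifier(n_trees=config.n_trees, random_state=config.seed).fit(X_train, y_train)
    oob = model.oob_scores_
    metrics = {"oob_auc": roc_auc(oob.dropna(), labels.loc[oob.dropna().index].to_numpy())}
    oob.rename("rfrs").rename_axis("sample_id").reset_index().to_csv(out / "oob_scores.tsv",
                                                             sep="\t", index=False)
    model.save(out / "model.joblib")
    done("train")

    # ---- compact -----------------------------------------------------
    stage("compact")
    gene_rank = deduplicate_features(model.feature_importances_, expr.feature_to_gene)
    gene_to_feature = gene_rank.attrs["gene_to_feature"]
    expr_genes = X_train.rename(columns={f: g for g, f in gene_to_feature.items()})
    top_n = min(config.top_n, len(gene_rank))
    sig_large = compact(gene_rank, expr_genes, k=min(config.k_large, top_n),
                        top_n=top_n, exclusions=config.exclusions, seed=config.seed)
    sig_small = eight_gene_variant(gene_rank, expr_genes,
                                   exclusions=config.exclusions, seed=config.seed)
    _write(sig_large.to_frame(), out / "signature_large.tsv")
    _write(sig_large.to_long_frame(), out / "signature_large_long.tsv")
    _write(sig_small.to_frame(), out / "signature_small.tsv")
    _write(sig_small.to_long_frame(), out / "signature_small_long.tsv")
    counts["signature_large_primaries"] = len(sig_large.primaries)
    counts["signature_small_primaries"] = len(sig_small.primaries)
    done("compact")

    # ---- calibrate ---------------------------------------------------
    stage("calibrate")
    calibrator = RiskCalibrator(
        target_prevalence=config.target_prevalence, n_iterations=config.n_iterations,
        random_state=config.seed, quantile_fallback=True,
    ).fit(oob, (labels.loc[oob.index] == RELAPSE).to_numpy())
    calibrator.bundle_.save(out / "calibration.joblib")
    _write(calibrator.curve_.to_frame(), out / "calibration_curve.tsv")
    gr = calibrator.group_rates_.reset_index(names="group")
    _write(gr, out / "group_rates.tsv")
    metrics["thresholds"] = (calibrator.thresholds_.t_low, calibrator.thresholds_.t_high)
    metrics["monotone_fraction"] = calibrator.group_rates_.attrs["monotone_fraction"]
    done("calibrate")

    # ---- validate ----------------------------------------------------
    stage("validate")
    X_test = expr.subset(samples=test_cls, features=retained).values
    test_scores = model.predict_score(X_test)
    y_test = labels.loc[test_cls].to_numpy()
    metrics["test_auc"] = roc_auc(test_scores, y_test)
    test_scores.rename("rfrs").rename_axis("sample_id").reset_index().to_csv(
        out / "test_scores.tsv", sep="\t", index=False)

    # retrained signature models, validated on the same test samples
    for name, sig in (("signature_large", sig_large), ("signature_small", sig_small)):
        feats = [gene_to_feature[g] for g in sig.primaries]
        sub = RfrsClassifier(n_trees=config.n_trees, random_state=config.seed).fit(
            expr.subset(samples=train_cls, features=feats).values, y_train)
        metrics[f"{name}_test_auc"] = roc_auc(
            sub.predict_score(expr.subset(samples=test_cls, features=feats).values), y_test)

    # survival across risk groups on all test samples (censoring allowed)
    surv = clinical.loc(split.test_ids).data
    surv = surv[surv["followup_years"] > 0]
    all_test_scores = model.predict_score(
        expr.subset(samples=list(surv["sample_id"]), features=retained).values)
    surv_groups = assign_groups(all_test_scores, calibrator.thresholds_)
    if surv_groups.nunique() >= 2:
        trend = logrank_trend(surv["followup_years"], surv["relapse_event"],
                              surv_groups.loc[surv["sample_id"]].to_numpy())
        metrics["trend_statistic"] = trend.statistic
        metrics["trend_p"] = trend.p_value
    done("validate")

    # ---- manifest ----------------------------------------------------
    cfg_dict = asdict(config)
    cfg_dict["filter"] = asdict(config.filter)
    if config.simulate is not None:
        cfg_dict["simulate"] = asdict(config.simulate)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()).hexdigest(),
        "counts": counts,
        "metrics": {k: (list(v) if isinstance(v, tuple) else v) for k, v in metrics.items()},
        "outputs": {p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))},
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return PipelineResult(split, model, sig_large, sig_small, calibrator, metrics, manifest)
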