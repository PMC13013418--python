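"""End-to-end tabular pipeline: harmonise → filter → screen → standardise →
RPV → composite signature → risk stratification → evaluation.

All parameters (ComBat estimates, retained feature lists, z-score means,
elastic-net coefficients, k-means centres) are fitted on the training split
only; validation cohorts are scored through the frozen
:class:`~nhocrad.survmodel.FittedSignature` objects, which is what makes
external testing leakage-free by construction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as ch
from . import survmodel as sm

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    icc_threshold: float = 0.8
    r_threshold: float = 0.9
    fdr_q: float = 0.01
    elasticnet_alpha: float = 0.5
    elasticnet_lambda: float | str = "cv"
    cv_folds: int = 5
    horizon_days: float = sm.DEFAULT_HORIZON_DAYS
    composite_components: tuple[str, ...] = sm.NLCEV_DEFAULT_COMPONENTS
    seed: int = 0

    def to_json(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class PipelineResult:
    rpv: sm.FittedSignature
    composite: sm.FittedSignature
    zscore_params: ch.ZScoreParams
    retained_features: list[str]
    stratification: sm.RiskStratification
    train_eval: sm.SurvivalEvaluation
    valid_eval: sm.SurvivalEvaluation | None
    dropped: dict


def run_pipeline(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    train_ids: list,
    valid_ids: list | None = None,
    config: PipelineConfig = PipelineConfig(),
    features_repeat: pd.DataFrame | None = None,
) -> PipelineResult:
    """Fit the full signature chain on the training split and evaluate.

    ``clinical`` must carry time_days, event, stage_simple and nhoc columns.
    ``features_repeat`` (a second reader/repeat extraction) enables the ICC
    reproducibility filter; without it that step is skipped.
    """
    clinical = ch.validate_clinical(clinical)
    train_ids = list(train_ids)
    valid_ids = list(valid_ids) if valid_ids is not None else []
    dropped = {}

    # 1. ComBat across sites (fitted jointly before outcome modelling)
    if "site" in clinical.columns and clinical["site"].nunique() > 1:
        features = ch.combat_harmonise(features, clinical.loc[features.index, "site"])

    # 2. ICC reproducibility filter (training-independent, reader-based)
    if features_repeat is not None:
        icc = ch.icc_filter(features, features_repeat, threshold=config.icc_threshold)
        keep = [r.feature_name for r in icc if r.retained]
        dropped["icc"] = [r.feature_name for r in icc if not r.retained]
        features = features[keep]

    train_feats = features.loc[train_ids]

    # 3. correlation pruning on the training set
    pruned, dropped_corr = ch.prune_correlated(train_feats, r_threshold=config.r_threshold)
    dropped["correlation"] = dropped_corr
    features = features[pruned.columns]

    # 4. univariable Cox FDR screen on the training set
    screen = ch.univariable_cox_screen(
        features.loc[train_ids], clinical.loc[train_ids], q_threshold=config.fdr_q
    )
    retained = [r.feature_name for r in screen if r.retained]
    dropped["screen"] = [r.feature_name for r in screen if not r.retained]
    if not retained:
        raise ValueError("no feature survived the univariable FDR screen")
    features = features[retained]

    # 5. z-score standardisation fitted on training
    standardised, zparams = ch.zscore(features, fit_on=train_ids)

    # 6. elastic-net Cox RPV
    rpv = sm.fit_rpv(
        standardised.loc[train_ids], clinical.loc[train_ids],
        alpha=config.elasticnet_alpha, lam=config.elasticnet_lambda,
        n_folds=config.cv_folds, seed=config.seed,
    )

    # 7. composite signature over RPV + NHOC + stage
    comp_table = pd.DataFrame({
        "rpv": rpv.score(standardised),
        "nhoc": clinical.loc[standardised.index, "nhoc"],
        "stage_simple": clinical.loc[standardised.index, "stage_simple"],
    })
    composite = sm.fit_composite(
        comp_table.loc[train_ids], clinical.loc[train_ids],
        which="nLCEV", columns=config.composite_components,
    )

    # 8. risk stratification by 1-D k-means on training scores
    train_scores = composite.score(comp_table.loc[train_ids])
    strat = sm.stratify_kmeans(train_scores)

    train_eval = sm.evaluate(
        strat.assign(train_scores), clinical.loc[train_ids],
        scores=train_scores, horizon_days=config.horizon_days,
    )
    valid_eval = None
    if valid_ids:
        valid_scores = composite.score(comp_table.loc[valid_ids])
        valid_eval = sm.evaluate(
            strat.assign(valid_scores), clinical.loc[valid_ids],
            scores=valid_scores, horizon_days=config.horizon_days,
        )

    return PipelineResult(
        rpv=rpv, composite=composite, zscore_params=zparams,
        retained_features=retained, stratification=strat,
        train_eval=train_eval, valid_eval=valid_eval, dropped=dropped,
    )


def save_artifacts(result: PipelineResult, out_dir: str | Path, config: PipelineConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.rpv.to_json(out / "rpv.json")
    result.composite.to_json(out / "nlcev.json")
    (out / "zscore.json").write_text(json.dumps(result.zscore_params.to_dict(), sort_keys=True))
    (out / "stratification.json").write_text(json.dumps({
        "centre_low": result.stratification.centre_low,
        "centre_high": result.stratification.centre_high,
    }, sort_keys=True))
    (out / "config.json").write_text(config.to_json())
    report = {"train": result.train_eval.to_dict()}
    if result.valid_eval is not None:
        report["validation"] = result.valid_eval.to_dict()
    (out / "evaluation.json").write_text(json.dumps(report, indent=2, sort_keys=True))


def score_external(
    artifact_dir: str | Path,
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    horizon_days: float = sm.DEFAULT_HORIZON_DAYS,
) -> sm.SurvivalEvaluation:
    """Score an external cohort using only serialized training parameters."""
    art = Path(artifact_dir)
    rpv = sm.FittedSignature.from_json(art / "rpv.json")
    composite = sm.FittedSignature.from_json(art / "nlcev.json")
    zparams = ch.ZScoreParams.from_dict(json.loads((art / "zscore.json").read_text()))
    strat_d = json.loads((art / "stratification.json").read_text())
    strat = sm.RiskStratification(
        centre_low=strat_d["centre_low"], centre_high=strat_d["centre_high"], labels={}
    )
    standardised = zparams.transform(features)
    comp = pd.DataFrame({
        "rpv": rpv.score(standardised),
        "nhoc": clinical.loc[standardised.index, "nhoc"],
        "stage_simple": clinical.loc[standardised.index, "stage_simple"],
    })
    scores = composite.score(comp)
    return sm.evaluate(strat.assign(scores), clinical, scores=scores,
                       horizon_days=horizon_days)
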