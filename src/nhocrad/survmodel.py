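"""Composite survival signatures and their evaluation.

The radiomics predictive vector (RPV) is the linear predictor of an
elastic-net-penalised Cox model over the screened, standardised radiomic
features.  The non-invasive lung cancer evolution vector (nLCEV) combines
RPV with NHOC and simplified disease stage in an unpenalised multivariable
Cox model; the stage-metabolic model (SMM) benchmark combines stage,
SUVmax, MTV and TLG the same way.  Patients are stratified into high/low
risk by one-dimensional two-cluster k-means on the training scores, and
groups are compared with Kaplan–Meier curves, the log-rank test, the Cox
hazard ratio of the group indicator, and the ROC AUC for 3-year overall
survival.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .cohort import validate_clinical

logger = logging.getLogger(__name__)

NLCEV_DEFAULT_COMPONENTS = ("rpv", "nhoc", "stage_simple")
SMM_COMPONENTS = ("stage_simple", "suv_max", "mtv_ml", "tlg")
DEFAULT_HORIZON_DAYS = 1095  # 3-year overall survival


@dataclass
class FittedSignature:
    """A named linear survival signature with its standardisation parameters."""

    name: str
    coefficients: dict[str, float]
    standardisation: dict[str, tuple[float, float]] = field(default_factory=dict)
    hyperparams: dict = field(default_factory=dict)
    training_ids: list[str] = field(default_factory=list)

    def score(self, table: pd.DataFrame) -> pd.Series:
        """Linear predictor Σ coef × standardised value for each row."""
        total = pd.Series(0.0, index=table.index)
        for feat, coef in self.coefficients.items():
            x = table[feat].astype(float)
            if feat in self.standardisation:
                mu, sd = self.standardisation[feat]
                x = (x - mu) / sd
            total = total + coef * x
        total.name = self.name
        return total

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({
            "name": self.name,
            "coefficients": self.coefficients,
            "standardisation": {k: list(v) for k, v in self.standardisation.items()},
            "hyperparams": self.hyperparams,
            "training_ids": self.training_ids,
        }, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, src: str | Path) -> "FittedSignature":
        text = Path(src).read_text() if Path(str(src)).exists() else str(src)
        d = json.loads(text)
        return cls(
            name=d["name"],
            coefficients=d["coefficients"],
            standardisation={k: tuple(v) for k, v in d["standardisation"].items()},
            hyperparams=d["hyperparams"],
            training_ids=d["training_ids"],
        )


def _surv_y(clinical: pd.DataFrame, ids) -> np.ndarray:
    c = clinical.loc[ids]
    return Surv.from_arrays(event=c["event"].astype(bool), time=c["time_days"])


def fit_rpv(
    train: pd.DataFrame,
    clinical: pd.DataFrame,
    alpha: float = 0.5,
    lam: float | str = "cv",
    n_folds: int = 5,
    seed: int = 0,
) -> FittedSignature:
    """Elastic-net Cox fit of the radiomics predictive vector.

    ``alpha`` is the L1/L2 mixing (1 = lasso); ``lam`` the penalty
    strength, chosen by k-fold cross-validated partial-likelihood deviance
    along the regularisation path when "cv".  Input features are assumed
    already standardised by the cohort pipeline.
    """
    clinical = validate_clinical(clinical)
    ids = list(train.index.intersection(clinical.index))
    if int(clinical.loc[ids, "event"].sum()) < 10:
        raise ValueError("fewer than 10 events in the training set")
    X = train.loc[ids].to_numpy(float)
    y = _surv_y(clinical, ids)

    if lam == "cv":
        path_model = CoxnetSurvivalAnalysis(l1_ratio=alpha, alpha_min_ratio=0.01,
                                            n_alphas=30, normalize=False)
        path_model.fit(X, y)
        alphas = path_model.alphas_
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(ids))
        folds = np.array_split(order, n_folds)
        scores = np.zeros(len(alphas))
        for fold in folds:
            mask = np.ones(len(ids), bool)
            mask[fold] = False
            m = CoxnetSurvivalAnalysis(l1_ratio=alpha, alphas=alphas, normalize=False)
            m.fit(X[mask], y[mask])
            for j, a in enumerate(alphas):
                lp_all = m.predict(X, alpha=a)
                # held-out deviance via full-vs-train log partial likelihood difference
                scores[j] += _cox_log_partial_likelihood(lp_all, clinical.loc[ids]) - \
                    _cox_log_partial_likelihood(lp_all[mask], clinical.loc[np.asarray(ids)[mask]])
        best = int(np.argmax(scores))
        lam = float(alphas[best])

    model = CoxnetSurvivalAnalysis(l1_ratio=alpha, alphas=[lam], normalize=False)
    model.fit(X, y)
    coefs = model.coef_[:, 0]
    nz = np.abs(coefs) > 0
    if not nz.any():
        raise ValueError(
            f"all coefficients are zero at lambda={lam:g}: choose a smaller penalty"
        )
    return FittedSignature(
        name="RPV",
        coefficients={f: float(c) for f, c in zip(train.columns, coefs) if abs(c) > 0},
        hyperparams={"alpha": alpha, "lambda": lam, "cv_folds": n_folds, "seed": seed},
        training_ids=[str(i) for i in ids],
    )


def _cox_log_partial_likelihood(lp: np.ndarray, clinical: pd.DataFrame) -> float:
    """Breslow log partial likelihood of a fixed linear predictor."""
    t = clinical["time_days"].to_numpy(float)
    e = clinical["event"].to_numpy(int)
    order = np.argsort(t)
    t, e, lp = t[order], e[order], np.asarray(lp)[order]
    exp_lp = np.exp(lp - lp.max())
    # risk set sums from the end
    rev_cumsum = np.cumsum(exp_lp[::-1])[::-1]
    ll = 0.0
    for i in np.nonzero(e)[0]:
        at_risk = rev_cumsum[np.searchsorted(t, t[i], side="left")]
        ll += (lp[i] - lp.max()) - np.log(at_risk)
    return float(ll)


def fit_composite(
    components: pd.DataFrame,
    clinical: pd.DataFrame,
    which: str = "nLCEV",
    columns: tuple[str, ...] | None = None,
    condition_limit: float = 1e8,
) -> FittedSignature:
    """Unpenalised multivariable Cox composite (nLCEV or SMM).

    nLCEV combines RPV + NHOC + simplified stage; SMM combines stage +
    SUVmax + MTV + TLG.  Per-covariate hazard ratios with 95% CIs are
    stored in the hyperparams.  Collinear inputs raise with the offending
    pair named.
    """
    clinical = validate_clinical(clinical)
    if columns is None:
        columns = NLCEV_DEFAULT_COMPONENTS if which == "nLCEV" else SMM_COMPONENTS
    missing = [c for c in columns if c not in components.columns]
    if missing:
        raise ValueError(f"missing component columns {missing}")
    ids = components.index.intersection(clinical.index)
    X = components.loc[ids, list(columns)].astype(float)

    corr = X.corr().to_numpy()
    xs = (X - X.mean()) / X.std(ddof=0).replace(0, 1)
    cond = np.linalg.cond(xs.T @ xs / len(xs))
    if cond > condition_limit:
        iu = np.triu_indices(len(columns), 1)
        worst = int(np.nanargmax(np.abs(corr[iu])))
        a, b = columns[iu[0][worst]], columns[iu[1][worst]]
        raise ValueError(f"collinear components: {a!r} and {b!r} (condition {cond:.2g})")

    df = X.copy()
    df["time"] = clinical.loc[ids, "time_days"]
    df["event"] = clinical.loc[ids, "event"]
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summary = cph.summary
    return FittedSignature(
        name=which,
        coefficients={c: float(cph.params_[c]) for c in columns},
        hyperparams={
            "hr": {c: float(np.exp(cph.params_[c])) for c in columns},
            "hr_ci95": {
                c: [float(np.exp(summary.loc[c, "coef lower 95%"])),
                    float(np.exp(summary.loc[c, "coef upper 95%"]))]
                for c in columns
            },
            "wald_p": {c: float(summary.loc[c, "p"]) for c in columns},
        },
        training_ids=[str(i) for i in ids],
    )


# ---------------------------------------------------------------------------
# Risk stratification


@dataclass
class RiskStratification:
    centre_low: float
    centre_high: float
    labels: dict[str, str]  # patient_id → "low" | "high"

    @property
    def decision_boundary(self) -> float:
        return 0.5 * (self.centre_low + self.centre_high)

    def assign(self, scores: pd.Series) -> pd.Series:
        return pd.Series(
            np.where(scores > self.decision_boundary, "high", "low"), index=scores.index
        )


def stratify_kmeans(train_scores: pd.Series, apply_to: pd.Series | None = None) -> RiskStratification:
    """Two-cluster 1-D k-means on signature scores.

    Deterministic: centres start at the 25th/75th training percentiles and
    Lloyd iterations run to convergence (1-D k-means needs no restarts).
    High risk is the cluster with the larger centre; new samples go to the
    nearer centre.
    """
    s = train_scores.to_numpy(float)
    if np.unique(s).size < 2:
        raise ValueError("all training scores identical: cannot stratify")
    c = np.percentile(s, [25, 75]).astype(float)
    if c[0] == c[1]:
        c = np.array([s.min(), s.max()], float)
    for _ in range(200):
        assign = np.abs(s[:, None] - c[None, :]).argmin(axis=1)
        new_c = np.array([
            s[assign == k].mean() if (assign == k).any() else c[k] for k in (0, 1)
        ])
        if np.allclose(new_c, c):
            break
        c = new_c
    lo, hi = sorted(c)
    strat = RiskStratification(centre_low=float(lo), centre_high=float(hi), labels={})
    target = apply_to if apply_to is not None else train_scores
    strat.labels = strat.assign(target).to_dict()
    return strat


# ---------------------------------------------------------------------------
# Evaluation


@dataclass
class SurvivalEvaluation:
    km_curves: dict[str, pd.DataFrame]
    logrank_chi2: float
    logrank_p: float
    hr: float
    hr_ci95: tuple[float, float]
    auc_3yr: float
    n_excluded_censored: int
    n_per_group: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "logrank_chi2": self.logrank_chi2, "logrank_p": self.logrank_p,
            "hr": self.hr, "hr_ci95": list(self.hr_ci95), "auc_3yr": self.auc_3yr,
            "n_excluded_censored": self.n_excluded_censored,
            "n_per_group": self.n_per_group,
        }


def roc_auc_at_horizon(
    scores: pd.Series, clinical: pd.DataFrame, horizon_days: float = DEFAULT_HORIZON_DAYS
) -> tuple[float, int]:
    """AUC for death-by-horizon, with pre-horizon censored patients excluded.

    Positives died before the horizon; negatives were followed beyond it.
    Patients censored before the horizon carry no 3-year status and are
    excluded (their count is returned).  The AUC is the Mann–Whitney rank
    statistic with the half-credit tie convention.
    """
    ids = scores.index.intersection(clinical.index)
    t = clinical.loc[ids, "time_days"].to_numpy(float)
    e = clinical.loc[ids, "event"].to_numpy(int)
    s = scores.loc[ids].to_numpy(float)
    positive = (e == 1) & (t <= horizon_days)
    negative = t > horizon_days
    excluded = int((~positive & ~negative).sum())
    pos, neg = s[positive], s[negative]
    if len(pos) == 0 or len(neg) == 0:
        return float("nan"), excluded
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg))), excluded


def evaluate(
    groups: pd.Series,
    clinical: pd.DataFrame,
    scores: pd.Series | None = None,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> SurvivalEvaluation:
    """Compare high- vs low-risk groups: KM, log-rank, HR, 3-year AUC.

    ``groups`` maps patient id → "low"/"high".  The hazard ratio comes from
    a univariable Cox fit on the high-group indicator (non-estimable when a
    group has no events, reported as NaN with KM/log-rank still produced).
    The AUC uses the continuous ``scores`` when given, else the binary
    group indicator.
    """
    clinical = validate_clinical(clinical)
    ids = groups.index.intersection(clinical.index)
    g = groups.loc[ids]
    for name in ("low", "high"):
        if (g == name).sum() == 0:
            raise ValueError(f"group {name!r} is empty")
    t = clinical.loc[ids, "time_days"]
    e = clinical.loc[ids, "event"]

    km = {}
    for name in ("low", "high"):
        kmf = KaplanMeierFitter()
        kmf.fit(t[g == name], e[g == name], label=name)
        curve = kmf.survival_function_.copy()
        ci = kmf.confidence_interval_
        curve["ci_lower"] = ci.iloc[:, 0]
        curve["ci_upper"] = ci.iloc[:, 1]
        km[name] = curve

    lr = logrank_test(t[g == "high"], t[g == "low"], e[g == "high"], e[g == "low"])

    hr, ci = float("nan"), (float("nan"), float("nan"))
    if e[g == "high"].sum() > 0 and e[g == "low"].sum() > 0:
        df = pd.DataFrame({"time": t, "event": e, "high": (g == "high").astype(int)})
        try:
            cph = CoxPHFitter()
            cph.fit(df, duration_col="time", event_col="event")
            hr = float(np.exp(cph.params_["high"]))
            ci = (
                float(np.exp(cph.summary.loc["high", "coef lower 95%"])),
                float(np.exp(cph.summary.loc["high", "coef upper 95%"])),
            )
        except Exception as exc:
            logger.warning("HR non-estimable: %s", exc)
    else:
        logger.warning("a group has zero events: HR non-estimable")

    auc_scores = scores if scores is not None else (g == "high").astype(float)
    auc, n_excl = roc_auc_at_horizon(auc_scores, clinical.loc[ids], horizon_days)

    return SurvivalEvaluation(
        km_curves=km,
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        hr=hr,
        hr_ci95=ci,
        auc_3yr=auc,
        n_excluded_censored=n_excl,
        n_per_group={"low": int((g == "low").sum()), "high": int((g == "high").sum())},
    )
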