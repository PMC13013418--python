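"""Cohort-level feature processing between extraction and modelling.

Fixed pipeline order (training parameters only, never refit on validation):

    ComBat harmonisation → ICC reproducibility filter → correlation
    pruning → univariable Cox FDR screen → z-score standardisation

Thresholds follow the study defaults: ICC(2,1) ≥ 0.8, |Pearson r| > 0.9
redundancy, Benjamini–Hochberg FDR q ≤ 0.01 on univariable Cox Wald tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CLINICAL_COLUMNS = ("time_days", "event")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient's outcome and covariates."""

    patient_id: str
    time_days: float
    event: int
    stage_simple: int | None = None
    stage_t: int | None = None
    stage_n: int | None = None
    stage_m: int | None = None
    age_years: float | None = None
    site: str = "site1"
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.time_days <= 0:
            raise ValueError("time_days must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.stage_simple is not None and self.stage_simple not in (1, 2, 3, 4):
            raise ValueError("stage_simple must be in 1..4")


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id, "time_days": r.time_days, "event": r.event,
               "stage_simple": r.stage_simple, "stage_t": r.stage_t,
               "stage_n": r.stage_n, "stage_m": r.stage_m,
               "age_years": r.age_years, "site": r.site}
        row.update(r.extra)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def validate_clinical(df: pd.DataFrame) -> pd.DataFrame:
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    if (df["time_days"] <= 0).any():
        raise ValueError("time_days must be positive")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event must be 0/1")
    return df


# ---------------------------------------------------------------------------
# ComBat harmonisation (parametric empirical Bayes)


def combat_harmonise(
    table: pd.DataFrame,
    batch: pd.Series | np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Remove additive and multiplicative scanner/site batch effects.

    Parametric empirical-Bayes location/scale adjustment: per-feature batch
    means and variances are shrunk towards batch-level priors (normal for
    locations, inverse-gamma for scales) and divided out on the standardised
    scale.  A single batch is the identity; a batch with one sample is an
    error because its variance is undefined.
    """
    batch = pd.Series(np.asarray(batch), index=table.index)
    groups = batch.unique()
    if len(groups) == 1:
        return table.copy()
    counts = batch.value_counts()
    singles = counts[counts < 2]
    if len(singles):
        raise ValueError(f"batch {singles.index[0]!r} has a single sample")

    X = table.to_numpy(dtype=float).T  # features × samples
    n_feat, n_samp = X.shape
    onehot = np.stack([(batch == g).to_numpy(float) for g in groups])  # batches × samples
    n_per = onehot.sum(axis=1)

    batch_means = (onehot @ X.T).T / n_per  # features × batches
    grand = batch_means @ (n_per / n_samp)
    resid = X - batch_means @ onehot
    pooled_var = (resid**2).mean(axis=1)
    pooled_sd = np.sqrt(np.maximum(pooled_var, np.finfo(float).tiny))

    Z = (X - grand[:, None]) / pooled_sd[:, None]

    X_adj = Z.copy()
    for b, g in enumerate(groups):
        cols = onehot[b].astype(bool)
        zb = Z[:, cols]
        n_b = int(n_per[b])
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)

        # hyperpriors by method of moments
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        lam = (2 * d_var + d_mean**2) / max(d_var, np.finfo(float).tiny)
        theta = (d_mean * d_var + d_mean**3) / max(d_var, np.finfo(float).tiny)

        gamma_star = gamma_hat.copy()
        delta_star = delta_hat.copy()
        for _ in range(max_iter):
            g_new = (n_b * tau2 * gamma_hat + delta_star * gamma_bar) / (
                n_b * tau2 + delta_star
            )
            ss = ((zb - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta + 0.5 * ss) / (n_b / 2.0 + lam - 1.0)
            change = max(np.abs(g_new - gamma_star).max(), np.abs(d_new - delta_star).max())
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break

        X_adj[:, cols] = (zb - gamma_star[:, None]) / np.sqrt(delta_star)[:, None]

    out = X_adj * pooled_sd[:, None] + grand[:, None]
    return pd.DataFrame(out.T, index=table.index, columns=table.columns)


# ---------------------------------------------------------------------------
# z-score standardisation


@dataclass
class ZScoreParams:
    mean: pd.Series
    sd: pd.Series  # population (n-denominator) standard deviation

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        cols = self.mean.index
        return (table[cols] - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.to_dict(), "sd": self.sd.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "ZScoreParams":
        return cls(mean=pd.Series(d["mean"]), sd=pd.Series(d["sd"]))


def zscore(table: pd.DataFrame, fit_on: list | None = None) -> tuple[pd.DataFrame, ZScoreParams]:
    """Standardise features to mean 0 / SD 1 on the training rows.

    The (mean, sd) pairs are fitted on ``fit_on`` rows only (all rows if
    None) and returned so validation cohorts are transformed with the
    training parameters.  Population (n-denominator) SD.  Zero-variance
    features are dropped with a warning.
    """
    train = table if fit_on is None else table.loc[fit_on]
    mean = train.mean()
    sd = train.std(ddof=0)
    keep = sd > 0
    dropped = list(sd.index[~keep])
    if dropped:
        logger.warning("dropping %d zero-variance feature(s): %s…", len(dropped), dropped[:3])
    params = ZScoreParams(mean=mean[keep], sd=sd[keep])
    return params.transform(table), params


# ---------------------------------------------------------------------------
# ICC(2,1) reproducibility filter


@dataclass(frozen=True)
class ICCResult:
    feature_name: str
    icc: float
    retained: bool


def icc_2_1(a: np.ndarray, b: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, single measurement, absolute agreement.

    From the two-way ANOVA mean squares with n subjects and k=2 raters:
        ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + k (MS_C − MS_E)/n)
    """
    x = np.column_stack([np.asarray(a, float), np.asarray(b, float)])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    if denom == 0:
        return 1.0
    return float((ms_r - ms_e) / denom)


def icc_filter(
    table_a: pd.DataFrame, table_b: pd.DataFrame, threshold: float = 0.8
) -> list[ICCResult]:
    """Per-feature inter-observer ICC(2,1) between two readers/repeats.

    Features with ICC ≥ threshold (default 0.8) are flagged as retained.
    """
    common = table_a.index.intersection(table_b.index)
    if len(common) < 3:
        raise ValueError("ICC requires at least 3 shared patients")
    feats = table_a.columns.intersection(table_b.columns)
    results = []
    for f in feats:
        icc = icc_2_1(table_a.loc[common, f].to_numpy(), table_b.loc[common, f].to_numpy())
        results.append(ICCResult(feature_name=f, icc=icc, retained=icc >= threshold))
    return results


# ---------------------------------------------------------------------------
# Correlation pruning


def prune_correlated(
    table: pd.DataFrame, r_threshold: float = 0.9
) -> tuple[pd.DataFrame, list[str]]:
    """Drop one member of every feature pair with |Pearson r| above threshold.

    Pairs are processed in decreasing |r|; the lower-variance member of each
    pair is dropped (ties broken by lexicographic name, the later name
    dropped), so the result is deterministic.  Returns the pruned table and
    the dropped names.
    """
    if len(table) < 3:
        raise ValueError("correlation pruning needs at least 3 samples")
    corr = table.corr().abs()
    cols = list(table.columns)
    var = table.var(ddof=0)
    pairs = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and r > r_threshold:
                pairs.append((float(r), a, b))
    pairs.sort(key=lambda p: (-p[0], p[1], p[2]))
    dropped: set[str] = set()
    for _, a, b in pairs:
        if a in dropped or b in dropped:
            continue
        if var[a] < var[b] or (var[a] == var[b] and a > b):
            dropped.add(a)
        else:
            dropped.add(b)
    if dropped:
        logger.info("correlation pruning dropped %d feature(s)", len(dropped))
    keep = [c for c in cols if c not in dropped]
    return table[keep], sorted(dropped)


# ---------------------------------------------------------------------------
# Univariable Cox FDR screen


@dataclass(frozen=True)
class ScreenResult:
    feature_name: str
    cox_beta: float
    wald_p: float
    fdr_q: float
    retained: bool


def cox_univariable(x, time_days, event) -> tuple[float, float]:
    """Single-covariate Cox PH fit (Efron ties): returns (beta, Wald p)."""
    df = pd.DataFrame({"time": np.asarray(time_days, float),
                       "event": np.asarray(event, int),
                       "x": np.asarray(x, float)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event",
            fit_options={"precision": 1e-9})
    return float(cph.params_["x"]), float(cph.summary.loc["x", "p"])


def univariable_cox_screen(
    table: pd.DataFrame,
    clinical: pd.DataFrame,
    q_threshold: float = 0.01,
) -> list[ScreenResult]:
    """Per-feature univariable Cox PH fit with Benjamini–Hochberg control.

    Each feature is fitted alone against overall survival (Efron tie
    handling); Wald p-values are corrected across all screened features and
    a feature is retained iff its q-value is at most ``q_threshold``
    (default 1% FDR).  Non-converging features are excluded and logged.
    """
    clinical = validate_clinical(clinical)
    merged_idx = table.index.intersection(clinical.index)
    n_events = int(clinical.loc[merged_idx, "event"].sum())
    if n_events < 10:
        raise ValueError(
            f"only {n_events} events: univariable screening is unreliable below 10"
        )
    betas, pvals, names, failed = [], [], [], []
    for f in table.columns:
        df = pd.DataFrame({
            "time": clinical.loc[merged_idx, "time_days"],
            "event": clinical.loc[merged_idx, "event"],
            "x": table.loc[merged_idx, f],
        })
        try:
            beta, p = cox_univariable(df["x"], df["time"], df["event"])
            betas.append(beta)
            pvals.append(p)
            names.append(f)
        except Exception as exc:  # non-convergence
            logger.warning("Cox fit failed for %r: %s", f, exc)
            failed.append(f)
    results = []
    if names:
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for f, b, p, q in zip(names, betas, pvals, qvals):
            results.append(ScreenResult(f, b, p, float(q), bool(q <= q_threshold)))
    for f in failed:
        results.append(ScreenResult(f, float("nan"), float("nan"), float("nan"), False))
    return results


def screen_report(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature_name, r.cox_beta, r.wald_p, r.fdr_q, r.retained) for r in results],
        columns=["feature", "beta", "p", "q", "retained"],
    ).set_index("feature")
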