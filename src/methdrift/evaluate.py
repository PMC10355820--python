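"""Downstream statistical designs for drift scores.

Covers the evaluation patterns used with methylation drift scores: OLS
residualization by covariates, Kruskal-Wallis group comparisons of the
residualized score, Pearson correlation with continuous covariates, and Cox
proportional-hazards models in which the score enters per standard deviation
and age per decade.  lifelines provides the partial-likelihood machinery
(Efron tie handling); statsmodels/scipy provide the rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .io import SampleSheet

__all__ = ["ScoreTable", "TestResult", "residualize", "group_test",
           "correlate", "cox_hazard", "run_design"]


@dataclass
class ScoreTable:
    """Raw and residualized scores per sample, with the covariates used."""

    sample_ids: list[str]
    raw: np.ndarray
    residual: np.ndarray
    covariates: list[str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw": self.raw, "residual": self.residual}, index=self.sample_ids
        )


@dataclass
class TestResult:
    """One statistical result: named statistic, p-value, n, extras."""

    name: str
    statistic: float
    p_value: float
    n: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def _design_matrix(sheet: SampleSheet, covariates: list[str]) -> np.ndarray:
    """Intercept + covariate columns; categoricals one-hot dropping one level."""
    n = len(sheet.sample_ids)
    cols = [np.ones(n)]
    names = ["intercept"]
    for cov in covariates:
        if cov not in sheet:
            raise KeyError(f"covariate {cov!r} not in sample sheet")
        series = sheet[cov]
        if series.isna().any():
            raise ValueError(f"covariate {cov!r} missing for some samples")
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(series.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"categorical covariate {cov!r} has <2 levels")
            for lev in levels[1:]:
                cols.append((series.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design ({rank} < {X.shape[1]}); columns: {names}"
        )
    return X


def residualize(
    scores: np.ndarray, sheet: SampleSheet, covariates: list[str]
) -> ScoreTable:
    """OLS residuals of score on intercept + covariates.

    With no covariates this is mean-centering.  Residuals are orthogonal to
    every design column; the operation is idempotent.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(sheet.sample_ids):
        raise ValueError("score length does not match sample sheet")
    X = _design_matrix(sheet, list(covariates))
    coef, *_ = np.linalg.lstsq(X, scores, rcond=None)
    residual = scores - X @ coef
    return ScoreTable(
        sample_ids=list(sheet.sample_ids),
        raw=scores,
        residual=residual,
        covariates=list(covariates),
    )


def group_test(table: ScoreTable, groups) -> TestResult:
    """Kruskal-Wallis H test of the residualized score across groups.

    Tie-corrected H, chi-square p on k-1 degrees of freedom.  When every
    observation is tied (H undefined), H = 0 and p = 1.
    """
    groups = np.asarray(groups)
    if len(groups) != len(table.residual):
        raise ValueError("group labels do not match score table")
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("group test needs at least 2 groups")
    samples = [table.residual[groups == g] for g in levels]
    for g, s in zip(levels, samples):
        if len(s) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    try:
        h, p = stats.kruskal(*samples)
    except ValueError:  # all observations identical
        h, p = 0.0, 1.0
    return TestResult(
        name="kruskal_wallis_H",
        statistic=float(h),
        p_value=float(p),
        n=int(len(groups)),
        extra={"n_groups": int(len(levels))},
    )


def correlate(x, y) -> TestResult:
    """Pearson correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return TestResult(name="pearson_r", statistic=float(r), p_value=float(p),
                      n=int(len(x)))


def cox_hazard(
    table: ScoreTable, sheet: SampleSheet, adjusters: list[str] = ()
) -> TestResult:
    """Cox proportional hazards for the score, reported per SD.

    The raw score is z-scored by its sample SD before entering the model, so
    the hazard ratio reads "per SD of score"; any ``age`` adjuster enters as
    age/10 ("per decade").  Ties are handled by the Efron approximation.
    Returns the per-SD hazard ratio with 95% CI and Wald p.
    """
    if "time" not in sheet or "event" not in sheet:
        raise KeyError("sample sheet must carry time and event columns")
    df = pd.DataFrame(index=sheet.sample_ids)
    df["time"] = sheet["time"].to_numpy(dtype=float)
    df["event"] = sheet["event"].to_numpy(dtype=float)
    if df["event"].sum() < 1:
        raise ValueError("no events in the cohort")
    sd = np.std(table.raw)
    if sd == 0:
        raise ValueError("score has zero variance")
    df["score_sd"] = (table.raw - np.mean(table.raw)) / sd
    for adj in adjusters:
        series = sheet[adj]
        if adj == "age":
            df["age_per_decade"] = series.to_numpy(dtype=float) / 10.0
        elif pd.api.types.is_numeric_dtype(series):
            df[adj] = series.to_numpy(dtype=float)
        else:
            dummies = pd.get_dummies(series.astype(str), prefix=adj,
                                     drop_first=True, dtype=float)
            dummies.index = df.index
            df = pd.concat([df, dummies], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summ = cph.summary.loc["score_sd"]
    return TestResult(
        name="cox_hr_per_sd",
        statistic=float(summ["exp(coef)"]),
        p_value=float(summ["p"]),
        n=int(len(df)),
        extra={
            "log_hr": float(summ["coef"]),
            "se_log_hr": float(summ["se(coef)"]),
            "ci_low": float(summ["exp(coef) lower 95%"]),
            "ci_high": float(summ["exp(coef) upper 95%"]),
            "n_events": int(df["event"].sum()),
        },
    )


def run_design(kind: str, scores, sheet: SampleSheet, config: dict | None = None) -> dict:
    """Run one of the canned evaluation designs and return a report dict.

    kind
        ``tumor_normal`` — residualize by ``config["covariates"]`` (default
        age, sex, tissue; only columns present are used) then Kruskal-Wallis
        across ``group``;
        ``survival`` — Cox per-SD hazard with ``config["adjusters"]``
        (default age);
        ``multi_tissue`` — Pearson r of score vs ``division_rate``;
        ``trajectory`` — per-phase Pearson r of score vs a time index, phases
        read from the ``phase`` column (a phase whose scores are degenerate
        is reported as an error entry, the others still run).
    """
    config = dict(config or {})
    scores = np.asarray(scores, dtype=float)
    report: dict = {"design": kind, "results": {}}
    if kind == "tumor_normal":
        if "group" not in sheet:
            raise KeyError("tumor_normal design requires a group column")
        wanted = config.get("covariates", ["age", "sex", "tissue"])
        covs = [c for c in wanted if c in sheet
                and (pd.api.types.is_numeric_dtype(sheet[c])
                     or sheet[c].astype(str).nunique() > 1)]
        table = residualize(scores, sheet, covs)
        res = group_test(table, sheet["group"].to_numpy())
        report["results"]["group_test"] = res
        report["covariates"] = covs
    elif kind == "survival":
        adjusters = [a for a in config.get("adjusters", ["age"]) if a in sheet]
        table = residualize(scores, sheet, [])
        report["results"]["cox"] = cox_hazard(table, sheet, adjusters)
        report["adjusters"] = adjusters
        report["ties"] = "efron"
    elif kind == "multi_tissue":
        if "division_rate" not in sheet:
            raise KeyError("multi_tissue design requires a division_rate column")
        report["results"]["correlation"] = correlate(
            scores, sheet["division_rate"].to_numpy(dtype=float))
    elif kind == "trajectory":
        if "phase" not in sheet:
            raise KeyError("trajectory design requires a phase column")
        time_col = config.get("time_column", "time_index")
        if time_col not in sheet:
            raise KeyError(f"trajectory design requires a {time_col!r} column")
        phases = sheet["phase"].astype(str)
        t = sheet[time_col].to_numpy(dtype=float)
        for phase in sorted(phases.unique()):
            mask = (phases == phase).to_numpy()
            try:
                report["results"][phase] = correlate(scores[mask], t[mask])
            except ValueError as exc:
                report["results"][phase] = {"error": str(exc)}
    else:
        raise ValueError(f"unknown design kind {kind!r}")
    return report
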