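"""Survival analysis for the muENV prognosis evaluation.

Kaplan-Meier estimation, the two-group log-rank test, Cox proportional-
hazards regression (Efron tie handling by default) and the Grambsch-Therneau
Schoenfeld-residual test of the PH assumption.  A time-varying covariate
effect (the GGI-by-time interaction of the multivariable model) is handled
by splitting each subject's follow-up at the distinct event times and
evaluating x * g(t) per risk interval, with g(t) = log(t in months) by
default — the same transform used for the Schoenfeld diagnostic, so the
fitted remediation and the diagnostic are consistent.

Fitting is delegated to lifelines (CoxPHFitter / CoxTimeVaryingFitter /
KaplanMeierFitter and the statistics module); this module owns the episode
splitting, the covariate dichotomizations of the clinical model (age > 50,
size > 2 cm, GGI > 0, all strict), and the 10-year administrative censoring
at 120 months.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test

from .core_io import CohortAnnotation

logger = logging.getLogger("muenv")

__all__ = [
    "SurvivalFit",
    "KMCurve",
    "dichotomize_covariates",
    "administrative_censor",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "schoenfeld_test",
    "TEN_YEAR_MONTHS",
]

#: administrative censoring horizon for "10-year" quantities
TEN_YEAR_MONTHS = 120.0


def _log_time(t):
    return np.log(t)


@dataclass
class SurvivalFit:
    """Cox fit summary: per-covariate beta/HR/CI/p plus model-level fields."""

    table: pd.DataFrame  # index covariate; beta, hr, ci_low, ci_high, wald_p
    loglik: float
    n: int
    n_events: int
    ties: str = "efron"
    schoenfeld_p: dict[str, float] = field(default_factory=dict)
    _model: object = None
    _training_df: Optional[pd.DataFrame] = None

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def to_tsv(self, path: str) -> None:
        out = self.table.copy()
        out["schoenfeld_p"] = [
            self.schoenfeld_p.get(c, float("nan")) for c in out.index
        ]
        out.to_csv(path, sep="\t", index_label="covariate", float_format="%.10g")


@dataclass
class KMCurve:
    """Product-limit estimate: event times, survival, at-risk, Greenwood var."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "surv": self.survival,
                "at_risk": self.at_risk,
                "greenwood_var": self.greenwood_var,
            }
        )


def dichotomize_covariates(
    ann: CohortAnnotation,
    covariates: tuple[str, ...] = ("age", "size", "ggi"),
) -> pd.DataFrame:
    """Dichotomize clinical covariates: age > 50, size > 2 cm, GGI > 0 (strict)."""
    colmap = {"age": "age_years", "size": "size_cm", "ggi": "ggi"}
    out = {}
    for cov in covariates:
        col = colmap.get(cov, cov)
        if col not in ann.table.columns:
            raise ValueError(f"annotation missing column {col!r} for covariate {cov!r}")
        x = ann.table[col].to_numpy(dtype=float)
        cut = {"age": 50.0, "size": 2.0, "ggi": 0.0}[cov]
        out[f"{cov}_hi"] = (x > cut).astype(int)
    return pd.DataFrame(out, index=ann.table.index)


def administrative_censor(
    time: np.ndarray, event: np.ndarray, horizon: float = TEN_YEAR_MONTHS
) -> tuple[np.ndarray, np.ndarray]:
    """Truncate follow-up at ``horizon`` months (events beyond become censorings)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    capped = np.minimum(time, horizon)
    ev = np.where(time <= horizon, event, 0)
    return capped, ev


def km_estimate(
    time: np.ndarray, event: np.ndarray, group: np.ndarray | None = None
) -> dict[object, KMCurve]:
    """Kaplan-Meier product-limit estimate per group (single group when None)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("times must be strictly positive")
    if group is None:
        group = np.zeros(len(time), dtype=int)
    group = np.asarray(group)
    out: dict[object, KMCurve] = {}
    for g in pd.unique(group):
        mask = group == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event[mask])
        tl = kmf.survival_function_.index.to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        # Greenwood from the event table
        et = kmf.event_table
        d = et["observed"].to_numpy(dtype=float)
        n = et["at_risk"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(n * (n - d) > 0, d / (n * (n - d)), 0.0)
        var = surv**2 * np.cumsum(terms)
        out[g] = KMCurve(tl, surv, n, var)
    return out


def logrank_test(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = pd.unique(group)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(labels)}")
    if event.sum() == 0:
        raise ValueError("no events: log-rank test undefined")
    a = group == labels[0]
    res = _ll_logrank(time[a], time[~a], event[a], event[~a])
    return float(res.test_statistic), float(res.p_value)


def _episode_split(
    covariates: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    tt_covariate: str,
    g: Callable[[np.ndarray], np.ndarray],
) -> pd.DataFrame:
    """Long-format start/stop data with the x*g(t) column evaluated per interval.

    Follow-up is split at the distinct event times; within each interval the
    time-varying column takes the value x * g(t_stop), the value the partial
    likelihood uses at the risk set of that interval's endpoint.
    """
    cuts = np.unique(time[event == 1])
    rows = []
    x_tt = covariates[tt_covariate].to_numpy(dtype=float)
    for i, (t_i, e_i) in enumerate(zip(time, event)):
        edges = cuts[cuts < t_i]
        starts = np.concatenate([[0.0], edges])
        stops = np.concatenate([edges, [t_i]])
        keep = stops > starts
        starts, stops = starts[keep], stops[keep]
        for j, (a, b) in enumerate(zip(starts, stops)):
            last = j == len(starts) - 1
            row = {
                "id": i,
                "start": a,
                "stop": b,
                "event": int(e_i) if last else 0,
                f"{tt_covariate}_gt": x_tt[i] * float(g(np.array([b]))[0]),
            }
            for c in covariates.columns:
                row[c] = covariates[c].iloc[i]
            rows.append(row)
    return pd.DataFrame(rows)


def cox_fit(
    covariates: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    tt_spec: Optional[tuple[str, Callable[[np.ndarray], np.ndarray]]] = None,
    ties: str = "efron",
) -> SurvivalFit:
    """Cox proportional-hazards regression; Efron ties by default.

    ``tt_spec = (covariate, g)`` adds a time-interaction term x*g(t) fitted by
    episode splitting at the event times (default g is log months — pass
    ``(cov, None)`` to use it).  Every covariate must vary and at least one
    event must be present.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 1:
        raise ValueError("no events: Cox model undefined")
    for c in covariates.columns:
        if covariates[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} does not vary")

    training_df = None
    if tt_spec is None:
        df = covariates.reset_index(drop=True).copy()
        df["time"] = time
        df["event"] = event
        cph = CoxPHFitter()
        cph.fit(df, duration_col="time", event_col="event")
        summary = cph.summary
        model = cph
        training_df = df
        loglik = float(cph.log_likelihood_)
    else:
        tt_cov, g = tt_spec
        if g is None:
            g = _log_time
        if tt_cov not in covariates.columns:
            raise ValueError(f"tt covariate {tt_cov!r} not in covariate table")
        long = _episode_split(covariates.reset_index(drop=True), time, event, tt_cov, g)
        ctv = CoxTimeVaryingFitter()
        ctv.fit(long, id_col="id", start_col="start", stop_col="stop",
                event_col="event")
        summary = ctv.summary
        model = ctv
        loglik = float(ctv.log_likelihood_)

    # Complete separation sends coefficients off to +/- infinity.  In the
    # episode-split model the (x, x*g(t)) pair is exempt: with few events the
    # pair is only weakly identified jointly (g(t) varies little over the
    # observed event times) and can drift large while every other coefficient
    # remains perfectly usable — mirroring how coxph reports such fits.
    guarded = summary["coef"].copy()
    if tt_spec is not None:
        guarded = guarded.drop(index=[tt_cov, f"{tt_cov}_gt"], errors="ignore")
        if np.any(np.abs(summary["coef"].loc[[tt_cov, f"{tt_cov}_gt"]]) > 10):
            logger.warning(
                "time-interaction pair (%s, %s_gt) weakly identified "
                "(|coef| > 10); other coefficients unaffected", tt_cov, tt_cov
            )
    if np.any(np.abs(guarded.to_numpy()) > 10):
        raise ValueError(
            "monotone partial likelihood (complete separation): no finite "
            "estimate exists; Firth-type penalization is out of scope"
        )
    table = pd.DataFrame(
        {
            "beta": summary["coef"],
            "hr": summary["exp(coef)"],
            "ci_low": np.exp(summary["coef lower 95%"]),
            "ci_high": np.exp(summary["coef upper 95%"]),
            "wald_p": summary["p"],
        }
    )
    table.index.name = "covariate"
    return SurvivalFit(
        table,
        loglik=loglik,
        n=len(time),
        n_events=int(event.sum()),
        ties=ties,
        _model=model,
        _training_df=training_df,
    )


def schoenfeld_test(
    fit: SurvivalFit,
    time: np.ndarray | None = None,
    event: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Grambsch-Therneau PH test on scaled Schoenfeld residuals vs log time.

    Returns a per-covariate p-value dict (also stored on ``fit``).  Only
    defined for plain (non-time-varying) fits with >= 2 events.
    """
    if fit.n_events < 2:
        raise ValueError("need at least 2 events for the Schoenfeld test")
    model = fit._model
    if not isinstance(model, CoxPHFitter) or fit._training_df is None:
        raise ValueError("Schoenfeld test is defined for plain Cox fits only")
    res = proportional_hazard_test(model, fit._training_df, time_transform="log")
    pvals = res.summary["p"]
    out = {str(idx[0] if isinstance(idx, tuple) else idx): float(p)
           for idx, p in pvals.items()}
    fit.schoenfeld_p = out
    return out


def univariable_cox(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, name: str = "x",
    ties: str = "efron",
) -> SurvivalFit:
    """Convenience single-covariate Cox fit."""
    cov = pd.DataFrame({name: np.asarray(x, dtype=float)})
    return cox_fit(cov, time, event, ties=ties)
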