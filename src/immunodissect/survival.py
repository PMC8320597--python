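"""Survival analysis: Kaplan-Meier, log-rank, Cox proportional hazards.

Wraps lifelines for the product-limit estimator, the log-rank test and
the Cox partial-likelihood fit (Efron tie handling by default, Breslow
behind a flag), and adds the univariable-screen helper used to choose
covariates for the multivariable model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import median_survival_times
from scipy import stats as _stats

from .dataio import DataError


@dataclass
class KMGroup:
    """Kaplan-Meier estimate for one group."""

    times: np.ndarray  # event/censoring times in the step function
    survival: np.ndarray  # S(t) at those times
    median: float | None  # None = not reached
    median_ci: tuple[float | None, float | None]
    n: int
    n_events: int


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (one row per coefficient)."""

    table: pd.DataFrame  # coef, HR, ci_low, ci_high, se, p
    log_likelihood: float
    n: int
    n_events: int
    tie_method: str

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "HR"])


def _check_surv(times, events):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if (times <= 0).any():
        raise DataError("survival times must be strictly positive")
    if not np.isin(events, [0, 1]).all():
        raise DataError("events must be binary (0/1)")
    return times, events


def km_estimate(
    times, events, groups=None, alpha: float = 0.05
) -> dict[str, KMGroup]:
    """Product-limit survival estimate per group.

    The median is the first time S(t) drops to 0.5 or below (None when
    never reached); its CI comes from the Greenwood-based confidence
    band.
    """
    times, events = _check_surv(times, events)
    if groups is None:
        groups = np.array(["all"] * len(times))
    groups = np.asarray(pd.Series(groups).astype(str))
    out: dict[str, KMGroup] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise DataError(f"empty group {g!r}")
        kmf = KaplanMeierFitter(alpha=alpha)
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        med = kmf.median_survival_time_
        ci = median_survival_times(kmf.confidence_interval_)
        lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
        out[g] = KMGroup(
            times=sf.index.to_numpy()[1:],  # drop the t=0 anchor row
            survival=sf.iloc[1:, 0].to_numpy(),
            median=None if np.isinf(med) else float(med),
            median_ci=(
                None if np.isinf(lo) else lo,
                None if np.isinf(hi) else hi,
            ),
            n=int(mask.sum()),
            n_events=int(events[mask].sum()),
        )
    return out


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank chi-square test across >= 2 groups."""
    times, events = _check_surv(times, events)
    groups = pd.Series(groups).astype(str).to_numpy()
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise DataError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), float(res.p_value)


def coxph_fit(
    times,
    events,
    covariates: pd.DataFrame,
    tie_method: str = "efron",
    alpha: float = 0.05,
) -> CoxFit:
    """Cox proportional-hazards regression.

    ``covariates`` is a numeric design matrix (categorical covariates
    already expanded against their reference level). Efron tie
    handling is the default; "breslow" is available behind the flag.
    Constant covariates and monotone-likelihood separation raise with
    the offending column named.
    """
    times, events = _check_surv(times, events)
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    if covariates.isna().any().any():
        raise DataError("covariates contain missing values")
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise DataError(f"covariate {col!r} is constant")
    if int(events.sum()) < covariates.shape[1]:
        raise DataError("fewer events than coefficients")
    frame = covariates.copy()
    frame["_time"] = times
    frame["_event"] = events
    cph = CoxPHFitter(alpha=alpha)
    try:
        with np.errstate(all="ignore"):
            cph.fit(
                frame,
                duration_col="_time",
                event_col="_event",
                fit_options={"step_size": 0.95},
            )
    except Exception as exc:  # lifelines raises ConvergenceError
        raise DataError(f"Cox fit failed to converge: {exc}") from exc
    if tie_method == "breslow":
        # lifelines uses Efron; refit via a from-scratch Breslow Newton solve
        beta, ll, se = _breslow_fit(times, events, covariates.to_numpy(float))
        z = 1 - alpha / 2
        zq = float(_stats.norm.ppf(z))
        table = pd.DataFrame(
            {
                "coef": beta,
                "HR": np.exp(beta),
                "ci_low": np.exp(beta - zq * se),
                "ci_high": np.exp(beta + zq * se),
                "se": se,
                "p": 2 * _stats.norm.sf(np.abs(beta / se)),
            },
            index=list(covariates.columns),
        )
        return CoxFit(table, float(ll), len(times), int(events.sum()), "breslow")
    if tie_method != "efron":
        raise DataError(f"unknown tie_method {tie_method!r}")
    summ = cph.summary
    table = pd.DataFrame(
        {
            "coef": summ["coef"],
            "HR": summ["exp(coef)"],
            "ci_low": np.exp(summ["coef lower 95%"]),
            "ci_high": np.exp(summ["coef upper 95%"]),
            "se": summ["se(coef)"],
            "p": summ["p"],
        }
    )
    table.index = list(covariates.columns)
    return CoxFit(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(times),
        n_events=int(events.sum()),
        tie_method="efron",
    )


def _breslow_fit(times, events, X, max_iter=100, tol=1e-9):
    """Newton-Raphson Cox fit with Breslow tie handling."""
    n, p = X.shape
    beta = np.zeros(p)
    order = np.argsort(times)
    t, d, Xs = times[order], events[order], X[order]
    ll_prev = -np.inf
    for _ in range(max_iter):
        eta = Xs @ beta
        w = np.exp(eta)
        # risk-set suffix sums
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
        S2 = np.cumsum((w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1]
        # map each time to the first index of its risk set (handle ties)
        first = np.searchsorted(t, t, side="left")
        ev = d == 1
        ll = float(np.sum(eta[ev] - np.log(S0[first[ev]])))
        U = Xs[ev].sum(axis=0) - (S1[first[ev]] / S0[first[ev], None]).sum(axis=0)
        xbar = S1[first[ev]] / S0[first[ev], None]
        I = (
            S2[first[ev]] / S0[first[ev], None, None]
            - xbar[:, :, None] * xbar[:, None, :]
        ).sum(axis=0)
        try:
            step = np.linalg.solve(I, U)
        except np.linalg.LinAlgError as exc:
            raise DataError("Breslow fit: singular information matrix") from exc
        beta = beta + step
        if abs(ll - ll_prev) < tol * max(abs(ll), 1.0):
            break
        ll_prev = ll
    se = np.sqrt(np.diag(np.linalg.inv(I)))
    return beta, ll, se


def univariable_screen(
    clinical: pd.DataFrame,
    covariate_cols: list[str],
    p_threshold: float = 0.05,
    time_col: str = "time",
    event_col: str = "event",
) -> tuple[pd.DataFrame, list[str]]:
    """Fit one single-covariate Cox model per column; return the summary
    table and the covariates passing ``p_threshold`` (the multivariable
    entry rule)."""
    rows = []
    selected = []
    for col in covariate_cols:
        fit = coxph_fit(
            clinical[time_col], clinical[event_col], clinical[[col]]
        )
        row = fit.table.loc[col]
        rows.append(row.rename(col))
        if row["p"] < p_threshold:
            selected.append(col)
    return pd.DataFrame(rows), selected


def expand_categorical(
    table: pd.DataFrame, column: str, reference: str
) -> pd.DataFrame:
    """Expand one categorical column into 0/1 indicators vs a reference
    level, returning the table with the original column replaced."""
    if reference not in set(table[column]):
        raise DataError(f"reference level {reference!r} absent from {column!r}")
    dummies = pd.get_dummies(table[column], prefix=column, dtype=float)
    dummies = dummies.drop(columns=f"{column}_{reference}")
    return pd.concat([table.drop(columns=column), dummies], axis=1)
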