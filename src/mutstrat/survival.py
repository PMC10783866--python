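"""Kaplan-Meier estimation, log-rank testing and Cox regression.

These are the screening and validation statistics of the pipeline: a
univariate Cox proportional-hazards fit per pathway selects
prognosis-associated pathways (p < 0.05, no multiplicity correction by
default; an optional Benjamini-Hochberg flag is provided), and subtype
validity is judged by Kaplan-Meier curves with the log-rank test plus
multivariate Cox fits for independence from clinical covariates.

Model fitting is delegated to lifelines; the score test at beta = 0 is
implemented directly with the hypergeometric (log-rank) variance, making
the classical identity "Cox score test on a binary covariate == two-group
log-rank test" exact, ties included.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as LLConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "km_estimate",
    "km_median",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "screen_prognostic_pathways",
]

Z975 = 1.959963984540054  # normal 97.5% quantile for the Wald CI


@dataclass
class CoxResult:
    """Per-covariate Wald summaries plus model-level statistics."""

    summary: pd.DataFrame  # index covariate; coef, se, hr, ci_low, ci_high, p
    log_likelihood: float
    n: int
    n_events: int
    converged: bool = True

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "p"])


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise DataError("no survival records")
    for col in ("os_months", "os_event"):
        if col not in records.columns:
            raise DataError(f"records missing column {col!r}")
    t = records["os_months"].to_numpy(dtype=float)
    e = records["os_event"].to_numpy(dtype=float)
    if not np.isfinite(t).all() or (t <= 0).any():
        raise DataError("survival times must be positive and finite")
    if not np.isin(e, [0, 1]).all():
        raise DataError("event indicator must be 0/1")
    return records


def km_estimate(
    records: pd.DataFrame, group_labels: pd.Series | None = None
) -> dict[object, pd.DataFrame]:
    """Product-limit survival curves, optionally per group.

    Returns {group: DataFrame(time, survival)}; the whole cohort sits
    under the key ``"all"`` when no labels are given.
    """
    _check_records(records)
    if group_labels is None:
        groups = pd.Series("all", index=records.index)
    else:
        groups = group_labels.reindex(records.index)
    out: dict[object, pd.DataFrame] = {}
    for g, sub in records.groupby(groups, sort=True):
        if sub.empty:
            raise DataError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["os_months"], event_observed=sub["os_event"])
        sf = kmf.survival_function_
        out[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def km_median(records: pd.DataFrame) -> float:
    """Median survival time (inf when the curve never reaches 0.5)."""
    _check_records(records)
    kmf = KaplanMeierFitter().fit(records["os_months"], records["os_event"])
    return float(kmf.median_survival_time_)


def logrank_test(records: pd.DataFrame, group_labels) -> tuple[float, int, float]:
    """Multigroup log-rank test; returns (chi-square, df, p)."""
    _check_records(records)
    groups = pd.Series(np.asarray(group_labels), index=records.index)
    uniq = groups.unique()
    if len(uniq) < 2:
        raise DataError("log-rank test needs at least 2 nonempty groups")
    res = multivariate_logrank_test(
        records["os_months"], groups, records["os_event"]
    )
    df = len(uniq) - 1
    return float(res.test_statistic), df, float(res.p_value)


def _encode_covariates(records: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """One-hot encode categorical covariates against the most frequent level."""
    cols = []
    for name in covariates:
        if name not in records.columns:
            raise DataError(f"covariate {name!r} not in records")
        col = records[name]
        if pd.api.types.is_numeric_dtype(col):
            if col.nunique() <= 1:
                raise DataError(f"covariate {name!r} is constant")
            cols.append(col.astype(float))
        else:
            levels = col.value_counts()
            if len(levels) <= 1:
                raise DataError(f"covariate {name!r} is constant")
            reference = levels.index[0]
            for lev in levels.index[1:]:
                cols.append((col == lev).astype(float).rename(f"{name}[{lev}]"))
    return pd.concat(cols, axis=1)


def cox_fit(records: pd.DataFrame, covariate_names: list[str] | str) -> CoxResult:
    """Cox proportional-hazards fit (partial likelihood, Wald inference).

    One covariate gives the univariate model; several give the
    multivariate model.  Non-convergence / monotone likelihood yields a
    flagged (converged=False) result with NaN summaries rather than a
    silent failure.
    """
    if isinstance(covariate_names, str):
        covariate_names = [covariate_names]
    _check_records(records)
    if int(records["os_event"].sum()) < 1:
        raise DataError("Cox fit needs at least one event")
    X = _encode_covariates(records, covariate_names)
    frame = pd.concat(
        [records[["os_months", "os_event"]].astype(float), X], axis=1
    )
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(frame, duration_col="os_months", event_col="os_event")
    except LLConvergenceError as exc:
        logger.warning("Cox fit did not converge: %s", exc)
        nan = np.full(X.shape[1], np.nan)
        summary = pd.DataFrame(
            {"coef": nan, "se": nan, "hr": nan, "ci_low": nan, "ci_high": nan, "p": nan},
            index=X.columns,
        )
        return CoxResult(
            summary=summary,
            log_likelihood=float("nan"),
            n=len(frame),
            n_events=int(records["os_event"].sum()),
            converged=False,
        )
    coef = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    summary = pd.DataFrame(
        {
            "coef": coef,
            "se": se,
            "hr": np.exp(coef),
            "ci_low": np.exp(coef - Z975 * se),
            "ci_high": np.exp(coef + Z975 * se),
            "p": 2.0 * stats.norm.sf(np.abs(coef / se)),
        },
        index=cph.params_.index,
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=len(frame),
        n_events=int(records["os_event"].sum()),
        converged=converged,
    )


def cox_score_test(records: pd.DataFrame, covariate: str) -> tuple[float, float]:
    """Score test of beta = 0 for a single numeric covariate.

    Uses the log-rank (hypergeometric) variance with ties correction, so
    for a binary covariate the statistic equals the two-group log-rank
    chi-square exactly.  Returns (chi-square, p).
    """
    _check_records(records)
    x = records[covariate].to_numpy(dtype=float)
    t = records["os_months"].to_numpy(dtype=float)
    e = records["os_event"].to_numpy(dtype=int)
    U = 0.0
    V = 0.0
    for tt in np.unique(t[e == 1]):
        at_risk = t >= tt
        n_t = int(at_risk.sum())
        deaths = (t == tt) & (e == 1)
        d_t = int(deaths.sum())
        xbar = x[at_risk].mean()
        U += x[deaths].sum() - d_t * xbar
        if n_t > 1:
            var_x = x[at_risk].var()  # population variance over the risk set
            V += d_t * var_x * (n_t - d_t) / (n_t - 1)
    if V <= 0:
        raise DataError("degenerate risk sets; score test undefined")
    chi2 = U * U / V
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def screen_prognostic_pathways(
    activity: pd.DataFrame,
    records: pd.DataFrame,
    alpha: float = 0.05,
    fdr: bool = False,
) -> pd.DataFrame:
    """Univariate Cox fit per pathway column; keep p < alpha.

    Returns a DataFrame ordered by p with columns hr, ci_low, ci_high, p,
    direction ("risk" when HR > 1 else "protective"), plus q when
    ``fdr=True`` (Benjamini-Hochberg), in which case retention is on q.
    An empty result is returned (with a warning) when nothing passes.
    """
    if not 0 < alpha <= 1:
        raise ParameterError("alpha must be in (0, 1]")
    common = activity.index.intersection(records.index)
    if len(common) < len(activity):
        logger.warning("screening on %d/%d samples with clinical records", len(common), len(activity))
    if len(common) == 0:
        raise DataError("no overlap between activity matrix and clinical records")
    act = activity.loc[common]
    rec = records.loc[common]

    rows = []
    for name in act.columns:
        frame = rec[["os_months", "os_event"]].copy()
        frame[name] = act[name].astype(float)
        if frame[name].nunique() <= 1:
            logger.warning("pathway %r constant; skipped", name)
            continue
        res = cox_fit(frame, [name])
        if not res.converged:
            continue
        s = res.summary.iloc[0]
        rows.append(
            {
                "pathway": name,
                "coef": s["coef"],
                "hr": s["hr"],
                "ci_low": s["ci_low"],
                "ci_high": s["ci_high"],
                "p": s["p"],
                "direction": "risk" if s["hr"] > 1 else "protective",
            }
        )
    table = pd.DataFrame(rows).set_index("pathway") if rows else pd.DataFrame()
    if table.empty:
        logger.warning("no pathway could be tested")
        return table
    if fdr:
        from statsmodels.stats.multitest import multipletests

        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        kept = table[table["q"] < alpha]
    else:
        kept = table[table["p"] < alpha]
    kept = kept.sort_values("p")
    if kept.empty:
        logger.warning("screening retained zero pathways at alpha=%g", alpha)
    return kept
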