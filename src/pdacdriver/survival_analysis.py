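"""Kaplan–Meier estimation, log-rank tests, Cox regression, and the
driver-mutation contrast battery.

The battery is the analysis core: a set of mutation-exclusive survival
contrasts that dissect which of the four PDAC driver genes carries the
prognostic signal.  With KRAS activation as background, single- and
co-mutation strata are each compared against the KRAS-only control, and
the marginal SMAD4/CDKN2A effects are re-tested after excluding
TP53-mutant patients — exposing co-occurrence with TP53 as the source of
their apparent prognostic value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats


@dataclass(frozen=True)
class SurvivalCurve:
    """Product-limit survival estimate at the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: Optional[float]


@dataclass(frozen=True)
class ComparisonResult:
    """One two-group log-rank contrast of the battery."""

    name: str
    group_labels: tuple
    group_sizes: tuple
    logrank_stat: Optional[float]
    p_value: Optional[float]
    medians: tuple
    evaluable: bool = True
    note: str = ""


@dataclass(frozen=True)
class CoxResult:
    """Multivariate proportional-hazards fit.

    ``summary`` has one row per model term (hazard ratio, 95% CI, Wald P);
    ``sequential_p`` maps each covariate to the likelihood-ratio P of
    adding it to the model containing the covariates before it — the
    analogue of a sequential analysis-of-deviance table.
    """

    summary: pd.DataFrame
    sequential_p: dict
    converged: bool
    log_likelihood: float


def _check_survival_input(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if times.size == 0:
        raise ValueError("survival input must contain at least one subject")
    if np.any(times <= 0):
        raise ValueError("survival times must be strictly positive")
    if not np.isin(events, [0, 1]).all():
        raise ValueError("event indicators must be 0/1")
    return times, events.astype(int)


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimator.

    The curve is reported at the distinct event times; the median is the
    first time at which survival drops to 0.5 or below, and is None when
    the curve never reaches 0.5 (censored-heavy data).
    """
    times, events = _check_survival_input(times, events)
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)

    event_times = np.sort(np.unique(times[events == 1]))
    if event_times.size:
        survival = (
            fitter.survival_function_at_times(event_times).to_numpy(dtype=float)
        )
        at_risk = np.array([(times >= t).sum() for t in event_times])
        n_events = np.array([((times == t) & (events == 1)).sum() for t in event_times])
    else:
        survival = np.array([])
        at_risk = np.array([], dtype=int)
        n_events = np.array([], dtype=int)

    median = fitter.median_survival_time_
    median = None if np.isinf(median) else float(median)
    return SurvivalCurve(event_times, survival, at_risk, n_events, median)


def logrank_test(
    times_a, events_a, times_b, events_b, name: str = "", labels: tuple = ("A", "B")
) -> ComparisonResult:
    """Two-group Mantel–Cox log-rank test (chi-square, 1 df)."""
    times_a, events_a = _check_survival_input(times_a, events_a)
    times_b, events_b = _check_survival_input(times_b, events_b)
    result = _ll_logrank(times_a, times_b, events_a, events_b)
    medians = (km_estimate(times_a, events_a).median, km_estimate(times_b, events_b).median)
    return ComparisonResult(
        name=name,
        group_labels=tuple(labels),
        group_sizes=(times_a.size, times_b.size),
        logrank_stat=float(result.test_statistic),
        p_value=float(result.p_value),
        medians=medians,
    )


def cox_fit(
    profiles: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
) -> CoxResult:
    """Multivariate Cox proportional-hazards fit with sequential significance.

    Categorical covariates (object/category dtype) are dummy-coded against
    their first level.  Per-variable significance is a sequential
    likelihood-ratio test: each covariate is tested against the model
    containing only the covariates listed before it, with degrees of
    freedom equal to the number of terms it contributes.
    """
    covariates = list(covariates)
    for cov in covariates:
        if cov not in profiles.columns:
            raise ValueError(f"covariate {cov!r} not present in profiles")
        if profiles[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant")

    design = profiles[[duration_col, event_col]].copy()
    term_cols: dict[str, list[str]] = {}
    for cov in covariates:
        col = profiles[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            design[dummies.columns] = dummies
            term_cols[cov] = list(dummies.columns)
        else:
            design[cov] = col.astype(float)
            term_cols[cov] = [cov]

    def _fit(cols: list[str]) -> CoxPHFitter:
        fitter = CoxPHFitter()
        fitter.fit(design[[duration_col, event_col] + cols], duration_col, event_col)
        return fitter

    all_cols = [c for cov in covariates for c in term_cols[cov]]
    try:
        full = _fit(all_cols)
        converged = True
    except Exception as exc:  # lifelines raises ConvergenceError/LinAlgError
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc

    summary = full.summary[["exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    summary = summary.rename(
        columns={
            "exp(coef)": "hazard_ratio",
            "exp(coef) lower 95%": "hr_ci_low",
            "exp(coef) upper 95%": "hr_ci_high",
            "p": "wald_p",
        }
    )

    sequential_p: dict[str, float] = {}
    cols_so_far: list[str] = []
    prev_ll = float(full._ll_null_)  # null (covariate-free) partial likelihood
    for cov in covariates:
        cols_so_far = cols_so_far + term_cols[cov]
        fitted = full if cols_so_far == all_cols else _fit(cols_so_far)
        ll = float(fitted.log_likelihood_)
        lr = 2.0 * (ll - prev_ll)
        df = len(term_cols[cov])
        sequential_p[cov] = float(stats.chi2.sf(max(lr, 0.0), df))
        prev_ll = ll

    return CoxResult(
        summary=summary,
        sequential_p=sequential_p,
        converged=converged,
        log_likelihood=float(full.log_likelihood_),
    )


def _contrast(
    profiles: pd.DataFrame, name: str, mask_a, mask_b, labels: tuple
) -> ComparisonResult:
    """Run one contrast, degrading to 'not evaluable' when an arm is empty."""
    a = profiles.loc[mask_a]
    b = profiles.loc[mask_b]
    if a.empty or b.empty:
        return ComparisonResult(
            name=name,
            group_labels=tuple(labels),
            group_sizes=(len(a), len(b)),
            logrank_stat=None,
            p_value=None,
            medians=(None, None),
            evaluable=False,
            note="not evaluable: empty arm",
        )
    return logrank_test(
        a["time"], a["event"], b["time"], b["event"], name=name, labels=labels
    )


def driver_contribution_battery(profiles: pd.DataFrame) -> list[ComparisonResult]:
    """The full mutation-exclusive driver-contribution contrast battery.

    Contrasts, in order:

    A. KRAS-only vs no-driver-mutation.
    B. KRAS+X-only vs KRAS-only for X in TP53, SMAD4, CDKN2A.
    C. each KRAS-background co-mutation combination vs KRAS-only.
    D. CDKN2A-mutant vs CDKN2A-wildtype — on all patients, and after
       excluding TP53-mutant patients.
    E. SMAD4-mutant vs SMAD4-wildtype — likewise twice.
    F. TP53-mutant vs TP53-wildtype.

    Contrasts with an empty arm are returned as not evaluable rather than
    raised.
    """
    k = profiles["kras_mut"]
    t = profiles["tp53_mut"]
    s = profiles["smad4_mut"]
    c = profiles["cdkn2a_mut"]
    kras_only = k & ~t & ~s & ~c
    no_driver = ~k & ~t & ~s & ~c

    results = [
        _contrast(profiles, "KRAS_only_vs_no_driver", kras_only, no_driver,
                  ("KRAS_only", "no_driver")),
    ]

    single = {"TP53": t & ~s & ~c, "SMAD4": s & ~t & ~c, "CDKN2A": c & ~t & ~s}
    for gene, extra in single.items():
        results.append(
            _contrast(profiles, f"KRAS+{gene}_only_vs_KRAS_only", k & extra, kras_only,
                      (f"KRAS+{gene}_only", "KRAS_only"))
        )

    combos = {
        "TP53+SMAD4": t & s & ~c,
        "TP53+CDKN2A": t & c & ~s,
        "SMAD4+CDKN2A": s & c & ~t,
        "TP53+SMAD4+CDKN2A": t & s & c,
    }
    for label, extra in combos.items():
        results.append(
            _contrast(profiles, f"KRAS+{label}_vs_KRAS_only", k & extra, kras_only,
                      (f"KRAS+{label}", "KRAS_only"))
        )

    for gene, flag in (("CDKN2A", c), ("SMAD4", s)):
        results.append(
            _contrast(profiles, f"{gene}_vs_wt_all", flag, ~flag,
                      (f"{gene}_mut", f"{gene}_wt"))
        )
        sub = ~t
        results.append(
            _contrast(profiles, f"{gene}_vs_wt_TP53_excluded", flag & sub, ~flag & sub,
                      (f"{gene}_mut", f"{gene}_wt"))
        )

    results.append(_contrast(profiles, "TP53_vs_wt", t, ~t, ("TP53_mut", "TP53_wt")))
    return results


def battery_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    """Serialize battery results to a flat table."""
    rows = []
    for r in results:
        rows.append(
            {
                "contrast": r.name,
                "arm_1": r.group_labels[0],
                "arm_2": r.group_labels[1],
                "n_1": r.group_sizes[0],
                "n_2": r.group_sizes[1],
                "logrank_chi2": r.logrank_stat,
                "p_value": r.p_value,
                "median_1": r.medians[0],
                "median_2": r.medians[1],
                "evaluable": r.evaluable,
                "note": r.note,
            }
        )
    return pd.DataFrame(rows)
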