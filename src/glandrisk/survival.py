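"""Survival and association statistics for classifier validation.

Kaplan-Meier curves, the two-group log-rank test and Cox proportional
hazards (Efron ties handling, Wald intervals) are computed with
lifelines; chi-square association uses Pearson's statistic without
continuity correction; Cohen's kappa quantifies inter-reader agreement;
biomarker binarization applies the conventional Ki67 (>= 14% positive)
and serum CEA (> 5 ng/ml elevated) cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .errors import DomainError


@dataclass
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function; S = 1 before any event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: np.ndarray, events: np.ndarray) -> KMCurve:
    """Kaplan-Meier estimator; censored subjects leave the risk set only."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    if len(times) < 1:
        raise DomainError("km_estimate needs at least one subject")
    if np.any(times < 0):
        raise DomainError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    ts = np.asarray(surv.index, dtype=float)
    return KMCurve(
        times=ts,
        survival=surv.to_numpy(),
        at_risk=tab["at_risk"].reindex(surv.index).to_numpy(),
    )


def logrank_test(
    group_a: tuple[np.ndarray, np.ndarray], group_b: tuple[np.ndarray, np.ndarray]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p), 1 d.f."""
    (ta, ea), (tb, eb) = group_a, group_b
    if len(ta) == 0 or len(tb) == 0:
        raise DomainError("both groups must be non-empty")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """One covariate's Cox regression summary."""

    covariate: str
    beta: float
    hr: float
    ci95: tuple[float, float]
    p: float
    converged: bool = True


def cox_fit(
    covariates: pd.DataFrame,
    times: np.ndarray,
    events: np.ndarray,
    mode: str = "multivariate",
    ties: str = "efron",
) -> list[CoxFit]:
    """Cox proportional-hazards regression.

    mode "univariate" fits each covariate in its own model; mode
    "multivariate" fits one joint model.  Efron tie handling and Wald
    95% intervals exp(beta +/- 1.96 se).  Non-convergence (typically
    monotone likelihood from complete separation) is reported per
    covariate via ``converged=False`` instead of raising.
    """
    if mode not in {"univariate", "multivariate"}:
        raise DomainError(f"unknown mode {mode!r}")
    events = np.asarray(events)
    if events.sum() < 1:
        raise DomainError("cox_fit needs at least one event")
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = events
    groups = [[c] for c in covariates.columns] if mode == "univariate" else [list(covariates.columns)]
    fits: list[CoxFit] = []
    for cols in groups:
        sub = df[cols + ["_time", "_event"]]
        constant = [c for c in cols if sub[c].nunique() <= 1]
        cph = CoxPHFitter()
        try:
            cph.fit(
                sub.drop(columns=constant) if constant else sub,
                duration_col="_time",
                event_col="_event",
                fit_options={"step_size": 0.5, "precision": 1e-12},
            )
            ok = True
        except ConvergenceError:
            ok = False
        for c in cols:
            if not ok:
                fits.append(CoxFit(c, float("nan"), float("nan"),
                                   (float("nan"), float("nan")), float("nan"), False))
            elif c in constant:
                # no variation carries no hazard information: beta = 0
                fits.append(CoxFit(c, 0.0, 1.0, (float("nan"), float("nan")), 1.0, True))
            else:
                beta = float(cph.params_[c])
                se = float(cph.standard_errors_[c])
                fits.append(
                    CoxFit(
                        covariate=c,
                        beta=beta,
                        hr=float(np.exp(beta)),
                        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
                        p=float(cph.summary.loc[c, "p"]),
                        converged=True,
                    )
                )
    return fits


def chi_square(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction, 1 d.f."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0) or table.sum() == 0:
        raise DomainError("chi_square needs a non-negative 2x2 table with total > 0")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DomainError("chi_square is undefined with a zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def cohens_kappa(ratings_a: np.ndarray, ratings_b: np.ndarray) -> float:
    """Cohen's kappa between two categorical raters.

    kappa = (po - pe) / (1 - pe) with pe from marginal products.  When
    pe = 1 (both raters constant) the convention is 1 for perfect
    agreement and 0 otherwise.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise DomainError("cohens_kappa needs two equal-length vectors")
    cats = np.unique(np.concatenate([a, b]))
    idx = {c: i for i, c in enumerate(cats)}
    n = len(a)
    table = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    po = np.trace(table) / n
    pe = float((table.sum(axis=1) * table.sum(axis=0)).sum()) / n**2
    if pe >= 1.0:
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1.0 - pe))


KI67_POSITIVE_PCT = 14.0
CEA_NORMAL_MAX_NG_ML = 5.0


def binarize_biomarkers(ki67_li: float, cea: float) -> tuple[str, str]:
    """Apply the conventional Ki67 and serum CEA cut-offs.

    Ki67 labeling index is positive at >= 14% reactive tumor cells;
    serum CEA is normal up to and including 5 ng/ml, elevated above.
    """
    if not 0.0 <= ki67_li <= 100.0:
        raise DomainError(f"ki67_li {ki67_li} outside [0, 100]")
    if cea < 0:
        raise DomainError(f"cea {cea} must be >= 0")
    ki67 = "pos" if ki67_li >= KI67_POSITIVE_PCT else "neg"
    cea_status = "normal" if cea <= CEA_NORMAL_MAX_NG_ML else "elevated"
    return ki67, cea_status
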