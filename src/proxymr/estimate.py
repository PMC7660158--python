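"""Stratified per-allele estimation and interaction tests.

The gene-by-environment MR logic: fit the per-allele association of the
instrument dosage with an outcome separately within environment strata
(maternal pregnancy smoking, own smoking), then test whether the stratum
associations differ — by Cochran's Q heterogeneity across k strata, by
the normal z-test on the difference of two stratum estimates, and by the
difference of two such differences (variance = sum of the four stratum
variances) for the three-way modulation question.

Regression fitting is delegated to statsmodels (OLS / Logit /
proportional-odds OrderedModel); the heterogeneity and contrast
statistics are computed here. 95% intervals use the normal critical
value 1.96 throughout and p-values are two-sided normal.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

logger = logging.getLogger(__name__)

Z95 = 1.96

__all__ = [
    "StratumEstimate",
    "HeterogeneityResult",
    "DifferenceEstimate",
    "fit_association",
    "stratify_and_fit",
    "cochran_q",
    "stratum_difference",
    "difference_of_differences",
    "confounder_scan",
    "estimates_to_frame",
]


@dataclass(frozen=True)
class StratumEstimate:
    """Per-allele (or per-unit-exposure) association in one stratum."""

    stratum_label: str
    n: int
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    family: str  # linear | logistic | ordinal
    odds_ratio: float | None = None  # logistic/ordinal only
    converged: bool = True
    note: str = ""

    @property
    def z(self) -> float:
        return self.beta / self.se if self.se > 0 else np.inf * np.sign(self.beta)


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q across k stratum estimates; chi-square with k-1 df."""

    q_stat: float
    df: int
    p: float


@dataclass(frozen=True)
class DifferenceEstimate:
    """Contrast between two independent estimates (or two differences)."""

    delta: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    label: str = ""


def _wald(beta: float, se: float) -> tuple[float, float, float, float]:
    if se > 0:
        z = beta / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = np.inf if beta != 0 else 0.0
        p = 0.0 if beta != 0 else 1.0
    return beta - Z95 * se, beta + Z95 * se, z, p


def fit_association(
    outcome: Sequence[float],
    exposure: Sequence[float],
    covariates: pd.DataFrame | np.ndarray | None = None,
    family: str = "linear",
    *,
    label: str = "",
) -> StratumEstimate:
    """Fit one regression and return the exposure coefficient.

    ``beta`` is the coefficient of ``exposure`` (per-allele when the
    exposure is a 0/1/2 dosage) with covariates partialled out. For
    logistic and ordinal families, ``beta`` is on the log-odds scale and
    the odds ratio is also reported. Rows with any missing value are
    dropped. Non-convergence or separation yields a flagged estimate
    (``converged=False``) rather than an exception; a constant exposure
    raises ``ValueError``.
    """
    if family not in ("linear", "logistic", "ordinal"):
        raise ValueError(f"unknown family {family!r}")
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if covariates is None:
        C = np.empty((len(y), 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    if not (len(y) == len(x) == len(C)):
        raise ValueError("outcome, exposure and covariates must have equal length")
    keep = np.isfinite(y) & np.isfinite(x) & np.all(np.isfinite(C), axis=1)
    y, x, C = y[keep], x[keep], C[keep]
    n = len(y)
    n_params = 2 + C.shape[1] if family != "ordinal" else 1 + C.shape[1]
    if n <= n_params:
        raise ValueError(f"n={n} does not exceed parameter count {n_params}")
    if np.ptp(x) == 0:
        raise ValueError("exposure is constant; association is not identified")

    odds_ratio = None
    converged = True
    note = ""
    try:
        if family == "linear":
            X = np.column_stack([np.ones(n), x, C])
            res = sm.OLS(y, X).fit()
            beta, se = float(res.params[1]), float(res.bse[1])
        elif family == "logistic":
            uniq = np.unique(y)
            if not np.isin(uniq, (0.0, 1.0)).all():
                raise ValueError("logistic family requires a binary 0/1 outcome")
            if len(uniq) < 2:
                raise ValueError("binary outcome is constant")
            X = np.column_stack([np.ones(n), x, C])
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta, se = float(res.params[1]), float(res.bse[1])
            converged = bool(res.mle_retvals.get("converged", True))
        else:
            levels = np.unique(y)
            if len(levels) < 3:
                raise ValueError("ordinal family requires >= 3 ordered categories")
            exog = np.column_stack([x, C])
            model = OrderedModel(y, exog, distr="logit")
            res = model.fit(method="bfgs", disp=False, maxiter=500)
            beta, se = float(res.params[0]), float(res.bse[0])
            converged = bool(res.mle_retvals.get("converged", True))
    except ValueError:
        raise
    except Exception as exc:  # separation / optimizer failure
        beta, se, converged = np.nan, np.nan, False
        note = f"fit failed: {type(exc).__name__}: {exc}"

    if converged and not (np.isfinite(beta) and np.isfinite(se)):
        converged = False
        note = note or "non-finite estimate (possible separation)"
    if not converged and not note:
        note = "optimizer did not converge"
    if family in ("logistic", "ordinal") and np.isfinite(beta):
        odds_ratio = float(np.exp(beta))

    if np.isfinite(beta) and np.isfinite(se):
        ci_low, ci_high, _, p = _wald(beta, se)
    else:
        ci_low = ci_high = p = np.nan
    return StratumEstimate(
        stratum_label=label,
        n=n,
        beta=beta,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        family=family,
        odds_ratio=odds_ratio,
        converged=converged,
        note=note,
    )


def stratify_and_fit(
    cohort: pd.DataFrame,
    outcome_name: str,
    strata_spec: Sequence[str],
    family: str = "linear",
    covariate_names: Sequence[str] = (),
    exposure_col: str = "g1_dosage",
    min_n: int = 50,
) -> list[StratumEstimate]:
    """One per-allele estimate per stratum of the stratification variables.

    Strata with fewer than ``min_n`` usable rows (or a constant exposure)
    are skipped with a logged reason. Stratum labels are
    ``"var=value,var2=value2"``, ordered deterministically.
    """
    for col in (outcome_name, exposure_col, *strata_spec, *covariate_names):
        if col not in cohort.columns:
            raise KeyError(f"column {col!r} not in cohort")
    estimates: list[StratumEstimate] = []
    grouped = cohort.groupby(list(strata_spec), dropna=True, observed=True)
    for key, group in sorted(grouped, key=lambda kv: str(kv[0])):
        key_t = key if isinstance(key, tuple) else (key,)
        label = ",".join(f"{c}={v}" for c, v in zip(strata_spec, key_t))
        usable = group[[outcome_name, exposure_col, *covariate_names]].dropna()
        if len(usable) < min_n:
            logger.warning(
                "stratum %s skipped: n=%d below minimum %d", label, len(usable), min_n
            )
            continue
        covs = usable[list(covariate_names)] if covariate_names else None
        try:
            est = fit_association(
                usable[outcome_name],
                usable[exposure_col],
                covs,
                family,
                label=label,
            )
        except ValueError as exc:
            logger.warning("stratum %s skipped: %s", label, exc)
            continue
        estimates.append(est)
    return estimates


def cochran_q(estimates: Sequence[StratumEstimate]) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test across stratum estimates.

    Inverse-variance weights w_i = 1/se_i^2; Q = sum w_i (b_i - b_pooled)^2
    referred to chi-square with k-1 degrees of freedom.
    """
    if len(estimates) < 2:
        raise ValueError("Cochran's Q needs at least two estimates")
    betas = np.array([e.beta for e in estimates], dtype=float)
    ses = np.array([e.se for e in estimates], dtype=float)
    if np.any(~np.isfinite(betas)) or np.any(~np.isfinite(ses)) or np.any(ses <= 0):
        raise ValueError("all estimates must have finite betas and positive SEs")
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = len(estimates) - 1
    p = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q_stat=q, df=df, p=p)


def stratum_difference(
    a: StratumEstimate, b: StratumEstimate, label: str = ""
) -> DifferenceEstimate:
    """Difference b/w two independent stratum estimates, normal z-test.

    delta = beta_a - beta_b with SE = sqrt(se_a^2 + se_b^2); for two
    strata this test is identical to Cochran's Q (Q = z^2).
    """
    if a.family != b.family:
        raise ValueError(
            f"cannot contrast estimates from different families: "
            f"{a.family!r} vs {b.family!r}"
        )
    delta = a.beta - b.beta
    se = float(np.sqrt(a.se**2 + b.se**2))
    ci_low, ci_high, z, p = _wald(delta, se)
    return DifferenceEstimate(
        delta=delta, se=se, ci_low=ci_low, ci_high=ci_high, z=z, p=p, label=label
    )


def difference_of_differences(
    d1: DifferenceEstimate, d2: DifferenceEstimate, label: str = ""
) -> DifferenceEstimate:
    """Contrast two stratum differences from disjoint strata.

    Variance adds: se^2 = d1.se^2 + d2.se^2, i.e. the sum of the four
    original stratum variances.
    """
    delta = d1.delta - d2.delta
    se = float(np.sqrt(d1.se**2 + d2.se**2))
    ci_low, ci_high, z, p = _wald(delta, se)
    return DifferenceEstimate(
        delta=delta, se=se, ci_low=ci_low, ci_high=ci_high, z=z, p=p, label=label
    )


def confounder_scan(
    cohort: pd.DataFrame,
    dosage_col: str = "g1_dosage",
    variable_names: Sequence[str] = (),
    z_flag: float = 3.0,
) -> list[StratumEstimate]:
    """Association of the instrument dosage with each candidate confounder.

    A valid instrument should be unrelated to confounders; associations
    here signal population structure, selection or collider bias. The
    model family is auto-selected: logistic for 0/1 variables, linear
    otherwise. P-values are multiplicity-unadjusted; estimates with
    |z| > ``z_flag`` carry a note.
    """
    if dosage_col not in cohort.columns:
        raise KeyError(f"dosage column {dosage_col!r} not in cohort")
    results = []
    for name in variable_names:
        if name not in cohort.columns:
            raise KeyError(
                f"variable {name!r} not in cohort; available: "
                f"{', '.join(cohort.columns)}"
            )
        sub = cohort[[name, dosage_col]].dropna()
        vals = sub[name].to_numpy(dtype=float)
        if len(sub) and np.ptp(vals) == 0:
            raise ValueError(f"variable {name!r} is constant")
        binary = np.isin(np.unique(vals), (0.0, 1.0)).all()
        family = "logistic" if binary else "linear"
        est = fit_association(
            vals, sub[dosage_col], None, family, label=name
        )
        if np.isfinite(est.se) and est.se > 0 and abs(est.beta / est.se) > z_flag:
            est = replace(est, note=(est.note + " " if est.note else "") + "|z|>3")
        results.append(est)
    return results


def estimates_to_frame(estimates: Iterable[StratumEstimate]) -> pd.DataFrame:
    """Tabulate estimates for CSV export."""
    rows = [
        {
            "label": e.stratum_label,
            "n": e.n,
            "beta": e.beta,
            "se": e.se,
            "ci_low": e.ci_low,
            "ci_high": e.ci_high,
            "p": e.p,
            "family": e.family,
            "odds_ratio": e.odds_ratio,
            "converged": e.converged,
            "note": e.note,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
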