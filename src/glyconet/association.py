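"""Metabolome-wide covariate-adjusted association scan.

Each preprocessed metabolite measure is regressed on a phenotype (diabetes
status by default) by ordinary least squares, adjusting for age, sex,
ethnicity (four levels, Arab reference) and BMI. Effect sizes are reported
in SD units of the z-scored, log-transformed measure (positive = higher in
cases); significance is tiered by a single pooled Bonferroni family across
all fluids plus the nominal 0.05 level.

`fit_metabolite_regression` fits a single measure through statsmodels;
:class:`AssociationScan` fits the whole panel by vectorised multi-response
OLS over a shared design matrix (numerically identical, asserted in the
test suite). Association fits use only participants whose fluid sample
truly exists — rows whose whole fluid was filled during imputation carry
no measurement information and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import ETHNICITIES, FLUIDS, FluidMatrix

__all__ = [
    "bonferroni_threshold",
    "build_design",
    "fit_metabolite_regression",
    "AssociationRecord",
    "AssociationScan",
    "run_scan",
]

DEFAULT_COVARIATES = ("age", "sex", "ethnicity", "bmi")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance cut-off ``alpha / m`` for ``m`` tests."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def build_design(
    cohort: pd.DataFrame,
    phenotype: str = "diabetes",
    covariates: tuple = DEFAULT_COVARIATES,
    phenotype_values: pd.Series | None = None,
) -> pd.DataFrame:
    """Design matrix [intercept, phenotype, covariates] with dummy coding.

    Ethnicity is coded as three indicator contrasts against the Arab
    reference; sex as a female indicator. ``phenotype_values`` may supply
    an external phenotype column (e.g. a glycaemic marker) instead of a
    cohort column.
    """
    x = phenotype_values if phenotype_values is not None else cohort[phenotype]
    design = pd.DataFrame({"const": 1.0, phenotype: pd.to_numeric(x, errors="coerce")})
    design.index = cohort.index
    for cov in covariates:
        if cov == "sex":
            design["sex_female"] = (cohort["sex"] == "female").astype(float)
        elif cov == "ethnicity":
            for level in ETHNICITIES[1:]:
                design[f"eth_{level.replace(' ', '_')}"] = (
                    cohort["ethnicity"] == level
                ).astype(float)
        else:
            design[cov] = pd.to_numeric(cohort[cov], errors="coerce")
    return design


@dataclass
class AssociationRecord:
    """One measure × one phenotype regression result."""

    measure: str
    fluid: str
    phenotype: str
    beta: float
    se: float
    p: float
    n: int
    tier: str = "none"
    estimable: bool = True


def fit_metabolite_regression(
    y: pd.Series,
    cohort: pd.DataFrame,
    phenotype: str = "diabetes",
    covariates: tuple = DEFAULT_COVARIATES,
    fluid: str = "",
    phenotype_values: pd.Series | None = None,
) -> AssociationRecord:
    """OLS fit of one measure on a phenotype with covariate adjustment.

    Rows with missing response, phenotype or covariates are dropped
    listwise. A rank-deficient design or a constant phenotype yields an
    unestimable record with ``p = 1``.
    """
    design = build_design(cohort, phenotype, covariates, phenotype_values)
    frame = design.assign(_y=pd.to_numeric(y, errors="coerce")).dropna()
    x = frame.drop(columns="_y")
    n = len(frame)
    if n == 0 or frame[phenotype].nunique() < 2 or np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        return AssociationRecord(
            measure=str(y.name), fluid=fluid, phenotype=phenotype,
            beta=np.nan, se=np.nan, p=1.0, n=n, estimable=False,
        )
    fit = sm.OLS(frame["_y"], x).fit()
    return AssociationRecord(
        measure=str(y.name),
        fluid=fluid,
        phenotype=phenotype,
        beta=float(fit.params[phenotype]),
        se=float(fit.bse[phenotype]),
        p=float(fit.pvalues[phenotype]),
        n=n,
    )


def multiresponse_ols(X: np.ndarray, Y: np.ndarray, coef_index: int):
    """Vectorised OLS of many responses on one design matrix.

    Returns (beta, se, p, df) for the coefficient at ``coef_index``,
    identical to per-column statsmodels OLS fits.
    """
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValueError("not enough observations for the design")
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = xtx_inv @ (X.T @ Y)
    resid = Y - X @ coefs
    sigma2 = (resid**2).sum(axis=0) / df
    beta = coefs[coef_index]
    se = np.sqrt(sigma2 * xtx_inv[coef_index, coef_index])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta, se, p, df


class AssociationScan(BaseEstimator):
    """Metabolome-wide association scan across all fluid matrices.

    Parameters
    ----------
    phenotype : str, default "diabetes"
        Cohort column tested.
    alpha : float, default 0.05
        Family-wise error level; the Bonferroni cut-off is ``alpha / m``
        with ``m`` the total measures tested across fluids (one pooled
        family), and ``alpha`` itself is the nominal tier.
    covariates : tuple of str
        Adjustment covariates (cohort columns; ethnicity and sex are dummy
        coded).

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per measure, ordered by (fluid, measure id), with columns
        measure, fluid, beta, se, p, n, tier, estimable.
    m_ : int
        Number of tests in the Bonferroni family.
    bonferroni_ : float
        Realised Bonferroni threshold ``alpha / m_``.
    """

    def __init__(
        self,
        phenotype: str = "diabetes",
        alpha: float = 0.05,
        covariates: tuple = DEFAULT_COVARIATES,
    ) -> None:
        self.phenotype = phenotype
        self.alpha = alpha
        self.covariates = covariates

    def fit(self, fluids: dict, cohort: pd.DataFrame) -> "AssociationScan":
        """Scan every measure in ``fluids`` (fluid name → FluidMatrix)."""
        rows = []
        for fluid in FLUIDS:
            if fluid not in fluids:
                continue
            fm = fluids[fluid]
            has_col = f"has_{fluid}"
            sub = cohort.loc[cohort.index.intersection(fm.data.index)]
            if has_col in cohort:
                sub = sub.loc[sub[has_col].astype(bool)]
            design = build_design(sub, self.phenotype, self.covariates).dropna()
            X = design.to_numpy(float)
            Y = fm.data.reindex(design.index).to_numpy(float)
            measures = list(fm.data.columns)
            estimable = (
                X.shape[0] > X.shape[1]
                and design[self.phenotype].nunique() >= 2
                and np.linalg.matrix_rank(X) == X.shape[1]
            )
            if estimable and not np.isnan(Y).any():
                beta, se, p, _ = multiresponse_ols(X, Y, coef_index=1)
                for j, mid in enumerate(measures):
                    rows.append((mid, fluid, beta[j], se[j], p[j], X.shape[0], True))
            else:
                # fall back to per-measure fits (handles residual missingness)
                for mid in measures:
                    rec = fit_metabolite_regression(
                        fm.data.reindex(design.index)[mid], sub.loc[design.index],
                        self.phenotype, self.covariates, fluid=fluid,
                    )
                    rows.append((mid, fluid, rec.beta, rec.se, rec.p, rec.n, rec.estimable))

        results = pd.DataFrame(
            rows, columns=["measure", "fluid", "beta", "se", "p", "n", "estimable"]
        )
        results["fluid"] = pd.Categorical(results["fluid"], categories=FLUIDS, ordered=True)
        results = results.sort_values(["fluid", "measure"]).reset_index(drop=True)

        self.m_ = len(results)
        if self.alpha <= 0 or self.m_ == 0:
            self.bonferroni_ = 0.0
        else:
            self.bonferroni_ = bonferroni_threshold(self.alpha, self.m_)
        tier = np.select(
            [results["p"] < self.bonferroni_, results["p"] < self.alpha],
            ["bonferroni", "nominal"],
            default="none",
        )
        results["tier"] = tier
        self.results_ = results
        return self

    def significant(self, tier: str = "bonferroni") -> pd.DataFrame:
        """Records at the requested tier ('bonferroni' or 'nominal')."""
        res = self.results_
        if tier == "bonferroni":
            return res[res["tier"] == "bonferroni"]
        if tier == "nominal":
            return res[res["tier"].isin(["bonferroni", "nominal"])]
        raise ValueError(f"unknown tier {tier!r}")


def run_scan(
    fluids: dict,
    cohort: pd.DataFrame,
    phenotype: str = "diabetes",
    alpha: float = 0.05,
    covariates: tuple = DEFAULT_COVARIATES,
) -> AssociationScan:
    """Fit an :class:`AssociationScan` and return the fitted estimator."""
    return AssociationScan(phenotype=phenotype, alpha=alpha, covariates=covariates).fit(
        fluids, cohort
    )
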