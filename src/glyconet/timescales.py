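"""Stratification of diabetes-associated metabolites by glycaemic timescale.

Within the diabetes cases only, every Bonferroni-significant
diabetes-associated measure is regressed (with the usual covariate
adjustment) on three markers of glycaemic control:

* **acute** (6–12 h): presence/absence of glucose in urine (glucosuria), a
  dichotomous detection indicator;
* **short_term** (1–2 weeks): plasma 1,5-anhydroglucitol, continuous;
* **long_term** (2–3 months): HbA1c (%), continuous.

Each candidate is labelled by the timescale with the strongest association
(largest −log10 p; ties broken by larger |β|, then the fixed order
acute < short_term < long_term) and placed into the Venn partition of the
three per-marker significant sets. A candidate measure identical to a
marker's source variable (urinary glucose vs acute, plasma 1,5-AG vs
short-term) is skipped and reported untested.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .association import (
    DEFAULT_COVARIATES,
    bonferroni_threshold,
    fit_metabolite_regression,
)
from .datatypes import FluidMatrix

__all__ = [
    "MARKER_NAMES",
    "detect_glucosuria",
    "TimescaleScan",
    "classify_primary_timescale",
    "venn_partition",
    "venn_region",
]

MARKER_NAMES = ("acute", "short_term", "long_term")
_TIE_ORDER = {name: i for i, name in enumerate(MARKER_NAMES)}


def detect_glucosuria(
    urine_raw: FluidMatrix, glucose_measure: str, cohort: pd.DataFrame
) -> pd.Series:
    """Dichotomous glucosuria indicator from the pre-imputation urine mask.

    True iff the urinary glucose measure was detected (non-missing before
    imputation); missing (``pd.NA``) for participants without a urine
    sample, who are excluded from acute-marker fits.
    """
    detected = urine_raw.data[glucose_measure].notna()
    out = pd.Series(detected, index=urine_raw.data.index, dtype="boolean")
    if "has_urine" in cohort:
        out[~cohort["has_urine"].reindex(out.index, fill_value=False)] = pd.NA
    return out.rename("glucosuria")


def classify_primary_timescale(
    neglog10_p: dict, beta: dict | None = None
) -> str:
    """Label a candidate by its strongest marker association.

    ``neglog10_p`` maps marker name to −log10(p) (``NaN``/absent markers
    are not considered). Ties on −log10 p are broken by larger |β|, then by
    the fixed order acute < short_term < long_term. Returns
    ``"unclassified"`` when no marker fit is estimable.
    """
    beta = beta or {}
    candidates = [
        (name, val)
        for name, val in neglog10_p.items()
        if name in MARKER_NAMES and val is not None and np.isfinite(val)
    ]
    if not candidates:
        return "unclassified"
    best = max(
        candidates,
        key=lambda item: (
            item[1],
            abs(beta.get(item[0], 0.0)) if np.isfinite(beta.get(item[0], np.nan)) else 0.0,
            -_TIE_ORDER[item[0]],
        ),
    )
    return best[0]


def venn_region(flags: dict) -> str:
    """Venn region label for one candidate's per-marker significance flags."""
    members = [name for name in MARKER_NAMES if flags.get(name)]
    return "&".join(members) if members else "none"


def venn_partition(flag_frame: pd.DataFrame) -> dict:
    """Counts over the 7 Venn regions plus 'none'.

    ``flag_frame`` holds one boolean column per marker, one row per
    candidate. Regions are disjoint and exhaustive, so the counts sum to
    the candidate-set size.
    """
    regions = {
        "&".join(combo): 0
        for r in (1, 2, 3)
        for combo in itertools.combinations(MARKER_NAMES, r)
    }
    regions["none"] = 0
    for _, row in flag_frame.iterrows():
        regions[venn_region(row.to_dict())] += 1
    return regions


class TimescaleScan(BaseEstimator):
    """Per-marker association scan over diabetes-associated candidates.

    Fits, on the case subcohort only, OLS of each candidate measure on each
    marker plus covariates; the Bonferroni family is the realised candidate
    count times three markers.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per candidate with per-marker beta/p/neglog10_p/significant
        columns, ``primary_timescale`` and ``venn_region``; untested
        (self-pair or unestimable) marker fits hold ``NaN``.
    threshold_ : float
        Realised Bonferroni threshold ``alpha / (n_candidates × 3)``.
    venn_counts_ : dict
        Region → count over candidates with at least one significant
        marker flag (non-significant candidates fall in ``"none"``).
    """

    def __init__(self, alpha: float = 0.05, covariates: tuple = DEFAULT_COVARIATES) -> None:
        self.alpha = alpha
        self.covariates = covariates

    def fit(
        self,
        candidates: pd.DataFrame,
        fluids: dict,
        cohort: pd.DataFrame,
        markers: dict,
        marker_sources: dict | None = None,
    ) -> "TimescaleScan":
        """Scan candidates against the three glycaemic markers.

        Parameters
        ----------
        candidates : DataFrame
            Rows with ``measure`` and ``fluid`` columns (typically the
            Bonferroni-significant slice of an association scan).
        fluids : dict
            Preprocessed fluid matrices (fluid → FluidMatrix).
        cohort : DataFrame
            Phenotype table; only rows with ``diabetes == 1`` are used.
        markers : dict
            Marker name → per-participant Series; the acute marker is the
            boolean glucosuria indicator, short_term/long_term continuous.
        marker_sources : dict, optional
            Marker name → measure id of the variable itself, used to skip
            self-pairs.
        """
        if candidates.empty:
            raise ValueError("candidate set must be non-empty")
        marker_sources = marker_sources or {}
        cases = cohort[cohort["diabetes"] == 1]

        self.n_candidates_ = len(candidates)
        self.m_ = self.n_candidates_ * len(MARKER_NAMES)
        self.threshold_ = bonferroni_threshold(self.alpha, self.m_)

        rows = []
        for _, cand in candidates.iterrows():
            measure, fluid = str(cand["measure"]), str(cand["fluid"])
            fm = fluids[fluid]
            has_col = f"has_{fluid}"
            sub = cases
            if has_col in cases:
                sub = cases[cases[has_col].astype(bool)]
            sub = sub.loc[sub.index.intersection(fm.data.index)]
            y = fm.data[measure].reindex(sub.index)

            row: dict = {"measure": measure, "fluid": fluid}
            neglog, betas, flags = {}, {}, {}
            for name in MARKER_NAMES:
                if marker_sources.get(name) == measure:
                    row.update({f"{name}_beta": np.nan, f"{name}_p": np.nan,
                                f"{name}_neglog10_p": np.nan, f"{name}_significant": False,
                                f"{name}_tested": False})
                    continue
                marker = markers[name]
                marker_num = pd.to_numeric(
                    marker.reindex(sub.index), errors="coerce"
                ).astype(float)
                rec = fit_metabolite_regression(
                    y, sub, phenotype=name, covariates=self.covariates,
                    fluid=fluid, phenotype_values=marker_num,
                )
                neglog[name] = -np.log10(rec.p) if rec.estimable and rec.p > 0 else (
                    np.inf if rec.estimable else np.nan
                )
                betas[name] = rec.beta
                flags[name] = bool(rec.estimable and rec.p < self.threshold_)
                row.update({
                    f"{name}_beta": rec.beta,
                    f"{name}_p": rec.p if rec.estimable else np.nan,
                    f"{name}_neglog10_p": neglog[name],
                    f"{name}_significant": flags[name],
                    f"{name}_tested": rec.estimable,
                })
            row["primary_timescale"] = classify_primary_timescale(neglog, betas)
            row["venn_region"] = venn_region(flags)
            rows.append(row)

        self.results_ = pd.DataFrame(rows)
        flag_frame = self.results_[[f"{n}_significant" for n in MARKER_NAMES]].rename(
            columns={f"{n}_significant": n for n in MARKER_NAMES}
        )
        self.venn_counts_ = venn_partition(flag_frame)
        return self

    def significant(self) -> pd.DataFrame:
        """Candidates significant for at least one marker."""
        return self.results_[self.results_["venn_region"] != "none"]

    def marker_counts(self) -> dict:
        """Per-marker significant counts (non-disjoint, unlike the Venn)."""
        return {
            name: int(self.results_[f"{name}_significant"].sum()) for name in MARKER_NAMES
        }
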