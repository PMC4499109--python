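"""Metabolite preprocessing: batch scaling, normalisation, transform, QC.

The fixed pipeline order is: run-day median scaling → osmolality
normalisation (saliva/urine only) → natural log → per-measure z-scoring →
outlier removal (|z| > k set missing) → minimum-value imputation →
low-detection filter. Each step is available as a module-level function on
:class:`~glyconet.datatypes.FluidMatrix`; :class:`FluidPreprocessor` chains
them and keeps an auditable :class:`~glyconet.datatypes.PreprocessReport`.

Left-censored missingness is imputed to the smallest detected value of the
measure, expressed on the transformed scale by pushing the raw minimum
through the donor cell's own run-day and osmolality factors before the
log-z transform (osmolality factors are participant-specific, so the
transformed column minimum would not be equivalent).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import FluidMatrix, PreprocessReport

__all__ = [
    "scale_by_runday_median",
    "normalize_osmolality",
    "log_z_transform",
    "remove_outliers",
    "impute_missing",
    "filter_low_detection",
    "FluidPreprocessor",
]


def scale_by_runday_median(m: FluidMatrix) -> FluidMatrix:
    """Divide each value by the median of its measure on its run-day.

    A (measure, run-day) group with no observed values is left missing.
    """
    data = m.data.copy()
    for day, idx in data.groupby(m.run_day).groups.items():
        block = data.loc[idx]
        med = block.median(axis=0, skipna=True)
        data.loc[idx] = block / med
    return m.copy_with(data)


def normalize_osmolality(m: FluidMatrix) -> FluidMatrix:
    """Divide each participant's row by that participant's osmolality.

    Plasma input is returned unchanged with a warning. A participant with
    data but no osmolality value has the whole row set missing.
    """
    if m.fluid == "plasma":
        warnings.warn("osmolality normalisation skipped for plasma", stacklevel=2)
        return m.copy_with(m.data.copy())
    osm = m.osmolality
    if osm is None:
        raise ValueError(f"{m.fluid} matrix lacks osmolality values")
    bad = osm.isna() & m.data.notna().any(axis=1)
    data = m.data.div(osm, axis=0)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} participants with data but no osmolality set to missing",
            stacklevel=2,
        )
        data.loc[bad] = np.nan
    return m.copy_with(data)


def log_z_transform(m: FluidMatrix) -> tuple[FluidMatrix, pd.DataFrame]:
    """Natural log, then centre/scale each measure to mean 0, SD 1.

    The sample SD uses the n−1 denominator over observed cells. Measures
    with fewer than two observations or zero variance are dropped. Returns
    the transformed matrix and a per-measure frame with columns ``mean``,
    ``sd`` and ``dropped_constant``.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        logged = np.log(m.data)
    mean = logged.mean(axis=0, skipna=True)
    sd = logged.std(axis=0, ddof=1, skipna=True)
    n_obs = logged.notna().sum(axis=0)
    ok = (n_obs >= 2) & (sd > 0)
    params = pd.DataFrame({"mean": mean, "sd": sd, "dropped_constant": ~ok})
    z = (logged.loc[:, ok] - mean[ok]) / sd[ok]
    return m.copy_with(z), params


def remove_outliers(m: FluidMatrix, k: float = 4.0) -> tuple[FluidMatrix, pd.Series]:
    """Set cells with |z| > k to missing; expects z-scored input."""
    mask = m.data.abs() > k
    data = m.data.mask(mask)
    return m.copy_with(data), mask.sum(axis=0)


def impute_missing(m: FluidMatrix, fill_values: pd.Series) -> tuple[FluidMatrix, pd.Series]:
    """Replace every missing cell with the measure's fill value.

    ``fill_values`` carries, per measure, the smallest detected raw value
    expressed on the current (transformed) scale. Output has no missing
    cells.
    """
    n_missing = m.data.isna().sum(axis=0)
    data = m.data.fillna(fill_values.reindex(m.data.columns))
    return m.copy_with(data), n_missing


def filter_low_detection(
    m: FluidMatrix, detections: pd.Series, min_detections: int = 50
) -> tuple[FluidMatrix, pd.Index]:
    """Drop measures with fewer than ``min_detections`` valid detections.

    ``detections`` must be computed on the raw matrix before imputation.
    """
    det = detections.reindex(m.data.columns).fillna(0)
    keep = det >= min_detections
    dropped = m.data.columns[~keep]
    return m.copy_with(m.data.loc[:, keep]), dropped


class FluidPreprocessor(BaseEstimator):
    """Transform one raw fluid matrix into the analysis-ready z-scored table.

    Parameters
    ----------
    min_detections : int, default 50
        Measures with fewer valid detections are excluded ("fewer than 50"
        → a measure with exactly 50 is kept).
    outlier_sd : float, default 4.0
        |z| beyond this many SDs is set missing before imputation.
    missing_rule : float, default 0.20
        Missing fraction above which a measure is flagged in the report.
        All missing cells are imputed regardless (the network stage needs a
        complete table); the flag records which measures cross the rule.

    Attributes (after :meth:`fit_transform`)
    ----------------------------------------
    report_ : PreprocessReport
        Per-measure audit of detections, imputations, outliers and drops.
    transform_params_ : pandas.DataFrame
        Per-retained-measure log-z parameters (mean, sd) and the imputation
        value used.
    """

    def __init__(
        self,
        min_detections: int = 50,
        outlier_sd: float = 4.0,
        missing_rule: float = 0.20,
    ) -> None:
        self.min_detections = min_detections
        self.outlier_sd = outlier_sd
        self.missing_rule = missing_rule

    def fit_transform(self, m: FluidMatrix) -> FluidMatrix:
        raw = m.data
        n_rows = raw.shape[0]
        detections = raw.notna().sum(axis=0)

        scaled = scale_by_runday_median(m)
        if m.fluid in ("saliva", "urine"):
            scaled = normalize_osmolality(scaled)
        zmat, zparams = log_z_transform(scaled)
        cleaned, n_outliers = remove_outliers(zmat, self.outlier_sd)

        fill = self._imputation_values(m, zparams)
        imputed, _ = impute_missing(cleaned, fill)
        filtered, low_det = filter_low_detection(imputed, detections, self.min_detections)

        retained = filtered.data.columns
        n_missing_final = n_rows - detections + n_outliers.reindex(raw.columns).fillna(0)
        reasons = pd.Series("", index=raw.columns, dtype=object)
        reasons[zparams.index[zparams["dropped_constant"]]] = "constant_or_too_few_values"
        reasons[low_det] = "low_detection"
        reasons[detections.index[detections == 0]] = "no_detections"
        dropped = ~raw.columns.isin(retained)

        per_measure = pd.DataFrame(
            {
                "n_detections": detections,
                "n_imputed": n_missing_final.where(~dropped, 0).astype(int),
                "n_outliers_removed": n_outliers.reindex(raw.columns).fillna(0).astype(int),
                "exceeds_missing_rule": (n_rows - detections) / n_rows > self.missing_rule,
                "dropped": dropped,
                "reason": reasons,
            }
        )
        self.report_ = PreprocessReport(
            fluid=m.fluid,
            per_measure=per_measure,
            n_input_measures=raw.shape[1],
            n_retained_measures=len(retained),
        )
        self.transform_params_ = zparams.loc[retained].assign(
            imputed_value=fill.reindex(retained)
        )
        self.detections_ = detections
        return filtered

    def _imputation_values(self, m: FluidMatrix, zparams: pd.DataFrame) -> pd.Series:
        """Smallest detected raw value per measure, on the transformed scale.

        The donor cell is the cell holding the raw minimum; its run-day
        median and osmolality are applied before the log-z transform, so
        the imputed constant equals the donor cell's own z-score.
        """
        raw = m.data
        day_groups = raw.groupby(m.run_day).groups

        day_medians = {}
        osm_factor = {}
        for day, idx in day_groups.items():
            day_medians[day] = raw.loc[idx].median(axis=0, skipna=True)
        if m.fluid in ("saliva", "urine") and m.osmolality is not None:
            osm = m.osmolality
        else:
            osm = pd.Series(1.0, index=raw.index)

        fill = pd.Series(np.nan, index=raw.columns)
        has_any = raw.notna().any(axis=0)
        donors = raw.loc[:, has_any].idxmin(axis=0)
        for measure, donor in donors.items():
            v = raw.at[donor, measure]
            med = day_medians[m.run_day.loc[donor]][measure]
            o = osm.loc[donor]
            if not np.isfinite(o):
                o = 1.0
            scaled = v / med / o
            mu, sd = zparams.at[measure, "mean"], zparams.at[measure, "sd"]
            if np.isfinite(mu) and np.isfinite(sd) and sd > 0:
                fill[measure] = (np.log(scaled) - mu) / sd
        return fill
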