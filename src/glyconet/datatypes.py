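"""Shared data containers for multi-fluid metabolomics analysis.

A study consists of a participant phenotype table (one row per participant)
and up to three fluid-specific intensity matrices (saliva, plasma, urine),
each carrying its own run-day assignment and, for saliva/urine, per-sample
osmolality. Missing cells encode either left-censoring (below the detection
limit) or an entirely absent fluid sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FLUIDS = ("saliva", "plasma", "urine")
ETHNICITIES = ("Arab", "South Asian", "Filipino", "Other")

#: phenotype columns required by the covariate-adjusted regressions
COVARIATE_COLUMNS = ("age", "sex", "ethnicity", "bmi")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


class GenerationError(RuntimeError):
    """Synthetic-data construction failed an internal guarantee."""


@dataclass
class FluidMatrix:
    """One fluid's participants × metabolite-measures intensity table.

    Parameters
    ----------
    fluid : str
        One of ``"saliva"``, ``"plasma"``, ``"urine"``.
    data : pandas.DataFrame
        Participants (rows, indexed by participant id) × measures (columns).
        ``NaN`` marks a missing cell. Raw intensities must be positive.
    run_day : pandas.Series
        Instrument run-day per participant (aligned with ``data.index``).
    osmolality : pandas.Series or None
        Sample osmolality per participant; ``None`` for plasma.
    """

    fluid: str
    data: pd.DataFrame
    run_day: pd.Series
    osmolality: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.fluid not in FLUIDS:
            raise ValueError(f"unknown fluid {self.fluid!r}; expected one of {FLUIDS}")
        if not self.data.index.is_unique:
            raise ValueError("participant ids must be unique")
        if not self.data.columns.is_unique:
            raise ValueError("measure ids must be unique")
        self.run_day = self.run_day.reindex(self.data.index)
        if self.osmolality is not None:
            self.osmolality = self.osmolality.reindex(self.data.index)

    @property
    def n_participants(self) -> int:
        return self.data.shape[0]

    @property
    def n_measures(self) -> int:
        return self.data.shape[1]

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask, True where a cell is missing."""
        return self.data.isna()

    def detection_counts(self) -> pd.Series:
        """Number of valid (non-missing) detections per measure."""
        return self.data.notna().sum(axis=0)

    def copy_with(self, data: pd.DataFrame) -> "FluidMatrix":
        """New FluidMatrix sharing metadata but holding ``data``."""
        return FluidMatrix(
            fluid=self.fluid,
            data=data,
            run_day=self.run_day.loc[data.index],
            osmolality=None if self.osmolality is None else self.osmolality.loc[data.index],
        )


@dataclass
class PreprocessReport:
    """Audit record of a preprocessing run on one fluid.

    ``per_measure`` has one row per input measure with columns
    ``n_detections``, ``n_imputed``, ``n_outliers_removed``,
    ``exceeds_missing_rule``, ``dropped`` and ``reason``.
    """

    fluid: str
    per_measure: pd.DataFrame
    n_input_measures: int = 0
    n_retained_measures: int = 0

    def __post_init__(self) -> None:
        dropped = int(self.per_measure["dropped"].sum())
        if dropped + self.n_retained_measures != self.n_input_measures:
            raise ValueError(
                "bookkeeping violated: dropped + retained != input "
                f"({dropped} + {self.n_retained_measures} != {self.n_input_measures})"
            )

    @property
    def dropped_measures(self) -> pd.DataFrame:
        return self.per_measure.loc[self.per_measure["dropped"]]


def make_participant_ids(n: int, prefix: str = "QM") -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"{prefix}{i + 1:0{width}d}" for i in range(n)], name="participant_id")


def measure_ids(fluid: str, n: int) -> list[str]:
    prefix = fluid[0].upper()
    return [f"{prefix}{i + 1:04d}" for i in range(n)]


def write_tsv(df: pd.DataFrame, path, index_label: str | None = "participant_id") -> None:
    """Write a table as TSV with empty fields for missing values."""
    df.to_csv(path, sep="\t", na_rep="", index_label=index_label, float_format="%.6g")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "participant_id"
    return df


def validate_probabilities(probs, name: str, atol: float = 1e-6) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=atol):
        raise ConfigurationError(f"{name} must be non-negative and sum to 1 (got {p})")
    return p / p.sum()
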