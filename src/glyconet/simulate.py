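"""Seeded synthetic case–control cohorts with multi-fluid metabolite data.

The generator emulates the statistical structure a cross-sectional diabetes
metabolomics study assumes: a case/control cohort with covariates (age, sex,
ethnicity, BMI), three partially overlapping fluid panels (saliva, plasma,
urine), instrument run-day batch factors, osmolality dilution for saliva and
urine, multiplicative measurement noise calibrated to per-fluid technical
CVs, left-censoring at per-measure detection limits, a sparse
partial-correlation network truth, diabetes mean shifts on a designated
subset of measures, and metabolite effects routed through three latent
glycaemic-burden variables (acute / short-term / long-term).

Two designated marker measures are generated directly from the latents:
plasma 1,5-anhydroglucitol (1,5-AG) decreases with the short-term latent,
and urinary glucose is detected (non-censored) exactly when the acute latent
exceeds a detection threshold calibrated to target glucosuria prevalences.

Every generator is deterministic given its config and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .datatypes import (
    ETHNICITIES,
    FLUIDS,
    ConfigurationError,
    FluidMatrix,
    GenerationError,
    make_participant_ids,
    measure_ids,
    validate_probabilities,
    write_tsv,
)

__all__ = [
    "CohortConfig",
    "MarkerConfig",
    "PanelConfig",
    "NoiseConfig",
    "NetworkConfig",
    "EffectConfig",
    "SimulationConfig",
    "NetworkTruth",
    "EffectTruth",
    "GlycaemicLatents",
    "SimulatedStudy",
    "generate_cohort",
    "generate_network_truth",
    "generate_glycaemic_markers",
    "generate_effects",
    "generate_fluid_matrices",
    "simulate_study",
    "qc_replicate_cv",
    "write_study",
]


# --------------------------------------------------------------------------
# configuration blocks
# --------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort composition and covariate distributions.

    Defaults reproduce the scale and mix of a 188-case / 181-control
    clinical study of Arab and Asian participants: cases older and heavier
    than controls, four ethnicity strata, per-fluid sample availability of
    328/359/356 out of 369, and twelve instrument run-days.
    """

    n_cases: int = 188
    n_controls: int = 181
    seed: int = 0
    age_case: tuple[float, float] = (54.0, 11.0)      # mean, SD (years)
    age_control: tuple[float, float] = (41.0, 12.0)
    bmi_case: tuple[float, float] = (30.0, 6.0)       # mean, SD (kg/m^2)
    bmi_control: tuple[float, float] = (28.0, 5.5)
    female_prob_case: float = 81 / 188
    female_prob_control: float = 99 / 181
    ethnicity_probs_case: tuple[float, ...] = (93 / 188, 74 / 188, 14 / 188, 7 / 188)
    ethnicity_probs_control: tuple[float, ...] = (113 / 181, 39 / 181, 22 / 181, 7 / 181)
    availability: dict = field(
        default_factory=lambda: {"saliva": 328 / 369, "plasma": 359 / 369, "urine": 356 / 369}
    )
    n_run_days: int = 12
    osmolality_logmean: dict = field(
        default_factory=lambda: {"saliva": math.log(70.0), "urine": math.log(600.0)}
    )
    osmolality_logsd: dict = field(default_factory=lambda: {"saliva": 0.35, "urine": 0.45})

    def validate(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ConfigurationError("n_cases and n_controls must be >= 1")
        if self.n_run_days < 1:
            raise ConfigurationError("n_run_days must be >= 1")
        validate_probabilities(self.ethnicity_probs_case, "ethnicity_probs_case")
        validate_probabilities(self.ethnicity_probs_control, "ethnicity_probs_control")
        for prob in (self.female_prob_case, self.female_prob_control):
            if not 0.0 <= prob <= 1.0:
                raise ConfigurationError("sex probabilities must be in [0, 1]")
        for fluid, avail in self.availability.items():
            if fluid not in FLUIDS:
                raise ConfigurationError(f"unknown fluid {fluid!r}")
            if not 0.0 < avail <= 1.0:
                raise ConfigurationError("availability probabilities must be in (0, 1]")


@dataclass
class MarkerConfig:
    """Latent glycaemic-burden model and its observable markers.

    Three correlated latents represent glycaemic dysregulation on acute
    (hours), short-term (1–2 week) and long-term (2–3 month) timescales.
    Controls draw each latent from N(0, 1); cases from N(shift, case_sd^2).
    The acute case shift and the glucosuria detection threshold are derived
    in closed form from the two target detection prevalences. HbA1c (%) is a
    noisy affine readout of the long-term latent; plasma 1,5-AG (log scale)
    is a noisy negative readout of the short-term latent.
    """

    latent_corr: float = 0.4
    case_shift_acute: float | None = None     # None -> calibrated from prevalences
    case_shift_short: float = 1.5
    case_shift_long: float = 2.2
    case_latent_sd: float = 1.3
    glucosuria_case_rate: float = 66 / 188
    glucosuria_control_rate: float = 2 / 181
    glucosuria_threshold: float | None = None  # None -> calibrated
    hba1c_base: float = 5.5                   # %
    hba1c_slope: float = 0.55                 # % per latent SD
    hba1c_noise_sd: float = 0.3
    ag_slope: float = 0.8                     # log-intensity per latent SD (negative sign applied)
    ag_noise_sd: float = 0.5

    def calibrated_threshold(self) -> float:
        if self.glucosuria_threshold is not None:
            return self.glucosuria_threshold
        return float(stats.norm.ppf(1.0 - self.glucosuria_control_rate))

    def calibrated_acute_shift(self) -> float:
        if self.case_shift_acute is not None:
            return self.case_shift_acute
        c = self.calibrated_threshold()
        return float(c + self.case_latent_sd * stats.norm.ppf(self.glucosuria_case_rate))


@dataclass
class PanelConfig:
    """Fluid-specific measure panels.

    Default sizes 581 (saliva) / 720 (plasma) / 877 (urine) give 2,178
    fluid-specific measures. The first plasma measure is designated 1,5-AG
    and the first urine measure urinary glucose.
    """

    sizes: dict = field(default_factory=lambda: {"saliva": 581, "plasma": 720, "urine": 877})
    ag_measure: str = "P0001"
    glucose_measure: str = "U0001"
    # cross-fluid duplication: groups of measures reading the same molecule
    # in different fluids load on one shared latent column
    n_shared_triples: int = 147
    n_shared_pairs: int = 391
    duplicate_loading: float = 0.7

    @property
    def total(self) -> int:
        return int(sum(self.sizes.values()))

    def all_measures(self) -> dict:
        """Mapping fluid -> list of measure ids, in canonical fluid order."""
        return {fluid: measure_ids(fluid, self.sizes[fluid]) for fluid in FLUIDS}

    def annotation(self) -> pd.DataFrame:
        rows = []
        for fluid in FLUIDS:
            for mid in measure_ids(fluid, self.sizes[fluid]):
                if mid == self.ag_measure:
                    name, pathway = "1,5-AG", "Carbohydrate"
                elif mid == self.glucose_measure:
                    name, pathway = "glucose", "Carbohydrate"
                else:
                    name, pathway = f"X-{mid}", "Unknown"
                rows.append({"measure": mid, "name": name, "super_pathway": pathway, "fluid": fluid})
        return pd.DataFrame(rows).set_index("measure")


@dataclass
class NoiseConfig:
    """Technical noise, batch structure and left-censoring.

    ``cv_target`` sets the per-fluid multiplicative noise so the technical
    CV of repeated measurements matches the given fractions (defaults
    15.3% / 15.8% / 9.8%). Run-day batch factors are log-normal per
    (measure, run-day). Per-measure censoring quantiles are drawn from a
    Beta(1.2, 8) bulk plus a small heavy-censoring component emulating
    rarely detected xenobiotics; ``censor_quantile`` fixes a single
    quantile for every measure instead (0 disables censoring).
    """

    cv_target: dict = field(
        default_factory=lambda: {"saliva": 0.153, "plasma": 0.158, "urine": 0.098}
    )
    batch_sd: float = 0.15
    censor_quantile: float | None = None
    censor_beta: tuple[float, float] = (1.2, 8.0)
    heavy_censor_fraction: float = 0.03
    heavy_censor_range: tuple[float, float] = (0.80, 0.98)

    def noise_log_sd(self, fluid: str) -> float:
        cv = float(self.cv_target[fluid])
        return math.sqrt(math.log1p(cv * cv))


@dataclass
class NetworkConfig:
    """Sparse partial-correlation ground truth for the metabolite panel."""

    edge_density: float = 0.0016
    pcor_range: tuple[float, float] = (0.3, 0.8)

    def validate(self, p: int) -> None:
        if p < 3:
            raise ConfigurationError("network truth needs p >= 3")
        if not 0.0 <= self.edge_density < 0.5:
            raise ConfigurationError("edge_density must be in [0, 0.5)")
        lo, hi = self.pcor_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError("pcor magnitudes must be in (0, 1)")


@dataclass
class EffectConfig:
    """Diabetes and glycaemic-latent effect sizes on the panel.

    A fraction of measures receives a diabetes mean shift (in latent-SD
    units, signed); a fraction of those additionally loads on exactly one
    glycaemic latent, so its within-case variation tracks one timescale.
    """

    diabetes_fraction: float = 0.043
    diabetes_effect_range: tuple[float, float] = (0.45, 1.25)
    timescale_fraction: float = 0.7
    timescale_effect_range: tuple[float, float] = (0.4, 1.0)


@dataclass
class SimulationConfig:
    """Complete recipe for one synthetic study."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    effects: EffectConfig = field(default_factory=EffectConfig)
    seed: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        def tuplify(obj):
            return tuple(obj) if isinstance(obj, list) else obj

        kwargs = {}
        for name, sub_cls in (
            ("cohort", CohortConfig),
            ("markers", MarkerConfig),
            ("panel", PanelConfig),
            ("noise", NoiseConfig),
            ("network", NetworkConfig),
            ("effects", EffectConfig),
        ):
            if name in raw:
                sub = {k: tuplify(v) for k, v in raw[name].items()}
                kwargs[name] = sub_cls(**sub)
        if "seed" in raw:
            kwargs["seed"] = int(raw["seed"])
        return cls(**kwargs)


# --------------------------------------------------------------------------
# ground-truth containers
# --------------------------------------------------------------------------

@dataclass
class NetworkTruth:
    """Known sparse conditional-dependence structure of the panel.

    ``precision`` has unit diagonal; ``pcor`` holds the implied partial
    correlations (``-omega_ij`` for a unit-diagonal precision matrix);
    ``edges`` is exactly the off-diagonal support.
    """

    precision: np.ndarray
    pcor: np.ndarray
    edges: list[tuple[int, int]]

    @property
    def p(self) -> int:
        return self.precision.shape[0]

    def correlation(self) -> np.ndarray:
        """Marginal correlation matrix implied by the precision matrix."""
        cov = np.linalg.inv(self.precision)
        d = np.sqrt(np.diag(cov))
        return cov / np.outer(d, d)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j in self.edges}


@dataclass
class EffectTruth:
    """Per-measure effect sizes (latent-SD units); 0 means no effect."""

    diabetes: np.ndarray
    acute: np.ndarray
    short_term: np.ndarray
    long_term: np.ndarray

    @property
    def p(self) -> int:
        return self.diabetes.shape[0]

    def null_mask(self) -> np.ndarray:
        """Measures with every effect exactly zero."""
        return (
            (self.diabetes == 0)
            & (self.acute == 0)
            & (self.short_term == 0)
            & (self.long_term == 0)
        )

    @classmethod
    def zeros(cls, p: int) -> "EffectTruth":
        z = np.zeros(p)
        return cls(z.copy(), z.copy(), z.copy(), z.copy())


@dataclass
class GlycaemicLatents:
    """Latent glycaemic burden per participant and its observable markers."""

    latents: pd.DataFrame            # columns: acute, short_term, long_term
    hba1c: pd.Series                 # %
    ag_log_abundance: pd.Series      # log-intensity driven by short-term latent
    glucosuria: pd.Series            # boolean; NA for participants without urine
    threshold: float

    def marker_frame(self) -> pd.DataFrame:
        out = self.latents.copy()
        out["hba1c"] = self.hba1c
        out["ag_log_abundance"] = self.ag_log_abundance
        out["glucosuria"] = self.glucosuria
        return out


@dataclass
class SimulatedStudy:
    """Everything one synthetic study run produced, truth included."""

    cohort: pd.DataFrame
    latents: GlycaemicLatents
    fluids: dict
    truth: NetworkTruth
    effects: EffectTruth
    annotation: pd.DataFrame
    measure_index: pd.Index          # global measure order matching truth/effects
    config: SimulationConfig
    duplicate_groups: list = field(default_factory=list)


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a phenotype table of ``n_cases + n_controls`` participants.

    Enrolment order is randomised, run-days are assigned round-robin in
    enrolment order, and per-fluid availability flags plus saliva/urine
    osmolality are drawn per participant. Deterministic given the config's
    seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls

    diabetes = np.concatenate([np.ones(config.n_cases, int), np.zeros(config.n_controls, int)])
    order = rng.permutation(n)
    diabetes = diabetes[order]
    is_case = diabetes == 1

    def per_group(case_params, control_params, lo, hi):
        vals = np.where(
            is_case,
            rng.normal(*case_params, size=n),
            rng.normal(*control_params, size=n),
        )
        return np.clip(vals, lo, hi)

    age = per_group(config.age_case, config.age_control, 20.0, 90.0)
    bmi = per_group(config.bmi_case, config.bmi_control, 16.0, 55.0)
    female_prob = np.where(is_case, config.female_prob_case, config.female_prob_control)
    sex = np.where(rng.random(n) < female_prob, "female", "male")

    eth = np.empty(n, dtype=object)
    eth_draw = rng.random(n)
    for params, mask in (
        (config.ethnicity_probs_case, is_case),
        (config.ethnicity_probs_control, ~is_case),
    ):
        cuts = np.cumsum(validate_probabilities(params, "ethnicity probabilities"))
        eth[mask] = np.array(ETHNICITIES, dtype=object)[
            np.searchsorted(cuts, eth_draw[mask], side="right").clip(0, 3)
        ]

    cohort = pd.DataFrame(
        {
            "diabetes": diabetes,
            "age": np.round(age, 1),
            "sex": sex,
            "ethnicity": eth,
            "bmi": np.round(bmi, 1),
            "run_day": np.arange(n) % config.n_run_days + 1,
        },
        index=make_participant_ids(n),
    )
    for fluid in FLUIDS:
        cohort[f"has_{fluid}"] = rng.random(n) < config.availability.get(fluid, 1.0)
    for fluid in ("saliva", "urine"):
        osm = rng.lognormal(config.osmolality_logmean[fluid], config.osmolality_logsd[fluid], n)
        osm[~cohort[f"has_{fluid}"].to_numpy()] = np.nan
        cohort[f"osmolality_{fluid}"] = np.round(osm, 2)
    return cohort


def generate_network_truth(
    p: int,
    edge_density: float,
    pcor_range: tuple[float, float] = (0.3, 0.8),
    seed: int = 0,
    min_eigenvalue: float = 0.05,
) -> NetworkTruth:
    """Sparse positive-definite precision matrix with known support.

    Support is Bernoulli(``edge_density``) over pairs; target partial
    correlations get magnitudes uniform in ``pcor_range`` with random sign.
    Starting from a unit-diagonal matrix with ``-rho`` off-diagonals, the
    diagonal is inflated until the smallest eigenvalue reaches
    ``min_eigenvalue`` and the matrix is rescaled back to unit diagonal
    (uniform inflation preserves the support exactly). The recorded partial
    correlations are computed from the final matrix, so they may sit
    slightly below the requested magnitudes when repair was needed.
    """
    cfg = NetworkConfig(edge_density=edge_density, pcor_range=pcor_range)
    cfg.validate(p)
    rng = np.random.default_rng(seed)

    iu = np.triu_indices(p, k=1)
    support = rng.random(iu[0].shape[0]) < edge_density
    lo, hi = pcor_range
    mags = rng.uniform(lo, hi, size=int(support.sum()))
    signs = rng.choice([-1.0, 1.0], size=mags.shape[0])

    omega = np.eye(p)
    rows, cols = iu[0][support], iu[1][support]
    omega[rows, cols] = omega[cols, rows] = -(mags * signs)

    if support.any():
        lam_min = float(np.linalg.eigvalsh(omega)[0])
        if lam_min < min_eigenvalue:
            d = 1.0 + (min_eigenvalue - lam_min)
            omega[np.diag_indices(p)] = d
            omega /= d  # rescale to unit diagonal; off-diagonals shrink uniformly
        lam_check = float(np.linalg.eigvalsh(omega)[0])
        if lam_check <= 0:
            raise GenerationError("precision matrix not positive definite after repair")

    pcor = -omega.copy()
    np.fill_diagonal(pcor, 1.0)
    edges = list(zip(rows.tolist(), cols.tolist()))
    return NetworkTruth(precision=omega, pcor=pcor, edges=edges)


def generate_glycaemic_markers(
    cohort: pd.DataFrame, params: MarkerConfig | None = None, seed: int = 0
) -> GlycaemicLatents:
    """Draw glycaemic latents and their observable markers for a cohort.

    Cases draw latents from shifted (and optionally wider) normals; HbA1c
    rises with the long-term latent, plasma 1,5-AG falls with the
    short-term latent, and glucosuria is the acute latent exceeding the
    calibrated detection threshold. The glucosuria indicator is missing for
    participants without a urine sample.
    """
    params = params or MarkerConfig()
    rng = np.random.default_rng(seed)
    n = len(cohort)
    is_case = cohort["diabetes"].to_numpy() == 1

    corr = np.full((3, 3), params.latent_corr)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n, 3)) @ chol.T

    shifts = np.array(
        [params.calibrated_acute_shift(), params.case_shift_short, params.case_shift_long]
    )
    scale = np.where(is_case[:, None], params.case_latent_sd, 1.0)
    latents = z * scale + np.where(is_case[:, None], shifts[None, :], 0.0)
    latents = pd.DataFrame(
        latents, index=cohort.index, columns=["acute", "short_term", "long_term"]
    )

    hba1c = (
        params.hba1c_base
        + params.hba1c_slope * latents["long_term"]
        + rng.normal(0.0, params.hba1c_noise_sd, n)
    )
    ag = -params.ag_slope * latents["short_term"] + rng.normal(0.0, params.ag_noise_sd, n)

    threshold = params.calibrated_threshold()
    glucosuria = pd.Series(latents["acute"] > threshold, index=cohort.index, dtype="boolean")
    glucosuria[~cohort["has_urine"]] = pd.NA

    return GlycaemicLatents(
        latents=latents,
        hba1c=pd.Series(np.round(hba1c, 2), index=cohort.index, name="hba1c"),
        ag_log_abundance=pd.Series(ag, index=cohort.index, name="ag_log_abundance"),
        glucosuria=glucosuria.rename("glucosuria"),
        threshold=float(threshold),
    )


def generate_effects(
    panel: PanelConfig,
    config: EffectConfig | None = None,
    seed: int = 0,
) -> EffectTruth:
    """Assign diabetes and timescale effect sizes across the panel.

    The designated marker measures (plasma 1,5-AG, urinary glucose) are
    excluded here; their signal comes directly from the latents during data
    generation.
    """
    config = config or EffectConfig()
    rng = np.random.default_rng(seed)
    p = panel.total
    order = [m for fluid in FLUIDS for m in measure_ids(fluid, panel.sizes[fluid])]
    special = {order.index(panel.ag_measure), order.index(panel.glucose_measure)}

    effects = EffectTruth.zeros(p)
    candidates = np.array([i for i in range(p) if i not in special])
    n_affected = int(round(config.diabetes_fraction * p))
    affected = rng.choice(candidates, size=min(n_affected, candidates.size), replace=False)
    lo, hi = config.diabetes_effect_range
    effects.diabetes[affected] = rng.uniform(lo, hi, affected.size) * rng.choice(
        [-1.0, 1.0], affected.size
    )

    n_ts = int(round(config.timescale_fraction * affected.size))
    ts_measures = rng.choice(affected, size=n_ts, replace=False)
    tlo, thi = config.timescale_effect_range
    arrays = (effects.acute, effects.short_term, effects.long_term)
    which = rng.integers(0, 3, size=n_ts)
    gammas = rng.uniform(tlo, thi, size=n_ts) * np.sign(effects.diabetes[ts_measures])
    for idx, w, g in zip(ts_measures, which, gammas):
        arrays[w][idx] = g
    return effects


def _draw_duplicate_groups(panel: PanelConfig, reserved: set, rng) -> list[list[int]]:
    """Disjoint cross-fluid measure groups sharing one latent column.

    Triples take one unused measure from each fluid; pairs take one from
    each of a random fluid pair. Designated marker columns never join a
    group. Group counts are capped by panel capacity.
    """
    offsets = {}
    pos = 0
    for fluid in FLUIDS:
        offsets[fluid] = pos
        pos += panel.sizes[fluid]
    free = {
        fluid: [
            offsets[fluid] + i
            for i in range(panel.sizes[fluid])
            if offsets[fluid] + i not in reserved
        ]
        for fluid in FLUIDS
    }
    for fluid in FLUIDS:
        free[fluid] = list(rng.permutation(free[fluid]))

    groups: list[list[int]] = []
    for _ in range(panel.n_shared_triples):
        if any(not free[f] for f in FLUIDS):
            break
        groups.append([free[f].pop() for f in FLUIDS])
    pair_choices = [("saliva", "plasma"), ("saliva", "urine"), ("plasma", "urine")]
    for _ in range(panel.n_shared_pairs):
        order = rng.permutation(3)
        chosen = None
        for k in order:
            f1, f2 = pair_choices[k]
            if free[f1] and free[f2]:
                chosen = (f1, f2)
                break
        if chosen is None:
            break
        groups.append([free[chosen[0]].pop(), free[chosen[1]].pop()])
    return groups


def _censor_quantiles(noise: NoiseConfig, n_measures: int, rng) -> np.ndarray:
    if noise.censor_quantile is not None:
        return np.full(n_measures, float(noise.censor_quantile))
    a, b = noise.censor_beta
    q = rng.beta(a, b, n_measures)
    heavy = rng.random(n_measures) < noise.heavy_censor_fraction
    lo, hi = noise.heavy_censor_range
    q[heavy] = rng.uniform(lo, hi, int(heavy.sum()))
    return q


def generate_fluid_matrices(
    cohort: pd.DataFrame,
    truth: NetworkTruth,
    effects: EffectTruth,
    latents: GlycaemicLatents,
    noise: NoiseConfig | None = None,
    panel: PanelConfig | None = None,
    seed: int = 0,
) -> tuple[dict, dict]:
    """Generate the three fluid intensity matrices from the ground truth.

    Log-abundances are multivariate normal with the correlation implied by
    the network truth, mean-shifted by diabetes status and by the glycaemic
    latents; intensities are the exponentials, multiplied by per-(measure,
    run-day) batch factors, scaled by osmolality dilution (saliva/urine),
    and degraded by log-normal noise matching the per-fluid CV targets.
    Values below each measure's detection quantile are censored to missing;
    participants lacking a fluid have that fluid's row entirely missing.

    Returns ``(fluids, truth_record)`` where ``fluids`` maps fluid name to
    :class:`FluidMatrix` and ``truth_record`` carries the per-measure censor
    quantiles and the noise-free log-abundance table used downstream in
    tests.
    """
    noise = noise or NoiseConfig()
    panel = panel or PanelConfig()
    p = panel.total
    if truth.p != p or effects.p != p:
        raise GenerationError(
            f"dimension mismatch: panel has {p} measures, truth {truth.p}, effects {effects.p}"
        )
    rng = np.random.default_rng(seed)
    n = len(cohort)
    order = [m for fluid in FLUIDS for m in measure_ids(fluid, panel.sizes[fluid])]
    measure_index = pd.Index(order, name="measure")

    corr = truth.correlation()
    chol = np.linalg.cholesky(corr + 1e-10 * np.eye(p))
    log_abund = rng.standard_normal((n, p)) @ chol.T

    dm = cohort["diabetes"].to_numpy()[:, None]
    lat = latents.latents.to_numpy()
    log_abund = (
        log_abund
        + dm * effects.diabetes[None, :]
        + lat[:, [0]] * effects.acute[None, :]
        + lat[:, [1]] * effects.short_term[None, :]
        + lat[:, [2]] * effects.long_term[None, :]
    )

    # designated marker measures are generated straight from the latents
    ag_col = measure_index.get_loc(panel.ag_measure)
    glu_col = measure_index.get_loc(panel.glucose_measure)
    log_abund[:, ag_col] = latents.ag_log_abundance.to_numpy()
    log_abund[:, glu_col] = 0.8 * lat[:, 0] + rng.normal(0.0, 0.5, n)

    # cross-fluid shared molecules: member columns load on the group's
    # source column plus idiosyncratic residual (same molecule read out in
    # several fluids correlates strongly across fluids)
    duplicate_groups = _draw_duplicate_groups(panel, {ag_col, glu_col}, rng)
    a = float(np.clip(panel.duplicate_loading, 0.0, 1.0))
    for group in duplicate_groups:
        source = group[0]
        for member in group[1:]:
            log_abund[:, member] = math.sqrt(a) * log_abund[:, source] + math.sqrt(
                1.0 - a
            ) * rng.standard_normal(n)

    censor_q = _censor_quantiles(noise, p, rng)

    fluids: dict = {}
    col0 = 0
    run_day = cohort["run_day"]
    n_days = int(run_day.max())
    for fluid in FLUIDS:
        cols = slice(col0, col0 + panel.sizes[fluid])
        mids = measure_index[cols]
        col0 += panel.sizes[fluid]

        log_int = log_abund[:, cols].copy()
        # per-(measure, run-day) batch shifts
        batch = rng.normal(0.0, noise.batch_sd, (n_days, len(mids)))
        log_int += batch[run_day.to_numpy() - 1, :]
        # osmolality dilution (concentration scales with osmolality)
        if fluid in ("saliva", "urine"):
            osm = cohort[f"osmolality_{fluid}"].to_numpy()
            ref = np.exp(CohortConfig().osmolality_logmean[fluid])
            with np.errstate(invalid="ignore"):
                log_int += np.log(np.where(np.isnan(osm), 1.0, osm) / ref)[:, None]
        # technical noise at the fluid's CV target
        log_int += rng.normal(0.0, noise.noise_log_sd(fluid), log_int.shape)

        intensity = np.exp(log_int)
        # missing fluid -> whole row missing (before detection limits are set)
        intensity[~cohort[f"has_{fluid}"].to_numpy(), :] = np.nan

        # left-censoring at per-measure detection quantiles
        q = censor_q[measure_index.get_indexer(mids)]
        limits = np.full(len(mids), -np.inf)
        for j in np.flatnonzero(q > 0):
            col = intensity[:, j]
            obs = col[~np.isnan(col)]
            if obs.size:
                limits[j] = np.quantile(obs, min(q[j], 1.0))
        with np.errstate(invalid="ignore"):
            intensity = np.where(intensity < limits[None, :], np.nan, intensity)

        data = pd.DataFrame(intensity, index=cohort.index, columns=mids)
        # urinary glucose detection is driven by the acute latent
        if fluid == "urine":
            detected = latents.glucosuria.fillna(False).to_numpy(dtype=bool)
            col = data[panel.glucose_measure].to_numpy()
            col[~detected] = np.nan
            data[panel.glucose_measure] = col

        osm_series = (
            cohort[f"osmolality_{fluid}"] if fluid in ("saliva", "urine") else None
        )
        fluids[fluid] = FluidMatrix(
            fluid=fluid, data=data, run_day=run_day, osmolality=osm_series
        )

    truth_record = {
        "censor_quantiles": pd.Series(censor_q, index=measure_index),
        "log_abundance": pd.DataFrame(log_abund, index=cohort.index, columns=measure_index),
        "measure_index": measure_index,
        "duplicate_groups": [
            [measure_index[i] for i in group] for group in duplicate_groups
        ],
    }
    return fluids, truth_record


def simulate_study(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    truth: NetworkTruth | None = None,
    effects: EffectTruth | None = None,
) -> SimulatedStudy:
    """Run every generator and bundle the study with its ground truth.

    ``truth`` and ``effects`` may be supplied to plant a known structure
    (used by end-to-end recovery tests); otherwise they are drawn from the
    config. ``seed`` overrides ``config.seed``.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config.seed = int(seed)
        config.cohort.seed = int(seed)
    else:
        config.cohort.seed = config.seed
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    cohort = generate_cohort(config.cohort)
    latents = generate_glycaemic_markers(cohort, config.markers, seed=seeds[0])
    if truth is None:
        truth = generate_network_truth(
            config.panel.total,
            config.network.edge_density,
            config.network.pcor_range,
            seed=seeds[1],
        )
    if effects is None:
        effects = generate_effects(config.panel, config.effects, seed=seeds[2])
    fluids, record = generate_fluid_matrices(
        cohort, truth, effects, latents, config.noise, config.panel, seed=seeds[3]
    )
    return SimulatedStudy(
        cohort=cohort,
        latents=latents,
        fluids=fluids,
        truth=truth,
        effects=effects,
        annotation=config.panel.annotation(),
        measure_index=record["measure_index"],
        config=config,
        duplicate_groups=record["duplicate_groups"],
    )


def qc_replicate_cv(
    cv_target: float, n_replicates: int, n_measures: int, seed: int = 0
) -> pd.Series:
    """Per-measure CV from simulated technical replicates of a pooled sample.

    Emulates the repeated measurement of one pooled QC sample: every
    replicate differs only by the multiplicative measurement noise, so the
    per-measure coefficient of variation estimates the process CV.
    """
    rng = np.random.default_rng(seed)
    sd = math.sqrt(math.log1p(cv_target * cv_target))
    reps = np.exp(rng.normal(0.0, sd, (n_replicates, n_measures)))
    return pd.Series(reps.std(axis=0, ddof=1) / reps.mean(axis=0), name="cv")


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write phenotypes, fluid matrices, annotation and truth as TSV/YAML."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_tsv(study.cohort, outdir / "phenotypes.tsv")
    for fluid, fm in study.fluids.items():
        write_tsv(fm.data, outdir / f"fluid_{fluid}.tsv")
    write_tsv(study.annotation, outdir / "annotation.tsv", index_label="measure")
    write_tsv(study.latents.marker_frame(), outdir / "glycaemic_markers.tsv")
    edges = pd.DataFrame(
        [
            {
                "node_i": study.measure_index[i],
                "node_j": study.measure_index[j],
                "pcor": study.truth.pcor[i, j],
            }
            for i, j in study.truth.edges
        ]
    )
    edges.to_csv(outdir / "truth_edges.tsv", sep="\t", index=False)
    eff = pd.DataFrame(
        {
            "diabetes": study.effects.diabetes,
            "acute": study.effects.acute,
            "short_term": study.effects.short_term,
            "long_term": study.effects.long_term,
        },
        index=study.measure_index,
    )
    write_tsv(eff, outdir / "truth_effects.tsv", index_label="measure")
    study.config.to_yaml(outdir / "config.yaml")
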