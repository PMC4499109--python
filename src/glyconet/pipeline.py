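"""End-to-end workflow orchestration and paper-style summary artefacts.

``run_pipeline`` drives simulate/load → preprocess → association scan →
timescale stratification → GGM → subnetwork extraction, writing every
intermediate table as TSV (one-line header, empty field = missing, floats
at 6 significant figures) plus GraphML/SIF exports, a YAML copy of the
config actually used and a JSON run summary. Deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ggm, simulate as sim
from .association import DEFAULT_COVARIATES, AssociationScan, build_design
from .datatypes import FLUIDS, FluidMatrix, read_matrix_tsv, write_tsv
from .preprocess import FluidPreprocessor
from .timescales import MARKER_NAMES, TimescaleScan, detect_glucosuria

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "count_unique_measures"]

log = logging.getLogger("glyconet")


def count_unique_measures(n_triple: int, n_double: int, n_single: int) -> tuple[int, int]:
    """Unique metabolites and fluid-specific signals from multiplicity counts.

    A molecule detected in all three fluids contributes three signals, one
    detected in two fluids two, and so on:
    ``unique = n3 + n2 + n1``; ``signals = 3*n3 + 2*n2 + n1``.
    """
    if min(n_triple, n_double, n_single) < 0:
        raise ValueError("multiplicity counts must be non-negative")
    return n_triple + n_double + n_single, 3 * n_triple + 2 * n_double + n_single


@dataclass
class RunConfig:
    """Single config driving both simulation and analysis."""

    simulate: sim.SimulationConfig | None = field(default_factory=sim.SimulationConfig)
    input_dir: str | None = None       # load TSVs from here instead of simulating
    alpha: float = 0.05
    min_detections: int = 50
    outlier_sd: float = 4.0
    missing_rule: float = 0.20
    min_subnetwork_size: int = 3
    covariates: tuple = DEFAULT_COVARIATES
    ggm_covariates: tuple = ("diabetes",) + DEFAULT_COVARIATES
    n_effective: int | None = None
    seed: int = 0
    outdir: str = "glyconet_run"

    def validate(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")
        for name in ("outlier_sd", "missing_rule"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_detections < 0 or self.min_subnetwork_size < 1:
            raise ValueError("thresholds must be positive")
        if self.simulate is None and self.input_dir is None:
            raise ValueError("either a simulate block or an input_dir is required")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["covariates"] = list(self.covariates)
        raw["ggm_covariates"] = list(self.ggm_covariates)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = sim.SimulationConfig.from_dict(raw["simulate"])
        for key in ("covariates", "ggm_covariates"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunSummary:
    """Counts at every workflow step plus the thresholds and seed used."""

    seed: int
    n_participants: int = 0
    n_cases: int = 0
    n_controls: int = 0
    n_input_measures: int = 0
    n_measures_tested: int = 0
    measures_per_fluid: dict = field(default_factory=dict)
    bonferroni_threshold: float = 0.0
    n_bonferroni: int = 0
    bonferroni_per_fluid: dict = field(default_factory=dict)
    n_nominal: int = 0
    timescale_threshold: float = 0.0
    n_timescale_associated: int = 0
    timescale_per_marker: dict = field(default_factory=dict)
    venn_counts: dict = field(default_factory=dict)
    edge_threshold: float = 0.0
    n_pairs: int = 0
    n_edges: int = 0
    n_connected_nodes: int = 0
    ggm_shrinkage: float = 0.0
    n_subnetworks: int = 0
    subnetwork_sizes: list = field(default_factory=list)
    n_subnetwork_measures: int = 0
    thresholds: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)
        log.info("summary written to %s", path)

    def check_consistency(self) -> None:
        """Internal bookkeeping identities."""
        assert self.n_cases + self.n_controls == self.n_participants
        assert sum(self.measures_per_fluid.values()) == self.n_measures_tested
        assert sum(self.bonferroni_per_fluid.values()) == self.n_bonferroni
        assert sum(self.venn_counts.values()) == max(self.n_bonferroni, 0) or not self.venn_counts
        assert sum(self.subnetwork_sizes) == self.n_subnetwork_measures


def _load_study(config: RunConfig):
    indir = Path(config.input_dir)
    cohort = pd.read_csv(indir / "phenotypes.tsv", sep="\t", index_col=0)
    fluids = {}
    for fluid in FLUIDS:
        path = indir / f"fluid_{fluid}.tsv"
        if not path.exists():
            continue
        data = read_matrix_tsv(path)
        osm = cohort.get(f"osmolality_{fluid}")
        fluids[fluid] = FluidMatrix(
            fluid=fluid, data=data, run_day=cohort["run_day"], osmolality=osm
        )
    ann_path = indir / "annotation.tsv"
    annotation = (
        pd.read_csv(ann_path, sep="\t", index_col=0) if ann_path.exists() else None
    )
    markers_path = indir / "glycaemic_markers.tsv"
    markers = (
        pd.read_csv(markers_path, sep="\t", index_col=0) if markers_path.exists() else None
    )
    return cohort, fluids, annotation, markers


def run_pipeline(
    config: RunConfig,
    truth: sim.NetworkTruth | None = None,
    effects: sim.EffectTruth | None = None,
) -> RunSummary:
    """Execute the full workflow and write all artefacts to ``config.outdir``.

    ``truth`` and ``effects`` optionally plant a known network/effect
    structure into the simulation (ignored when loading from
    ``input_dir``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(seed=config.seed)

    # ---- stage: simulate or load ------------------------------------------------
    stage = "simulate/load"
    try:
        if config.input_dir is not None:
            cohort, fluids_raw, annotation, marker_frame = _load_study(config)
            hba1c = marker_frame["hba1c"] if marker_frame is not None else None
            ag_measure = glucose_measure = None
            if annotation is not None:
                names = annotation["name"]
                ag_hits = names.index[names == "1,5-AG"]
                glu_hits = names.index[names == "glucose"]
                ag_measure = ag_hits[0] if len(ag_hits) else None
                glucose_measure = glu_hits[0] if len(glu_hits) else None
        else:
            study = sim.simulate_study(
                config.simulate, seed=config.seed, truth=truth, effects=effects
            )
            cohort, fluids_raw = study.cohort, study.fluids
            annotation = study.annotation
            hba1c = study.latents.hba1c
            ag_measure = study.config.panel.ag_measure
            glucose_measure = study.config.panel.glucose_measure
            sim.write_study(study, outdir / "simulated")
        write_tsv(cohort, outdir / "phenotypes.tsv")
        summary.n_participants = len(cohort)
        summary.n_cases = int((cohort["diabetes"] == 1).sum())
        summary.n_controls = summary.n_participants - summary.n_cases
        log.info("%s: %d participants", stage, summary.n_participants)

        # ---- stage: preprocess --------------------------------------------------
        stage = "preprocess"
        fluids, reports = {}, []
        for fluid in FLUIDS:
            if fluid not in fluids_raw:
                continue
            prep = FluidPreprocessor(
                min_detections=config.min_detections,
                outlier_sd=config.outlier_sd,
                missing_rule=config.missing_rule,
            )
            fluids[fluid] = prep.fit_transform(fluids_raw[fluid])
            reports.append(prep.report_.per_measure.assign(fluid=fluid))
            write_tsv(fluids[fluid].data, outdir / f"fluid_{fluid}_preprocessed.tsv")
        report = pd.concat(reports)
        write_tsv(report, outdir / "preprocess_report.tsv", index_label="measure")
        summary.n_input_measures = int(report.shape[0])
        summary.measures_per_fluid = {
            f: int(fluids[f].n_measures) for f in fluids
        }
        summary.n_measures_tested = sum(summary.measures_per_fluid.values())

        # ---- stage: association scan -------------------------------------------
        stage = "scan"
        scan = AssociationScan(alpha=config.alpha, covariates=config.covariates).fit(
            fluids, cohort
        )
        results = scan.results_
        if annotation is not None:
            results = results.merge(
                annotation.reset_index()[["measure", "name", "super_pathway"]],
                on="measure", how="left",
            )
        results.to_csv(outdir / "scan.tsv", sep="\t", index=False, float_format="%.6g")
        summary.bonferroni_threshold = float(scan.bonferroni_)
        hits = scan.significant("bonferroni")
        summary.n_bonferroni = len(hits)
        summary.bonferroni_per_fluid = {
            f: int((hits["fluid"] == f).sum()) for f in fluids
        }
        summary.n_nominal = len(scan.significant("nominal"))
        log.info("%s: %d/%d Bonferroni hits", stage, summary.n_bonferroni, scan.m_)

        # ---- stage: glycaemic timescales ---------------------------------------
        stage = "timescales"
        ts = None
        if summary.n_bonferroni and "urine" in fluids_raw and glucose_measure:
            glucosuria = detect_glucosuria(fluids_raw["urine"], glucose_measure, cohort)
            ag_series = None
            if ag_measure is not None and "plasma" in fluids and ag_measure in fluids["plasma"].data:
                ag_series = fluids["plasma"].data[ag_measure]
            markers = {
                "acute": glucosuria,
                "short_term": ag_series,
                "long_term": hba1c,
            }
            if all(v is not None for v in markers.values()):
                ts = TimescaleScan(alpha=config.alpha, covariates=config.covariates).fit(
                    hits, fluids, cohort, markers,
                    marker_sources={"acute": glucose_measure, "short_term": ag_measure},
                )
                ts.results_.to_csv(
                    outdir / "timescales.tsv", sep="\t", index=False, float_format="%.6g"
                )
                pd.Series(ts.venn_counts_, name="count").rename_axis("region").to_csv(
                    outdir / "venn_counts.tsv", sep="\t"
                )
                summary.timescale_threshold = float(ts.threshold_)
                summary.n_timescale_associated = len(ts.significant())
                summary.timescale_per_marker = ts.marker_counts()
                summary.venn_counts = ts.venn_counts_

        # ---- stage: GGM ---------------------------------------------------------
        stage = "network"
        complete = pd.concat([fluids[f].data for f in fluids], axis=1)
        design = build_design(cohort, "diabetes", config.covariates).drop(columns="const")
        keep_cov = [c for c in design.columns]
        residuals = ggm.residualize(complete, design[keep_cov])
        k_adj = design.shape[1]
        estimator = ggm.ShrinkagePartialCorrelation(
            n_effective=config.n_effective, k_adjusted=k_adj, alpha=config.alpha
        ).fit(residuals)
        edges = estimator.edges(config.alpha)
        edges.to_csv(outdir / "edges.tsv", sep="\t", index=False, float_format="%.6g")
        summary.edge_threshold = float(edges.attrs["threshold"])
        summary.n_pairs = estimator.n_pairs_
        summary.n_edges = len(edges)
        summary.n_connected_nodes = int(
            pd.unique(pd.concat([edges["node_i"], edges["node_j"]])).shape[0]
        )
        summary.ggm_shrinkage = float(estimator.shrinkage_)
        log.info("%s: %d edges, lambda=%.3f", stage, summary.n_edges, estimator.shrinkage_)

        # ---- stage: subnetwork extraction --------------------------------------
        stage = "subnetworks"
        nominal = scan.significant("nominal")
        node_attrs = results.set_index("measure")[
            [c for c in ("fluid", "beta", "p", "tier", "name", "super_pathway")
             if c in results.columns]
        ].copy()
        node_attrs["direction"] = node_attrs["beta"].map(
            lambda b: "up" if b > 0 else ("down" if b < 0 else "")
        )
        if ts is not None:
            for name in MARKER_NAMES:
                node_attrs[f"{name}_significant"] = (
                    ts.results_.set_index("measure")[f"{name}_significant"]
                    .reindex(node_attrs.index)
                    .astype("boolean")
                    .fillna(False)
                    .astype(bool)
                )
        subnets = ggm.filter_and_extract(
            edges, nominal["measure"], node_attrs, min_size=config.min_subnetwork_size
        )
        sub_rows = []
        for s in subnets:
            for node in s.nodes:
                sub_rows.append({"subnetwork": s.component_id, "measure": node,
                                 "size": s.size})
        pd.DataFrame(sub_rows, columns=["subnetwork", "measure", "size"]).to_csv(
            outdir / "subnetworks.tsv", sep="\t", index=False
        )
        summary.n_subnetworks = len(subnets)
        summary.subnetwork_sizes = [s.size for s in subnets]
        summary.n_subnetwork_measures = sum(s.size for s in subnets)

        ggm.export_graphml(edges, outdir / "network.graphml", node_attrs)
        ggm.export_sif(edges, outdir / "network.sif")
    except Exception:
        log.exception("pipeline aborted in stage %r", stage)
        raise

    summary.thresholds = {
        "alpha": config.alpha,
        "min_detections": config.min_detections,
        "outlier_sd": config.outlier_sd,
        "missing_rule": config.missing_rule,
        "min_subnetwork_size": config.min_subnetwork_size,
    }
    summary.check_consistency()
    config.to_yaml(outdir / "run_config.yaml")
    summary.to_json(outdir / "summary.json")
    return summary
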