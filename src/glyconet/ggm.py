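"""Covariate-adjusted Gaussian graphical model over the metabolite panel.

The conditional-independence network is estimated in three steps:

1. every measure in the complete imputed table is replaced by its OLS
   residual against the covariate design (diabetes status, age, sex,
   ethnicity, BMI) — covariates never appear as network nodes;
2. the residual correlation matrix is shrunk toward the identity with a
   data-driven (Schäfer–Strimmer-style) intensity, which keeps the matrix
   invertible in the n ≪ p regime, and partial correlations are read off
   the standardised inverse, pcor(i, j) = −ω_ij / √(ω_ii ω_jj);
3. per-pair two-sided p-values come from the Fisher z-transform with
   variance 1/(n_eff − 3 − k_adj), where k_adj counts the regressed-out
   covariate columns — an approximation under shrinkage whose family-wise
   error behaviour is validated by simulation in the test suite.

Edges significant after Bonferroni correction over all p(p−1)/2 pairs form
the network; restricting nodes to the disease-associated set and taking
connected components yields the reported subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .association import bonferroni_threshold

__all__ = [
    "residualize",
    "shrinkage_intensity",
    "partial_correlations_from_correlation",
    "ShrinkagePartialCorrelation",
    "call_edges",
    "Subnetwork",
    "filter_and_extract",
    "export_graphml",
    "export_sif",
]


def residualize(data: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace each column of ``data`` by its OLS residual on ``covariates``.

    The covariate design must be full rank (an intercept column is added if
    absent); a rank-deficient design raises a ``ValueError`` naming the
    collinear columns. Residual columns are orthogonal to every covariate
    column by construction.
    """
    X = covariates.copy()
    if not (X.nunique() == 1).any():
        X.insert(0, "const", 1.0)
    Xv = X.to_numpy(float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        bad = []
        for col in X.columns:
            rest = X.drop(columns=col).to_numpy(float)
            if np.linalg.matrix_rank(rest) == np.linalg.matrix_rank(Xv):
                bad.append(col)
        raise ValueError(f"covariate design is rank deficient; collinear columns: {bad}")
    Y = data.to_numpy(float)
    coef, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
    resid = Y - Xv @ coef
    return pd.DataFrame(resid, index=data.index, columns=data.columns)


def shrinkage_intensity(X: np.ndarray) -> float:
    """Analytic shrinkage intensity toward the identity correlation target.

    Ratio of the summed estimated variances of the empirical correlations
    to their summed squares (off-diagonal), clipped to [0, 1]; data-driven
    and fully deterministic given the data.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n < 3:
        return 1.0
    Xs = (X - X.mean(0)) / X.std(0, ddof=1)
    r = (Xs.T @ Xs) / (n - 1)
    # var(r_ij) via the empirical variance of the products w_kij
    w_bar = r * (n - 1) / n
    w2 = (Xs**2).T @ (Xs**2)
    var_w = w2 / n - w_bar**2
    var_r = n / (n - 1) ** 3 * var_w * n
    iu = np.triu_indices(p, 1)
    denom = float((r[iu] ** 2).sum())
    if denom <= 0:
        return 1.0
    lam = float(var_r[iu].sum()) / denom
    return float(np.clip(lam, 0.0, 1.0))


def partial_correlations_from_correlation(R: np.ndarray) -> np.ndarray:
    """Partial correlations from a (possibly shrunk) correlation matrix."""
    omega = np.linalg.inv(R)
    d = np.sqrt(np.diag(omega))
    pcor = -omega / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return pcor


class ShrinkagePartialCorrelation(BaseEstimator):
    """Shrinkage estimator of the partial-correlation network.

    Parameters
    ----------
    shrinkage : float or None, default None
        Shrinkage intensity λ toward the identity correlation target;
        ``None`` selects the analytic data-driven value. λ = 0 requires a
        numerically invertible sample correlation (n > p in practice);
        λ = 1 forces every off-diagonal partial correlation to zero.
    n_effective : int or None
        Effective sample size for the Fisher-z test; defaults to the
        number of rows seen in :meth:`fit`.
    k_adjusted : int, default 0
        Number of covariate columns regressed out before estimation
        (degrees-of-freedom correction).
    alpha : float, default 0.05
        Family-wise level used by :meth:`edges`.

    Attributes
    ----------
    pcor_ : ndarray (p, p)
        Symmetric partial-correlation estimates, unit diagonal.
    shrinkage_ : float
        The λ actually used.
    pvalues_ : ndarray (p, p)
        Two-sided Fisher-z p-values (diagonal 1).
    feature_names_ : list of str
        Column names of the fitted table.
    """

    def __init__(
        self,
        shrinkage: float | None = None,
        n_effective: int | None = None,
        k_adjusted: int = 0,
        alpha: float = 0.05,
    ) -> None:
        self.shrinkage = shrinkage
        self.n_effective = n_effective
        self.k_adjusted = k_adjusted
        self.alpha = alpha

    def fit(self, X, y=None) -> "ShrinkagePartialCorrelation":
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = [str(c) for c in X.columns]
            Xv = X.to_numpy(float)
        else:
            Xv = np.asarray(X, float)
            self.feature_names_ = [f"V{i}" for i in range(Xv.shape[1])]
        n, p = Xv.shape
        if n < 3 or p < 2:
            raise ValueError("need at least 3 observations and 2 variables")
        sd = Xv.std(0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant columns cannot enter the network")
        R = np.corrcoef(Xv, rowvar=False)

        lam = self.shrinkage if self.shrinkage is not None else shrinkage_intensity(Xv)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"shrinkage must be in [0, 1], got {lam}")
        R_shrunk = (1.0 - lam) * R
        np.fill_diagonal(R_shrunk, 1.0)
        if lam == 0.0:
            if n <= p or np.linalg.cond(R_shrunk) > 1e12:
                raise np.linalg.LinAlgError(
                    "sample correlation matrix is singular; use shrinkage > 0"
                )
        self.pcor_ = partial_correlations_from_correlation(R_shrunk)
        self.pcor_ = (self.pcor_ + self.pcor_.T) / 2.0
        np.fill_diagonal(self.pcor_, 1.0)
        self.shrinkage_ = float(lam)
        self.n_ = n
        self.p_ = p
        self._compute_pvalues()
        return self

    def _compute_pvalues(self) -> None:
        n_eff = self.n_effective if self.n_effective is not None else self.n_
        df = n_eff - 3 - self.k_adjusted
        p = self.p_
        if df <= 0:
            import warnings

            warnings.warn("insufficient effective sample size; all p-values set to 1")
            self.pvalues_ = np.ones((p, p))
            return
        r = np.clip(self.pcor_.copy(), -1 + 1e-15, 1 - 1e-15)
        np.fill_diagonal(r, 0.0)
        z = np.arctanh(r) * np.sqrt(df)
        pv = 2.0 * stats.norm.sf(np.abs(z))
        np.fill_diagonal(pv, 1.0)
        self.pvalues_ = pv

    @property
    def n_pairs_(self) -> int:
        return self.p_ * (self.p_ - 1) // 2

    def edges(self, alpha: float | None = None) -> pd.DataFrame:
        """Significant edges after Bonferroni correction over all pairs.

        Returns a frame with columns node_i, node_j, pcor, p sorted by
        ascending p then node ids.
        """
        alpha = self.alpha if alpha is None else alpha
        threshold = bonferroni_threshold(alpha, self.n_pairs_) if alpha > 0 else 0.0
        iu = np.triu_indices(self.p_, 1)
        keep = self.pvalues_[iu] < threshold
        names = np.asarray(self.feature_names_)
        out = pd.DataFrame(
            {
                "node_i": names[iu[0][keep]],
                "node_j": names[iu[1][keep]],
                "pcor": self.pcor_[iu][keep],
                "p": self.pvalues_[iu][keep],
            }
        )
        out.attrs["threshold"] = threshold
        return out.sort_values(["p", "node_i", "node_j"]).reset_index(drop=True)


def call_edges(network: ShrinkagePartialCorrelation, alpha: float = 0.05) -> pd.DataFrame:
    """Functional wrapper over :meth:`ShrinkagePartialCorrelation.edges`."""
    return network.edges(alpha)


@dataclass
class Subnetwork:
    """A connected component of the disease-filtered network."""

    component_id: int
    nodes: list[str]
    edges: list[tuple[str, str]]
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def size(self) -> int:
        return len(self.nodes)


def filter_and_extract(
    edges: pd.DataFrame,
    nominal_nodes,
    node_attributes: pd.DataFrame | None = None,
    min_size: int = 3,
) -> list[Subnetwork]:
    """Disease-filtered connected subnetworks of the significant-edge graph.

    The graph induced on ``nominal_nodes`` (measures nominally associated
    with the phenotype) is split into connected components; components with
    at least ``min_size`` nodes are returned, ordered by descending size
    then lexically smallest node id. ``node_attributes`` (indexed by
    measure) is attached per component when given.
    """
    nominal = set(map(str, nominal_nodes))
    g = nx.Graph()
    g.add_nodes_from(nominal)
    for _, row in edges.iterrows():
        i, j = str(row["node_i"]), str(row["node_j"])
        if i in nominal and j in nominal:
            g.add_edge(i, j, pcor=float(row["pcor"]), p=float(row["p"]))

    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= min_size]
    comps.sort(key=lambda nodes: (-len(nodes), nodes[0]))
    out = []
    for k, nodes in enumerate(comps, start=1):
        sub = g.subgraph(nodes)
        ann = (
            node_attributes.reindex(nodes)
            if node_attributes is not None
            else pd.DataFrame(index=pd.Index(nodes, name="measure"))
        )
        out.append(
            Subnetwork(
                component_id=k,
                nodes=nodes,
                edges=sorted(tuple(sorted(e)) for e in sub.edges()),
                annotations=ann,
            )
        )
    return out


def _attribute_graph(edges: pd.DataFrame, node_attributes: pd.DataFrame | None) -> nx.Graph:
    g = nx.Graph()
    if node_attributes is not None:
        for node, row in node_attributes.iterrows():
            g.add_node(str(node), **{k: _graphml_safe(v) for k, v in row.items()})
    for _, row in edges.iterrows():
        g.add_edge(
            str(row["node_i"]), str(row["node_j"]),
            pcor=float(row["pcor"]), p=float(row["p"]),
        )
    return g


def _graphml_safe(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if pd.isna(value):
        return ""
    return value if isinstance(value, (bool, int, float, str)) else str(value)


def export_graphml(edges: pd.DataFrame, path, node_attributes: pd.DataFrame | None = None):
    """Write the network (with node annotations) as GraphML."""
    nx.write_graphml(_attribute_graph(edges, node_attributes), path)


def export_sif(edges: pd.DataFrame, path, relation: str = "pcor") -> None:
    """Write the edge list in simple interaction format (SIF)."""
    with open(path, "w") as fh:
        for _, row in edges.iterrows():
            fh.write(f"{row['node_i']}\t{relation}\t{row['node_j']}\n")
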