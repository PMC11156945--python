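"""Directional tau-spreading graphs and the conditional-independence backbone.

Two complementary graphs are built from two-visit regional tau panels:

* the *bipartite directional graph*: for every ordered region pair (i, j)
  the partial correlation of baseline tau at i with follow-up tau at j,
  conditioned on baseline tau at j (so the association reflects longitudinal
  accumulation at the target, not cross-sectional covariance) plus the
  configured covariates; and
* the *backbone*: the skeleton phase of the PC algorithm on baseline values,
  pruning a complete undirected graph by Fisher-z conditional-independence
  tests with growing conditioning sets, with arrows afterwards copied from
  the bipartite graph's significant directions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import fisher_z_pvalue, partial_corr, partial_corr_pvalue
from .exceptions import ParameterError, SchemaError
from .synthetic_data import RegionalTauPanel

logger = logging.getLogger(__name__)

DEFAULT_GRAPH_COVARIATES = ("age", "sex", "apoe4", "smoking", "interval")


@dataclass
class DirectedSpreadGraph:
    """Asymmetric region x region matrix of conditioned associations.

    Row = source region i (baseline), column = target region j (follow-up).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    alpha: float
    covariates: tuple
    degenerate: pd.DataFrame | None = None

    @property
    def regions(self) -> list:
        return list(self.r.columns)

    def adjacency(self) -> pd.DataFrame:
        """Binary edge matrix at the stored alpha."""
        return ((self.p < self.alpha) & self.p.notna()).astype(int)

    def has_edge(self, src: str, dst: str) -> bool:
        p = self.p.loc[src, dst]
        return bool(np.isfinite(p) and p < self.alpha)


def tau_connectivity(
    panel: RegionalTauPanel,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> DirectedSpreadGraph:
    """Bipartite baseline -> follow-up conditioned association graph.

    For each ordered pair (i != j): partial correlation of baseline_i with
    followup_j given {baseline_j} + covariates, with a t-based two-sided
    p-value. Pairs whose conditioned residuals are (numerically) constant —
    e.g. follow-up identical to baseline — are reported as NaN with the
    ``degenerate`` flag set rather than as spurious zeros.
    """
    regions = panel.regions
    if list(panel.followup.columns) != regions:
        raise SchemaError("baseline and follow-up panels list different regions")
    n = len(panel.baseline)
    cov = None
    cov_names: tuple = ()
    if covariates is not None and len(covariates.columns):
        cov = covariates.to_numpy(dtype=float)
        cov_names = tuple(covariates.columns)
        if len(cov) != n:
            raise SchemaError("covariate rows do not match panel subjects")
    n_cond = 1 + (0 if cov is None else cov.shape[1])
    if n < n_cond + 12:
        raise ParameterError("need at least ~10 subjects more than conditioning size")
    k = len(regions)
    r_mat = np.full((k, k), np.nan)
    p_mat = np.full((k, k), np.nan)
    degen = np.zeros((k, k), bool)
    base = panel.baseline.to_numpy(float)
    fol = panel.followup.to_numpy(float)
    for j in range(k):
        cond = base[:, [j]] if cov is None else np.column_stack([base[:, j], cov])
        # residual variance of followup_j given the conditioning set
        X = np.column_stack([np.ones(n), cond])
        beta, _, _, _ = np.linalg.lstsq(X, fol[:, j], rcond=None)
        resid = fol[:, j] - X @ beta
        scale = max(np.abs(fol[:, j]).max(), 1.0)
        j_degenerate = resid.std() < 1e-12 * scale
        for i in range(k):
            if i == j:
                continue
            if base[:, i].std() == 0 or j_degenerate:
                degen[i, j] = True
                logger.info("degenerate pair %s->%s; edge missing", regions[i], regions[j])
                continue
            r = partial_corr(base[:, i], fol[:, j], cond)
            r_mat[i, j] = r
            p_mat[i, j] = partial_corr_pvalue(r, n, n_cond)
    return DirectedSpreadGraph(
        r=pd.DataFrame(r_mat, index=regions, columns=regions),
        p=pd.DataFrame(p_mat, index=regions, columns=regions),
        alpha=alpha,
        covariates=cov_names,
        degenerate=pd.DataFrame(degen, index=regions, columns=regions),
    )


def node_degrees(g: DirectedSpreadGraph) -> pd.DataFrame:
    """Weighted out/in degree per region: sum of |r| over significant edges."""
    sig = (g.p < g.alpha) & g.p.notna()
    weighted = g.r.abs().where(sig, 0.0)
    return pd.DataFrame(
        {"out_degree": weighted.sum(axis=1), "in_degree": weighted.sum(axis=0)}
    )


@dataclass
class BackboneGraph:
    """Undirected PC skeleton with separating sets and optional arrows."""

    nodes: list
    edges: set  # frozenset pairs
    separating_sets: dict  # frozenset pair -> tuple of separating nodes
    oriented: dict = field(default_factory=dict)  # (src, dst) -> "->" / "<->"
    alpha: float = 0.05
    max_cond: int | None = None

    def has_edge(self, a, b) -> bool:
        return frozenset((a, b)) in self.edges

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for e in sorted(self.edges, key=sorted):
            a, b = sorted(e)
            direction = ""
            if (a, b) in self.oriented:
                direction = self.oriented[(a, b)]
            elif (b, a) in self.oriented:
                a, b = b, a
                direction = self.oriented[(a, b)]
            rows.append({"source": a, "target": b, "direction": direction or "--"})
        return pd.DataFrame(rows, columns=["source", "target", "direction"])


def pc_skeleton(
    data: pd.DataFrame,
    alpha: float = 0.05,
    max_cond: int | None = None,
) -> BackboneGraph:
    """Skeleton phase of the PC algorithm on subjects x nodes data.

    Starting from the complete undirected graph, for growing conditioning-set
    size l = 0, 1, ..., each remaining edge X-Y is tested against every
    size-l subset of the current neighbors of X (and of Y); independence is
    declared by the Fisher-z partial-correlation test at ``alpha``, the edge
    removed and the first separating set found recorded. Subsets are
    enumerated lexicographically over sorted neighbor names, so the output is
    deterministic.
    """
    nodes = list(data.columns)
    if len(nodes) < 2:
        raise ParameterError("need at least 2 nodes")
    n = len(data)
    arr = {c: data[c].to_numpy(float) for c in nodes}
    limit = n - 4  # Fisher-z needs n - l - 3 >= 1
    if max_cond is None:
        max_cond = len(nodes) - 2
    if max_cond > limit:
        raise ParameterError(
            f"n={n} too small for Fisher-z with conditioning sets of size "
            f"{max_cond}; the largest testable size is {max(limit, 0)}"
        )
    edges = {frozenset((a, b)) for a, b in itertools.combinations(nodes, 2)}
    sepsets: dict = {}
    for ell in range(0, max_cond + 1):
        any_testable = False
        for e in sorted(edges, key=sorted):
            x, y = sorted(e)
            removed = False
            for first, other in ((x, y), (y, x)):
                neighbors = sorted(
                    nb
                    for nb in nodes
                    if nb not in (x, y) and frozenset((first, nb)) in edges
                )
                if len(neighbors) < ell:
                    continue
                any_testable = True
                for S in itertools.combinations(neighbors, ell):
                    Z = np.column_stack([arr[s] for s in S]) if S else None
                    r = partial_corr(arr[x], arr[y], Z)
                    p = fisher_z_pvalue(r, n, ell)
                    if p > alpha:
                        edges.discard(e)
                        sepsets[e] = tuple(S)
                        removed = True
                        break
                if removed:
                    break
        if not any_testable and ell > 0:
            break
    return BackboneGraph(
        nodes=nodes, edges=edges, separating_sets=sepsets, alpha=alpha, max_cond=max_cond
    )


def orient_backbone(skeleton: BackboneGraph, g: DirectedSpreadGraph) -> BackboneGraph:
    """Copy arrows onto skeleton edges from the bipartite graph's directions.

    For each skeleton edge {i, j}: arrow i->j if the bipartite graph has
    i->j significant and not j->i; "<->" if both directions are significant;
    undirected if neither.
    """
    oriented = {}
    for e in skeleton.edges:
        a, b = sorted(e)
        fwd = a in g.regions and b in g.regions and g.has_edge(a, b)
        rev = a in g.regions and b in g.regions and g.has_edge(b, a)
        if fwd and rev:
            oriented[(a, b)] = "<->"
        elif fwd:
            oriented[(a, b)] = "->"
        elif rev:
            oriented[(b, a)] = "->"
    return BackboneGraph(
        nodes=skeleton.nodes,
        edges=set(skeleton.edges),
        separating_sets=dict(skeleton.separating_sets),
        oriented=oriented,
        alpha=skeleton.alpha,
        max_cond=skeleton.max_cond,
    )


def to_networkx(g: DirectedSpreadGraph):
    """Export the significant directed edges as a networkx DiGraph."""
    import networkx as nx

    out = nx.DiGraph()
    out.add_nodes_from(g.regions)
    adj = g.adjacency()
    for src in g.regions:
        for dst in g.regions:
            if src != dst and adj.loc[src, dst]:
                out.add_edge(src, dst, r=float(g.r.loc[src, dst]), p=float(g.p.loc[src, dst]))
    return out
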