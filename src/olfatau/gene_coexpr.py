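"""Region-level transcriptome processing and co-expression clustering.

Samples are mapped to atlas regions (per-donor region means, cross-donor
median, per-gene z-score across regions), pairwise Pearson co-expression is
clustered agglomeratively with the cluster count chosen by the silhouette
index, cluster mean-expression maps are re-z-scored per hemisphere, and a
gene-trait catalog extract is reduced to a bipartite gene-domain network
weighted by the best (minimum) GWAS p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import silhouette_score

from .exceptions import ParameterError, SchemaError
from .imaging_io import RegionAtlas
from .synthetic_data import ExpressionMatrix

logger = logging.getLogger(__name__)

#: GWAS-catalog inclusion bound: reported associations have p < 1e-5.
CATALOG_P_BOUND = 1e-5

DOMAINS = ("tau", "amyloid", "alzheimer", "aging", "cognition", "brain")


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene row across regions (ddof=0)."""
    arr = values.to_numpy(float)
    mean = np.nanmean(arr, axis=1, keepdims=True)
    sd = np.nanstd(arr, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame((arr - mean) / sd, index=values.index, columns=values.columns)


def map_samples_to_regions(
    samples: pd.DataFrame,
    gene_columns,
    atlas: RegionAtlas | None = None,
    distance_bound_mm: float = 4.0,
) -> ExpressionMatrix:
    """Donor samples -> per-region donor means -> cross-donor median -> z-score.

    ``samples`` must carry a ``donor`` column and either a ``region`` column
    (pre-assigned, the default path) or ``x``/``y``/``z`` world coordinates to
    be assigned to the nearest atlas label within ``distance_bound_mm``.
    Regions with no samples in any donor become missing columns (logged).
    """
    if "donor" not in samples.columns:
        raise SchemaError("samples require a 'donor' column")
    samples = samples.copy()
    if "region" not in samples.columns:
        if atlas is None:
            raise SchemaError("coordinate-based assignment requires an atlas")
        coords = samples[["x", "y", "z"]].to_numpy(float)
        labeled = np.argwhere(atlas.labels > 0)
        world = labeled @ atlas.affine[:3, :3].T + atlas.affine[:3, 3]
        from scipy.spatial import cKDTree

        dist, nearest = cKDTree(world).query(coords)
        labels = atlas.labels[tuple(labeled[nearest].T)]
        region = np.array([atlas.names[l] for l in labels], dtype=object)
        region[dist > distance_bound_mm] = None
        samples["region"] = region
        dropped = samples["region"].isna().sum()
        if dropped:
            logger.info("%d samples beyond %.1f mm of any region dropped", dropped, distance_bound_mm)
        samples = samples.dropna(subset=["region"])
    per_donor = (
        samples.groupby(["donor", "region"], sort=True)[list(gene_columns)].mean()
    )
    median = per_donor.groupby(level="region", sort=True).median()
    values = zscore_rows(median.T)  # genes x regions
    if atlas is not None:
        missing = [n for n in atlas.names.values() if n not in values.columns]
        if missing:
            logger.info("regions with no samples in any donor: %s", missing)
    hemis = ["L" if str(r).lower().startswith(("lh", "l_", "left")) else "R" for r in values.columns]
    meta = pd.DataFrame({"region": list(values.columns), "hemisphere": hemis})
    return ExpressionMatrix(values=values, region_meta=meta)


def coexpression(expr: ExpressionMatrix) -> pd.DataFrame:
    """Gene x gene Pearson correlation over regions (pairwise deletion)."""
    return expr.values.T.corr(method="pearson")


@dataclass
class CoexprClusters:
    """Agglomerative co-expression clusters with silhouette-selected k."""

    labels: pd.Series  # gene -> cluster id (0-based)
    k: int
    silhouette_by_k: dict
    linkage: str

    def genes_in(self, cluster: int) -> list:
        return list(self.labels.index[self.labels == cluster])


def cluster_genes(
    coexpr: pd.DataFrame,
    k_range=range(2, 9),
    linkage: str = "average",
) -> CoexprClusters:
    """Cluster genes on distance 1 - r; pick k maximizing mean silhouette.

    Ties in silhouette resolve to the smallest k.
    """
    n = len(coexpr)
    k_range = list(k_range)
    if not k_range or min(k_range) < 2 or max(k_range) > n - 1:
        raise ParameterError(f"k_range must lie within [2, {n - 1}]")
    dist = 1.0 - coexpr.to_numpy(float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    scores, labelings = {}, {}
    for k in k_range:
        model = AgglomerativeClustering(n_clusters=k, metric="precomputed", linkage=linkage)
        lab = model.fit_predict(dist)
        scores[k] = float(silhouette_score(dist, lab, metric="precomputed"))
        labelings[k] = lab
    best = max(sorted(scores), key=lambda k: scores[k])
    return CoexprClusters(
        labels=pd.Series(labelings[best], index=coexpr.index, name="cluster"),
        k=best,
        silhouette_by_k=scores,
        linkage=linkage,
    )


def cluster_maps(expr: ExpressionMatrix, clusters: CoexprClusters) -> pd.DataFrame:
    """Per-cluster mean region maps, z-scored within each hemisphere.

    Returns clusters x regions; each row has mean 0 / sd 1 separately over
    the left- and right-hemisphere region subsets.
    """
    hemi = expr.region_meta.set_index("region")["hemisphere"]
    rows = {}
    for c in sorted(clusters.labels.unique()):
        mean_map = expr.values.loc[clusters.genes_in(c)].mean(axis=0)
        out = mean_map.copy()
        for h in ("L", "R"):
            sel = [r for r in mean_map.index if hemi.get(r) == h]
            if not sel:
                continue
            v = mean_map[sel]
            sd = v.std(ddof=0)
            out[sel] = (v - v.mean()) / (sd if sd > 0 else 1.0)
        rows[f"cluster_{c}"] = out
    return pd.DataFrame(rows).T


@dataclass
class GeneTraitNetwork:
    """Bipartite gene-trait and reduced gene-domain networks."""

    gene_trait: pd.DataFrame  # columns gene, trait, domain, weight (best p)
    gene_domain: pd.DataFrame  # columns gene, domain, weight (min over traits)
    n_rejected: int = 0
    domain_matrix: pd.DataFrame = field(default_factory=pd.DataFrame)


def gene_trait_network(gene_trait_table: pd.DataFrame, domain_map: dict) -> GeneTraitNetwork:
    """Reduce a (gene, trait, p) catalog extract to best-p bipartite networks.

    Rows with traits outside ``domain_map`` are ignored; rows violating the
    catalog inclusion bound (p >= 1e-5) are rejected and counted. Edge weight
    is the minimum p over supporting associations, and the domain network
    takes the minimum over member traits.
    """
    required = {"gene", "trait", "p"}
    if not required <= set(gene_trait_table.columns):
        raise SchemaError(f"gene-trait table requires columns {sorted(required)}")
    t = gene_trait_table.copy()
    bad = t["p"] >= CATALOG_P_BOUND
    n_rejected = int(bad.sum())
    if n_rejected:
        logger.info("rejected %d associations with p >= %.0e", n_rejected, CATALOG_P_BOUND)
    t = t[~bad]
    t["domain"] = t["trait"].map(domain_map)
    t = t.dropna(subset=["domain"])
    if t.empty:
        empty = pd.DataFrame(columns=["gene", "trait", "domain", "weight"])
        return GeneTraitNetwork(
            gene_trait=empty,
            gene_domain=pd.DataFrame(columns=["gene", "domain", "weight"]),
            n_rejected=n_rejected,
        )
    gt = (
        t.groupby(["gene", "trait", "domain"], sort=True)["p"].min().rename("weight").reset_index()
    )
    gd = gt.groupby(["gene", "domain"], sort=True)["weight"].min().reset_index()
    matrix = gd.pivot(index="gene", columns="domain", values="weight")
    return GeneTraitNetwork(
        gene_trait=gt[["gene", "trait", "domain", "weight"]],
        gene_domain=gd,
        n_rejected=n_rejected,
        domain_matrix=matrix,
    )
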