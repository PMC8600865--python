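"""Post-discovery analyses: correlation structure of RS genes, hierarchical
clustering of patients on a gene panel with per-cluster survival comparison,
and the extreme-survivor expression contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .config import RunConfig
from .engine import KMCurve, km_estimate, logrank_test, pearson_with_category, wilcoxon_ranksum
from .prep import CohortDataset

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    """Agglomerative clustering of patients on a gene panel.

    Defaults follow the heatmap-tool conventions: per-gene z-scoring,
    Euclidean distance, complete linkage, tree cut at k clusters.
    """

    labels: pd.Series  # per-sample cluster id in 1..k
    k: int
    linkage_method: str
    metric: str
    gene_panel: list[str]
    sizes: dict[int, int] = field(default_factory=dict)
    degenerate: bool = False


@dataclass
class ClusterSurvival:
    cluster: int
    evaluable: bool
    statistic: float = float("nan")
    p: float = float("nan")
    curves: dict[object, KMCurve] | None = None
    reason: str = ""


def rs_correlation(
    cohort: CohortDataset,
    genes: list[str],
    thresholds: tuple[float, float] = (0.3, 0.8),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation across samples with verbal categories.

    Returns (r matrix, category matrix); symmetric with unit diagonal.
    """
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a correlation structure")
    missing = [g for g in genes if g not in cohort.expression.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing}")
    r = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    cat = pd.DataFrame("strong", index=genes, columns=genes, dtype=object)
    for i, g1 in enumerate(genes):
        x = cohort.expression.loc[g1].to_numpy()
        for g2 in genes[i + 1 :]:
            y = cohort.expression.loc[g2].to_numpy()
            try:
                rv, category = pearson_with_category(x, y, thresholds)
            except ValueError as exc:
                raise ValueError(f"degenerate gene in pair ({g1}, {g2}): {exc}") from exc
            r.loc[g1, g2] = r.loc[g2, g1] = rv
            cat.loc[g1, g2] = cat.loc[g2, g1] = category
    return r, cat


def cluster_patients(
    cohort: CohortDataset,
    gene_panel: list[str],
    k: int = 2,
    exclusions: tuple[str, ...] = (),
    linkage_method: str = "complete",
    metric: str = "euclidean",
) -> ClusterResult:
    """Cluster patients on per-gene standardized expression.

    Rows are patients, columns the panel genes minus exclusions; each gene is
    z-scored across patients, then agglomerative clustering (Euclidean,
    complete linkage by default) is cut into k clusters.  Order of genes and
    patients does not affect the partition (up to label permutation).
    """
    panel = [g for g in gene_panel if g not in set(exclusions)]
    if len(panel) < 2:
        raise ValueError("gene panel minus exclusions must keep >= 2 genes")
    if cohort.n < k:
        raise ValueError(f"cannot form {k} clusters from {cohort.n} patients")
    X = cohort.expression.loc[panel].to_numpy().T  # patients x genes
    sd = X.std(axis=0)
    degenerate = bool(np.all(sd == 0))
    if degenerate:
        logger.warning("all genes constant across patients: single effective cluster")
        labels = pd.Series(1, index=cohort.clinical.index)
        return ClusterResult(labels, k, linkage_method, metric, panel,
                             {1: cohort.n}, True)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd_safe
    # stable patient order for reproducibility regardless of input order
    order = np.argsort(cohort.clinical.index.to_numpy())
    tree = linkage(Z[order], method=linkage_method, metric=metric)
    flat = fcluster(tree, t=k, criterion="maxclust")
    labels = pd.Series(0, index=cohort.clinical.index.to_numpy()[order], dtype=int)
    labels[:] = flat
    labels = labels.reindex(cohort.clinical.index)
    sizes = labels.value_counts().to_dict()
    return ClusterResult(labels, k, linkage_method, metric, panel, sizes, False)


def compare_cluster_survival(
    cohort: CohortDataset, clusters: ClusterResult, config: RunConfig
) -> dict:
    """Within each cluster, K-M curves and log-rank for RT vs NRT.

    A cluster is reported as the radio-sensitive cluster when the
    radiotherapy benefit is significant in exactly one cluster.
    """
    sch = cohort.schema
    clin = cohort.clinical
    results: list[ClusterSurvival] = []
    for cl in sorted(clusters.labels.unique()):
        members = clin[clusters.labels == cl]
        cells = members.groupby(sch.rt_col).size()
        if len(cells) < 2 or (cells < 1).any() or members[sch.event_col].sum() < 1:
            results.append(
                ClusterSurvival(int(cl), False, reason="empty RT cell or no events")
            )
            continue
        stat, p = logrank_test(
            members[sch.time_col], members[sch.event_col], members[sch.rt_col]
        )
        curves = km_estimate(
            members[sch.time_col].to_numpy(),
            members[sch.event_col].to_numpy(),
            members[sch.rt_col].to_numpy(),
        )
        results.append(ClusterSurvival(int(cl), True, stat, p, curves))
    significant = [r.cluster for r in results if r.evaluable and r.p < config.alpha]
    rs_cluster = significant[0] if len(significant) == 1 else None
    return {"per_cluster": results, "rs_cluster": rs_cluster}


def extreme_survivor_contrast(
    cohort: CohortDataset,
    genes: list[str],
    rt_status: int,
    long_cut: float,
    short_cut: float,
) -> pd.DataFrame:
    """Compare expression between extreme survivors and early deaths.

    The long-survivor ("alive") group is everyone whose follow-up exceeds
    long_cut — they demonstrably survived past the cut, whatever happened
    later; the "dead" group died before short_cut.  Both restricted to the
    given radiotherapy status.  Per gene: two-sided Wilcoxon rank-sum on
    expression, with group sizes and medians.
    """
    if long_cut < short_cut:
        raise ValueError(
            f"long_cut ({long_cut}) must be >= short_cut ({short_cut})"
        )
    sch = cohort.schema
    clin = cohort.clinical
    stratum = clin[clin[sch.rt_col] == rt_status]
    alive = stratum[stratum[sch.time_col] > long_cut]
    dead = stratum[(stratum[sch.event_col] == 1) & (stratum[sch.time_col] < short_cut)]
    if len(alive) == 0:
        raise ValueError(f"no patients with follow-up beyond long_cut={long_cut}")
    if len(dead) == 0:
        raise ValueError(f"no deaths before short_cut={short_cut}")
    rows = []
    for gene in genes:
        if gene not in cohort.expression.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        xa = cohort.expression.loc[gene, alive.index].to_numpy(dtype=float)
        xd = cohort.expression.loc[gene, dead.index].to_numpy(dtype=float)
        stat, p = wilcoxon_ranksum(xa, xd)
        rows.append(
            {
                "gene": gene,
                "n_alive": len(xa),
                "n_dead": len(xd),
                "median_alive": float(np.median(xa)),
                "median_dead": float(np.median(xd)),
                "statistic": stat,
                "p": p,
            }
        )
    return pd.DataFrame(rows).set_index("gene")
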