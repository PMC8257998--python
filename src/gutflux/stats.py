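"""Clustering, association, correlation and differential-production statistics.

This layer consumes capability (NMPC) matrices and abundance tables and
produces the study-level statistics: best-of-replicates k-means++ clustering
(squared Euclidean), silhouette-based selection of the cluster number (L1
distance), PCA projections for visualization, Fisher's exact test for
cluster-phenotype association, two-sided Wilcoxon rank-sum tests with
Benjamini-Hochberg FDR for the differential-production screen, the
proportionality coefficient for compositional correlation, and the
multi-diet concordance comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

DEFAULT_FDR_ALPHA = 0.05
DEFAULT_PRODUCTION_FLOOR = 10.0  # mmol/day, mean in at least one cluster
DEFAULT_RELATIVE_DIFFERENCE = 0.10
DEFAULT_KMEANS_REPLICATES = 1000
DEFAULT_SILHOUETTE_REPLICATES = 100


@dataclass
class ClusterResult:
    """Best-of-replicates k-means partition with phenotype bookkeeping."""

    assignments: pd.Series  # sample -> cluster id (0 = largest cluster)
    k: int
    centroids: np.ndarray
    inertia: float  # total within-cluster sum of squared distances
    phenotype_counts: pd.DataFrame | None = None

    def cluster_samples(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])


@dataclass
class AssociationResult:
    """2x2 contingency table with Fisher's exact test."""

    table: np.ndarray
    odds_ratio: float
    p_value: float
    zero_margin: bool = False


def kmeans_cluster(
    X: pd.DataFrame,
    k: int,
    replicates: int = DEFAULT_KMEANS_REPLICATES,
    seed: int = 0,
    phenotype: pd.Series | None = None,
) -> ClusterResult:
    """k-means++ with squared Euclidean distance, best of ``replicates`` runs.

    Cluster ids are relabeled by descending cluster size (ties broken by the
    original fit label) so results are stable across the arbitrary labeling
    of individual k-means runs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(X):
        raise ValueError(f"k={k} exceeds number of samples {len(X)}")
    if X.isna().any().any():
        raise ValueError("capability matrix contains missing rows")
    km = KMeans(
        n_clusters=k, init="k-means++", n_init=replicates, random_state=seed,
        algorithm="lloyd",
    ).fit(X.values)
    counts = pd.Series(km.labels_).value_counts()
    order = sorted(range(k), key=lambda l: (-int(counts.get(l, 0)), l))
    relabel = {old: new for new, old in enumerate(order)}
    labels = pd.Series(
        [relabel[l] for l in km.labels_], index=X.index, name="cluster"
    )
    centroids = km.cluster_centers_[order]
    counts = None
    if phenotype is not None:
        counts = (
            pd.crosstab(labels, phenotype.loc[X.index])
            .reindex(range(k), fill_value=0)
        )
    return ClusterResult(
        assignments=labels, k=k, centroids=centroids,
        inertia=float(km.inertia_), phenotype_counts=counts,
    )


def select_k(
    X: pd.DataFrame,
    k_range: tuple[int, int] = (2, 6),
    replicates: int = DEFAULT_SILHOUETTE_REPLICATES,
    seed: int = 0,
) -> tuple[int, pd.Series]:
    """Cluster number maximizing mean silhouette under L1 distance.

    Returns the selected k (ties -> smallest) and the silhouette score per
    candidate k.
    """
    lo, hi = k_range
    if lo < 2 or hi > len(X) - 1:
        raise ValueError(f"k_range {k_range} must lie within [2, n-1]")
    if (X.values == X.values[0]).all():
        raise ValueError("degenerate matrix: all rows identical")
    scores = {}
    for k in range(lo, hi + 1):
        result = kmeans_cluster(X, k, replicates=replicates, seed=seed)
        scores[k] = float(
            silhouette_score(X.values, result.assignments.values, metric="manhattan")
        )
    series = pd.Series(scores, name="mean_silhouette")
    best = min(k for k, s in scores.items() if s == series.max())
    return best, series


def pca_project(
    X: pd.DataFrame, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA scores and explained-variance fractions."""
    if np.allclose(X.values, X.values.mean(axis=0), atol=1e-12):
        raise ValueError("constant matrix has no principal components")
    rank = np.linalg.matrix_rank(X.values - X.values.mean(axis=0))
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(X.values)
    frame = pd.DataFrame(
        scores, index=X.index,
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    return frame, pca.explained_variance_ratio_


def fisher_exact_2x2(table) -> AssociationResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p is the hypergeometric sum over tables (margins fixed)
    whose point probability does not exceed the observed table's.  A zero
    row or column margin carries no information; p = 1 by convention,
    flagged.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise ValueError("table entries must be non-negative integers")
    arr = arr.astype(int)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        a, b, c, d = arr.ravel()
        odds = np.nan if (b * c == 0) else (a * d) / (b * c)
        return AssociationResult(arr, float(odds), 1.0, zero_margin=True)
    odds, p = sps.fisher_exact(arr, alternative="two-sided")
    return AssociationResult(arr, float(odds), float(p))


def ranksum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration when the smaller sample has <= 10 observations
    and there are no ties across the pooled data; otherwise the normal
    approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 10 and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True
        )
    return float(res.pvalue)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def proportionality(x, y, pseudocount: float | None = None) -> float:
    """Proportionality coefficient rho_p for compositional association.

    rho_p = 2 cov(log x, log y) / (var(log x) + var(log y)); equals 1 iff
    log y = log x + c and -1 for log-antiproportional vectors.  Zeros are
    replaced by ``pseudocount`` (default: half the smallest nonzero value
    across both vectors).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must have equal length >= 3")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("abundances must be non-negative")
    pooled = np.concatenate([x, y])
    nonzero = pooled[pooled > 0]
    if nonzero.size == 0:
        raise ValueError("all values are zero")
    eps = pseudocount if pseudocount is not None else nonzero.min() / 2.0
    lx = np.log(np.where(x > 0, x, eps))
    ly = np.log(np.where(y > 0, y, eps))
    vx, vy = lx.var(ddof=1), ly.var(ddof=1)
    if vx + vy == 0:
        raise ValueError("zero variance after log transform; rho_p undefined")
    cov = np.cov(lx, ly, ddof=1)[0, 1]
    return float(2.0 * cov / (vx + vy))


def differential_metabolites(
    nmpc: pd.DataFrame,
    groups: pd.Series,
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
    floor: float = DEFAULT_PRODUCTION_FLOOR,
    rel_diff: float = DEFAULT_RELATIVE_DIFFERENCE,
) -> pd.DataFrame:
    """Differential-production screen between two sample groups.

    A metabolite is flagged differential iff its BH-adjusted rank-sum q is
    below ``fdr_alpha`` AND its mean capability exceeds ``floor`` mmol/day
    in at least one group AND the relative mean difference (|m1 - m2| /
    max(m1, m2)) is at least ``rel_diff``.  Metabolites with all-zero
    capability in both groups are reported untested.
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1 = nmpc.loc[groups.index[groups == labels[0]]]
    g2 = nmpc.loc[groups.index[groups == labels[1]]]

    rows = []
    for met in nmpc.columns:
        x, y = g1[met].values, g2[met].values
        m1, m2 = float(np.mean(x)), float(np.mean(y))
        tested = not (np.all(x == 0) and np.all(y == 0))
        p = ranksum(x, y) if tested else np.nan
        top = max(m1, m2)
        rel = abs(m1 - m2) / top if top > 0 else 0.0
        rows.append({
            "metabolite": met,
            f"mean_{labels[0]}": m1,
            f"mean_{labels[1]}": m2,
            "relative_difference": rel,
            "tested": tested,
            "p": p,
        })
    out = pd.DataFrame(rows).set_index("metabolite")
    out["q"] = np.nan
    tested_mask = out["tested"].values
    if tested_mask.any():
        out.loc[tested_mask, "q"] = bh_fdr(out.loc[tested_mask, "p"].values)
    out["passes_magnitude"] = (
        (out[[f"mean_{labels[0]}", f"mean_{labels[1]}"]].max(axis=1) > floor)
        & (out["relative_difference"] >= rel_diff)
    )
    out["differential"] = (
        tested_mask & (out["q"] < fdr_alpha) & out["passes_magnitude"]
    )
    return out


def select_high_low_clusters(
    result: ClusterResult, min_size: int = 10
) -> tuple[int, int]:
    """Clusters with the highest and lowest gouty fraction among those of
    at least ``min_size`` samples (the small outlier cluster is excluded
    from the differential screen)."""
    if result.phenotype_counts is None:
        raise ValueError("cluster result carries no phenotype counts")
    counts = result.phenotype_counts
    totals = counts.sum(axis=1)
    eligible = totals[totals >= min_size].index
    if len(eligible) < 2:
        raise ValueError(f"fewer than two clusters of size >= {min_size}")
    gouty = counts.get("gouty", pd.Series(0, index=counts.index))
    frac = (gouty / totals).loc[eligible]
    return int(frac.idxmax()), int(frac.idxmin())


def cluster_phenotype_association(
    result: ClusterResult, cluster_a: int, cluster_b: int
) -> AssociationResult:
    """Fisher's exact test of gouty/healthy counts between two clusters."""
    counts = result.phenotype_counts
    if counts is None:
        raise ValueError("cluster result carries no phenotype counts")
    table = [
        [int(counts.loc[cluster_a].get("gouty", 0)),
         int(counts.loc[cluster_a].get("healthy", 0))],
        [int(counts.loc[cluster_b].get("gouty", 0)),
         int(counts.loc[cluster_b].get("healthy", 0))],
    ]
    return fisher_exact_2x2(table)


def co_clustering_agreement(a: pd.Series, b: pd.Series) -> float:
    """Fraction of sample pairs on which two partitions agree (co-clustered
    in both or separated in both) -- the Rand index between labelings."""
    if not a.index.sort_values().equals(b.index.sort_values()):
        raise ValueError("partitions cover different sample sets")
    idx = a.index
    la, lb = a.values, b.loc[idx].values
    n = len(idx)
    same_a = la[:, None] == la[None, :]
    same_b = lb[:, None] == lb[None, :]
    iu = np.triu_indices(n, k=1)
    return float((same_a[iu] == same_b[iu]).mean())


@dataclass
class DietComparison:
    agreement: dict[tuple[str, str], float]
    matched_clusters: dict[tuple[str, str], dict[int, int]]
    screens: dict[tuple[str, str, int], pd.DataFrame] = field(default_factory=dict)


def compare_diets(
    nmpc_by_diet: dict[str, pd.DataFrame],
    clusterings: dict[str, ClusterResult],
    fdr_alpha: float = DEFAULT_FDR_ALPHA,
) -> DietComparison:
    """Cross-diet concordance of cluster memberships plus a per-metabolite
    rank-sum screen between matched clusters of each diet pair.

    Clusters are matched across diets by maximal sample overlap (Hungarian
    assignment); for each matched pair the screen tests, per metabolite,
    whether the two diets yield different capability distributions within
    that cluster (BH-adjusted).
    """
    diets = list(nmpc_by_diet)
    samples = set(nmpc_by_diet[diets[0]].index)
    for d in diets[1:]:
        if set(nmpc_by_diet[d].index) != samples:
            raise ValueError("diets cover different retained sample sets")

    agreement: dict[tuple[str, str], float] = {}
    matched: dict[tuple[str, str], dict[int, int]] = {}
    screens: dict[tuple[str, str, int], pd.DataFrame] = {}
    for i, d1 in enumerate(diets):
        for d2 in diets[i + 1:]:
            c1, c2 = clusterings[d1], clusterings[d2]
            agreement[(d1, d2)] = co_clustering_agreement(
                c1.assignments, c2.assignments
            )
            overlap = pd.crosstab(
                c1.assignments, c2.assignments.loc[c1.assignments.index]
            ).reindex(index=range(c1.k), columns=range(c2.k), fill_value=0)
            rows, cols = linear_sum_assignment(-overlap.values)
            pairing = {int(r): int(c) for r, c in zip(rows, cols)}
            matched[(d1, d2)] = pairing
            for cl1, cl2 in pairing.items():
                s1 = c1.cluster_samples(cl1)
                s2 = c2.cluster_samples(cl2)
                mets = nmpc_by_diet[d1].columns
                recs = []
                for met in mets:
                    x = nmpc_by_diet[d1].loc[s1, met].values
                    y = nmpc_by_diet[d2].loc[s2, met].values
                    if np.all(x == 0) and np.all(y == 0):
                        continue
                    recs.append((met, float(np.mean(x)), float(np.mean(y)),
                                 ranksum(x, y)))
                screen = pd.DataFrame(
                    recs, columns=["metabolite", f"mean_{d1}", f"mean_{d2}", "p"]
                ).set_index("metabolite")
                if len(screen):
                    screen["q"] = bh_fdr(screen["p"].values)
                    screen["differential"] = screen["q"] < fdr_alpha
                screens[(d1, d2, cl1)] = screen
    return DietComparison(agreement=agreement, matched_clusters=matched, screens=screens)
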