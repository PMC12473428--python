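"""Divergence grouping: Gower dissimilarity, Ward linkage, Ward-MLM.

The grouping chain mirrors the Ward-MLM strategy used in clonal
diversity studies:

1. genotype profiles (means over replicates) -> Gower dissimilarity,
   which for quantitative traits is the range-normalized absolute
   difference averaged over traits, bounded in [0, 1];
2. Ward hierarchical clustering of the dissimilarity matrix (Ward.D2
   convention, i.e. scipy's ``ward`` update applied to the
   dissimilarities);
3. for each candidate group count k, the Ward cut initializes a
   classification-EM fit of a k-component Gaussian model with
   group-specific means and a single pooled covariance — the
   continuous-variable reduction of the modified location model
   (with zero categorical variables the location model collapses to
   exactly this common-covariance mixture);
4. the chosen k maximizes the increment of the classification
   log-likelihood over k; pseudo-F (Calinski-Harabasz) and pseudo-T2
   (Duda-Hart) are reported alongside as concordance diagnostics;
5. inter-group divergence is the squared Mahalanobis distance between
   group mean vectors under the pooled within-group covariance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Gower dissimilarity
# --------------------------------------------------------------------------


@dataclass
class DissimilarityMatrix:
    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("dissimilarity matrix must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.abs(np.diag(v)).max() > 1e-12:
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-9:
            raise ValueError("Gower dissimilarities must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        n = len(self.labels)
        return self.values[np.triu_indices(n, 1)]


def gower_matrix(profiles: pd.DataFrame, ranges: pd.Series | None = None) -> DissimilarityMatrix:
    """Gower dissimilarity between genotype trait profiles.

    All traits here are quantitative, so d(i, j) is the mean over
    traits of |x_it - x_jt| / range_t. Traits with zero observed range
    carry no information and are dropped with a warning.
    """
    if profiles.shape[0] < 2:
        raise ValueError("need at least 2 genotypes")
    x = profiles.to_numpy(float)
    if not np.isfinite(x).all():
        raise ValueError("profiles contain non-finite values")
    if ranges is None:
        rng = x.max(axis=0) - x.min(axis=0)
    else:
        rng = np.asarray(ranges.reindex(profiles.columns), float)
    keep = rng > 0
    if not keep.all():
        dropped = list(profiles.columns[~keep])
        warnings.warn(f"dropping zero-range traits from Gower: {dropped}", stacklevel=2)
    if not keep.any():
        raise ValueError("no traits with positive range")
    xn = x[:, keep] / rng[keep]
    diff = np.abs(xn[:, None, :] - xn[None, :, :])
    d = diff.mean(axis=2)
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d, [str(i) for i in profiles.index])


def range_normalize(profiles: pd.DataFrame) -> pd.DataFrame:
    """Scale each trait by its observed range (zero-range traits dropped)."""
    rng = profiles.max() - profiles.min()
    keep = rng[rng > 0].index
    return profiles[keep] / rng[keep]


# --------------------------------------------------------------------------
# Ward linkage
# --------------------------------------------------------------------------


@dataclass
class WardTree:
    """Agglomerative merge tree (scipy linkage encoding)."""

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        z = np.asarray(self.linkage, float)
        n = len(self.labels)
        if z.shape != (n - 1, 4):
            raise ValueError("linkage must have n-1 rows")
        heights = z[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")
        self.linkage = z

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> pd.Series:
        """Partition into k groups, labelled 1..k in leaf order."""
        n = len(self.labels)
        if not 1 <= k <= n:
            raise ValueError(f"k must be in 1..{n}")
        raw = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        # relabel deterministically by first occurrence
        order: dict[int, int] = {}
        out = np.empty_like(raw)
        for i, c in enumerate(raw):
            if c not in order:
                order[c] = len(order) + 1
            out[i] = order[c]
        return pd.Series(out, index=self.labels, name="group")


def ward_linkage(d: DissimilarityMatrix) -> WardTree:
    """Ward clustering of a dissimilarity matrix (Ward.D2 convention).

    scipy's ``ward`` Lance-Williams update is applied directly to the
    Gower dissimilarities; ties are resolved by scipy's deterministic
    nearest-neighbor-chain order, so fixed input gives a fixed tree.
    """
    if len(d.labels) < 2:
        raise ValueError("need at least 2 items to cluster")
    z = hierarchy.linkage(d.condensed(), method="ward")
    return WardTree(z, d.labels)


# --------------------------------------------------------------------------
# Modified location model (continuous reduction): classification EM
# --------------------------------------------------------------------------


@dataclass
class MLMSolution:
    k: int
    assignments: pd.Series
    means: pd.DataFrame
    covariance: pd.DataFrame
    log_likelihood: float
    n_iter: int
    group_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = self.assignments.value_counts().to_dict()
        if len(sizes) != self.k or min(sizes.values()) < 1:
            raise ValueError("solution must have k non-empty groups")
        self.group_sizes = {int(g): int(sizes[g]) for g in sorted(sizes)}


def _pooled_covariance(x: np.ndarray, z: np.ndarray, means: np.ndarray, ridge: float) -> np.ndarray:
    n, t = x.shape
    resid = x - means[z]
    cov = resid.T @ resid / n  # ML divisor under the classification likelihood
    cov = cov + ridge * (np.trace(cov) / t if np.trace(cov) > 0 else 1.0) * np.eye(t)
    return cov


def _log_densities(x: np.ndarray, means: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """n x k matrix of Gaussian log densities."""
    t = x.shape[1]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("pooled covariance is singular after ridge")
    prec = np.linalg.inv(cov)
    diff = x[:, None, :] - means[None, :, :]
    maha = np.einsum("nkt,ts,nks->nk", diff, prec, diff)
    return -0.5 * (t * np.log(2.0 * np.pi) + logdet + maha)


def fit_mlm(
    profiles: pd.DataFrame,
    initial_partition: pd.Series,
    k: int,
    *,
    max_iter: int = 100,
    ridge: float = 1e-8,
    hard: bool = True,
) -> MLMSolution:
    """Classification-EM fit of the common-covariance Gaussian grouping.

    Starting from the Ward cut, iterate (assign each genotype to the
    group with the highest normal log-density; re-estimate group means
    and the pooled covariance) until assignments stabilize. The
    reported log-likelihood is the classification log-likelihood at
    convergence. ``hard=False`` runs soft EM (responsibilities instead
    of hard assignments) and reports the mixture log-likelihood.
    """
    x = profiles.to_numpy(float)
    n, t = x.shape
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genotypes ({n})")
    z = np.asarray(initial_partition.reindex(profiles.index), int) - 1
    if len(np.unique(z)) != k:
        raise ValueError(f"initial partition must have exactly {k} non-empty groups")

    if k == 1:
        means = x.mean(axis=0, keepdims=True)
        cov = _pooled_covariance(x, np.zeros(n, int), means, ridge)
        ll = float(_log_densities(x, means, cov).sum())
        return MLMSolution(
            k=1,
            assignments=pd.Series(np.ones(n, int), index=profiles.index, name="group"),
            means=pd.DataFrame(means, index=[1], columns=profiles.columns),
            covariance=pd.DataFrame(cov, index=profiles.columns, columns=profiles.columns),
            log_likelihood=ll,
            n_iter=0,
        )

    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        means = np.stack([x[z == g].mean(axis=0) for g in range(k)])
        cov = _pooled_covariance(x, z, means, ridge)
        logd = _log_densities(x, means, cov)
        if not hard:
            w = np.full(k, 1.0 / k)
            z_new = np.argmax(logd + np.log(w), axis=1)
        else:
            z_new = np.argmax(logd, axis=1)
        # re-seed emptied groups with the point farthest (Mahalanobis,
        # i.e. lowest pooled-cov log-density) from its assigned mean
        for g in range(k):
            if not np.any(z_new == g):
                warnings.warn(f"group {g + 1} emptied during CEM; re-seeded", stacklevel=2)
                own = logd[np.arange(n), z_new].copy()
                sizes = np.bincount(z_new, minlength=k)
                own[sizes[z_new] <= 1] = np.inf  # never empty another group
                z_new[int(np.argmin(own))] = g
        if np.array_equal(z_new, z):
            break
        z = z_new

    means = np.stack([x[z == g].mean(axis=0) for g in range(k)])
    cov = _pooled_covariance(x, z, means, ridge)
    logd = _log_densities(x, means, cov)
    if hard:
        ll = float(logd[np.arange(n), z].sum())
    else:
        from scipy.special import logsumexp

        ll = float(logsumexp(logd + np.log(1.0 / k), axis=1).sum())
    # relabel groups deterministically by first occurrence in index order
    order: dict[int, int] = {}
    relabeled = np.empty_like(z)
    for i, g in enumerate(z):
        if g not in order:
            order[g] = len(order) + 1
        relabeled[i] = order[g]
    perm = sorted(order, key=order.get)
    return MLMSolution(
        k=k,
        assignments=pd.Series(relabeled, index=profiles.index, name="group"),
        means=pd.DataFrame(means[perm], index=range(1, k + 1), columns=profiles.columns),
        covariance=pd.DataFrame(cov, index=profiles.columns, columns=profiles.columns),
        log_likelihood=ll,
        n_iter=n_iter,
    )


# --------------------------------------------------------------------------
# Cluster-count criteria
# --------------------------------------------------------------------------


@dataclass
class ClusterCriteria:
    """pseudo-F, pseudo-T2 and the MLM likelihood profile over k."""

    table: pd.DataFrame  # columns: k, pseudo_f, pseudo_t2, log_likelihood, delta_log_likelihood
    solutions: dict[int, MLMSolution]


def _within_trace(x: np.ndarray, labels: np.ndarray) -> float:
    w = 0.0
    for g in np.unique(labels):
        sub = x[labels == g]
        w += ((sub - sub.mean(axis=0)) ** 2).sum()
    return float(w)


def _pseudo_t2(x: np.ndarray, tree_labels_k: np.ndarray, tree_labels_km1: np.ndarray) -> float:
    """Duda-Hart statistic for the merge taking k groups to k-1."""
    pairs = {}
    for ck, ck1 in zip(tree_labels_k, tree_labels_km1):
        pairs.setdefault(ck1, set()).add(ck)
    merged = [c for c, members in pairs.items() if len(members) == 2]
    if len(merged) != 1:
        return float("nan")
    a, b = sorted(pairs[merged[0]])
    xa, xb = x[tree_labels_k == a], x[tree_labels_k == b]
    na, nb = len(xa), len(xb)
    wa = ((xa - xa.mean(axis=0)) ** 2).sum()
    wb = ((xb - xb.mean(axis=0)) ** 2).sum()
    xm = np.vstack([xa, xb])
    wm = ((xm - xm.mean(axis=0)) ** 2).sum()
    b_kl = wm - wa - wb
    if na + nb < 3 or (wa + wb) <= 0:
        return float("nan")
    return float(b_kl / ((wa + wb) / (na + nb - 2)))


def cluster_criteria(
    profiles: pd.DataFrame,
    tree: WardTree,
    kmax: int | None = None,
    *,
    normalize: bool = True,
    ridge: float = 1e-8,
) -> ClusterCriteria:
    """Criteria for every candidate group count k = 1..kmax.

    pseudo-F (Calinski-Harabasz) and pseudo-T2 (Duda-Hart) are computed
    on range-normalized profiles at the Ward cut; the log-likelihood is
    the converged MLM classification likelihood initialized from that
    cut. Undefined criteria (degenerate partitions) are reported as
    missing, never fabricated.
    """
    n = len(profiles)
    kmax = min(10, n - 1) if kmax is None else kmax
    if not 2 <= kmax <= n - 1:
        raise ValueError(f"kmax must be in 2..{n - 1}")
    xdf = range_normalize(profiles) if normalize else profiles
    if xdf.shape[1] == 0:
        # all profiles identical: every criterion is undefined
        table = pd.DataFrame(
            {
                "k": range(1, kmax + 1),
                "pseudo_f": np.nan,
                "pseudo_t2": np.nan,
                "log_likelihood": np.nan,
                "delta_log_likelihood": np.nan,
            }
        )
        return ClusterCriteria(table=table, solutions={})
    x = xdf.to_numpy(float)
    total = float(((x - x.mean(axis=0)) ** 2).sum())

    cuts = {k: tree.cut(k).to_numpy() for k in range(1, kmax + 1)}
    rows, solutions = [], {}
    for k in range(1, kmax + 1):
        sol = fit_mlm(xdf, pd.Series(cuts[k], index=xdf.index), k, ridge=ridge)
        solutions[k] = sol
        if k >= 2:
            within = _within_trace(x, cuts[k])
            between = total - within
            pf = (
                (between / (k - 1)) / (within / (n - k))
                if within > 0 and n > k
                else float("nan")
            )
            pt2 = _pseudo_t2(x, cuts[k], cuts[k - 1])
        else:
            pf, pt2 = float("nan"), float("nan")
        rows.append(
            {
                "k": k,
                "pseudo_f": pf,
                "pseudo_t2": pt2,
                "log_likelihood": sol.log_likelihood,
            }
        )
    table = pd.DataFrame(rows)
    table["delta_log_likelihood"] = table["log_likelihood"].diff()
    drops = table["delta_log_likelihood"].dropna() < -1e-6
    if drops.any():
        logger.warning(
            "log-likelihood decreased at k in %s; inspect the profile",
            list(table.loc[drops[drops].index, "k"]),
        )
    return ClusterCriteria(table=table, solutions=solutions)


def select_group_count(criteria: ClusterCriteria) -> int:
    """Choose k at the greatest increase of the log-likelihood profile.

    k* = argmax over k >= 2 of logL(k) - logL(k-1); ties break toward
    the smaller k. pseudo-F / pseudo-T2 stay in the criteria table as
    concordance diagnostics but do not enter the decision.
    """
    t = criteria.table
    cand = t[(t["k"] >= 2) & t["delta_log_likelihood"].notna()]
    if cand.empty:
        raise ValueError("no candidate k >= 2 with a defined likelihood increment")
    best = cand.loc[cand["delta_log_likelihood"].idxmax()]
    ties = cand[np.isclose(cand["delta_log_likelihood"], best["delta_log_likelihood"])]
    k_star = int(ties["k"].min())
    if len(ties) > 1:
        logger.info("tie in likelihood increments; choosing smallest k = %d", k_star)
    return k_star


# --------------------------------------------------------------------------
# Inter-group divergence
# --------------------------------------------------------------------------


def intergroup_distances(solution: MLMSolution) -> pd.DataFrame:
    """Squared Mahalanobis distances between group means (pooled cov)."""
    if solution.k < 2:
        raise ValueError("need at least 2 groups")
    means = solution.means.to_numpy(float)
    cov = solution.covariance.to_numpy(float)
    sign, _ = np.linalg.slogdet(cov)
    if sign <= 0:
        raise np.linalg.LinAlgError("pooled covariance is singular")
    prec = np.linalg.inv(cov)
    diff = means[:, None, :] - means[None, :, :]
    d2 = np.einsum("ijt,ts,ijs->ij", diff, prec, diff)
    d2 = 0.5 * (d2 + d2.T)
    np.fill_diagonal(d2, 0.0)
    groups = list(solution.means.index)
    return pd.DataFrame(d2, index=groups, columns=groups)
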