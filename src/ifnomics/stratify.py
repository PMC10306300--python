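"""Unsupervised stratification of the cohort.

Two complementary routes:

* consensus clustering (Monti resampling scheme) of inflammatory-marker
  z-scores — repeated subsampled hierarchical clusterings with a Pearson
  correlation distance, co-clustering frequencies as stability evidence,
  and the consensus-CDF delta-area curve to choose k;
* mixed-data clinical clustering — Gower distances over binary condition
  flags plus the numeric IFN score, PAM (partitioning around medoids) with
  average silhouette width to choose k, observed/expected case ratios and
  Fisher exact tests per condition, and Mann-Whitney comparisons of score
  distributions across the resulting groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples

from .association import bh_adjust

__all__ = [
    "ConsensusResult", "ConsensusClustering", "PAM",
    "consensus_cluster", "select_k_delta_area", "gower_distance",
    "pam_cluster", "silhouette_select_k", "condition_enrichment",
    "compare_scores_across_groups",
]


# ---------------------------------------------------------------------------
# Consensus clustering

@dataclass
class ConsensusResult:
    consensus: dict[int, pd.DataFrame]      # k -> sample x sample in [0, 1]
    labels: dict[int, pd.Series]            # k -> final labels (1..k)
    auc: dict[int, float]                   # k -> consensus-CDF area
    delta_area: dict[int, float]            # k -> relative AUC gain
    chosen_k: int | None = None
    resample_log: dict = field(default_factory=dict)


def _pearson_distance(X: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows."""
    c = np.corrcoef(X)
    return np.clip(1.0 - c, 0.0, 2.0)


def _cdf_area(consensus: np.ndarray) -> float:
    """Area under the empirical CDF of upper-triangle consensus entries."""
    iu = np.triu_indices(consensus.shape[0], k=1)
    vals = consensus[iu]
    grid = np.linspace(0.0, 1.0, 101)
    cdf = np.searchsorted(np.sort(vals), grid, side="right") / len(vals)
    return float(np.trapezoid(cdf, grid))


def consensus_cluster(
    marker_z: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7),
    reps: int = 100,
    item_fraction: float = 0.8,
    linkage: str = "average",
    seed: int = 0,
    gain_threshold: float = 0.05,
) -> ConsensusResult:
    """Monti consensus clustering of samples by marker z-scores.

    ``marker_z`` is marker x sample. Each rep subsamples
    ``item_fraction`` of the samples, computes 1 - Pearson distance among
    them, cuts an agglomerative tree at each k, and accumulates
    co-clustering counts normalized by co-sampling counts. Final labels per
    k come from a hierarchical cut of 1 - consensus. Zero-variance markers
    are dropped with a warning.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    var = marker_z.var(axis=1)
    if (var == 0).any():
        warnings.warn(f"dropped zero-variance marker(s): {list(marker_z.index[var == 0])}")
        marker_z = marker_z.loc[var > 0]
    X = marker_z.to_numpy(float).T          # samples x markers
    n = X.shape[0]
    if max(k_range) > n - 1:
        raise ValueError(f"max k {max(k_range)} exceeds n - 1 = {n - 1}")
    samples = list(marker_z.columns)
    rng = np.random.default_rng(seed)
    m = max(2, int(round(item_fraction * n)))

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sampled = np.zeros((n, n))
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False)) if m < n else np.arange(n)
        co_sampled[np.ix_(idx, idx)] += 1
        D = _pearson_distance(X[idx])
        Z = scipy_linkage(squareform(D, checks=False), method=linkage)
        for k in k_range:
            lab = fcluster(Z, t=k, criterion="maxclust")
            same = lab[:, None] == lab[None, :]
            co_cluster[k][np.ix_(idx, idx)] += same

    result = ConsensusResult(consensus={}, labels={}, auc={}, delta_area={},
                             resample_log={"seed": seed, "reps": reps,
                                           "item_fraction": item_fraction,
                                           "linkage": linkage})
    with np.errstate(invalid="ignore"):
        for k in k_range:
            C = np.where(co_sampled > 0, co_cluster[k] / np.maximum(co_sampled, 1), 0.0)
            np.fill_diagonal(C, 1.0)
            C = (C + C.T) / 2
            result.consensus[k] = pd.DataFrame(C, index=samples, columns=samples)
            Zf = scipy_linkage(squareform(np.clip(1.0 - C, 0, None), checks=False),
                               method=linkage)
            result.labels[k] = pd.Series(fcluster(Zf, t=k, criterion="maxclust"),
                                         index=samples, name=f"k{k}")
            result.auc[k] = _cdf_area(C)

    ks = sorted(k_range)
    for i, k in enumerate(ks):
        if i == 0:
            result.delta_area[k] = result.auc[k]
        else:
            prev = result.auc[ks[i - 1]]
            result.delta_area[k] = (result.auc[k] - prev) / prev if prev > 0 else np.inf
    result.chosen_k = select_k_delta_area(result, gain_threshold)
    return result


def select_k_delta_area(result: ConsensusResult, gain_threshold: float = 0.05) -> int:
    """Choose k as the last one before the relative AUC gain plateaus.

    The smallest k whose relative gain over k-1 falls below
    ``gain_threshold`` marks the plateau; the selection is the k before it.
    A curve that never plateaus returns the largest k with a warning.
    """
    ks = sorted(result.delta_area)
    if len(ks) < 3:
        raise ValueError("need at least 3 evaluated k values")
    for i, k in enumerate(ks[1:], start=1):
        if result.delta_area[k] < gain_threshold:
            return ks[i - 1]
    warnings.warn("consensus AUC gains never fell below the threshold; "
                  "returning the largest k")
    return ks[-1]


class ConsensusClustering(BaseEstimator, ClusterMixin):
    """sklearn-style estimator over :func:`consensus_cluster`.

    fit(X) expects samples as rows, features (marker z-scores) as columns.
    Fitted attributes: ``labels_`` (at the chosen k), ``k_``,
    ``consensus_matrices_``, ``auc_``, ``delta_area_``, ``result_``.
    """

    def __init__(self, k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7),
                 reps: int = 100, item_fraction: float = 0.8,
                 linkage: str = "average", gain_threshold: float = 0.05,
                 random_state: int = 0):
        self.k_range = k_range
        self.reps = reps
        self.item_fraction = item_fraction
        self.linkage = linkage
        self.gain_threshold = gain_threshold
        self.random_state = random_state

    def fit(self, X, y=None):
        df = pd.DataFrame(X)
        res = consensus_cluster(df.T, k_range=self.k_range, reps=self.reps,
                                item_fraction=self.item_fraction,
                                linkage=self.linkage, seed=self.random_state,
                                gain_threshold=self.gain_threshold)
        self.result_ = res
        self.k_ = res.chosen_k
        self.labels_ = res.labels[self.k_].to_numpy()
        self.consensus_matrices_ = res.consensus
        self.auc_ = res.auc
        self.delta_area_ = res.delta_area
        return self


# ---------------------------------------------------------------------------
# Gower distance

def gower_distance(records: pd.DataFrame) -> pd.DataFrame:
    """Gower dissimilarity over mixed binary/numeric variables.

    Rows are records (samples), columns variables. Boolean (or 0/1) columns
    contribute simple matching (0 if equal, 1 otherwise — symmetric);
    numeric columns contribute |xi - xj| / range. Missing values are
    excluded pairwise from the average; zero-range numeric variables carry
    no information and are excluded. A record pair sharing no non-missing
    variable raises.
    """
    n = len(records)
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for col in records.columns:
        v = records[col]
        ok = v.notna().to_numpy()
        both = np.outer(ok, ok)
        if pd.api.types.is_bool_dtype(v) or set(v.dropna().unique()) <= {0, 1, True, False}:
            x = v.to_numpy()
            x = np.where(ok, np.asarray(x, float), np.nan)
            d = (x[:, None] != x[None, :]).astype(float)
        else:
            x = v.to_numpy(float)
            rng_ = np.nanmax(x) - np.nanmin(x)
            if not np.isfinite(rng_) or rng_ == 0:
                continue
            d = np.abs(x[:, None] - x[None, :]) / rng_
        num += np.where(both, d, 0.0)
        den += both
    if (den == 0).any():
        i, j = np.argwhere(den == 0)[0]
        raise ValueError(f"record pair ({records.index[i]}, {records.index[j]}) "
                         "shares no non-missing variables")
    D = num / den
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=records.index, columns=records.index)


# ---------------------------------------------------------------------------
# PAM

def _pam_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam_cluster(dist: pd.DataFrame | np.ndarray, k: int, seed: int = 0,
                max_iter: int = 200, method: str = "auto",
                exact_limit: int = 2000) -> tuple[np.ndarray, list[int]]:
    """Partitioning around medoids.

    For small instances (at most ``exact_limit`` candidate medoid sets) the
    optimum is found by exhaustive enumeration, so tiny problems are exact
    by construction. Larger instances use the classic greedy BUILD phase
    followed by steepest-descent SWAP until no single medoid exchange
    lowers the total distance-to-medoid cost (a local search, as in the
    standard implementations). Deterministic: ties break toward the lowest
    index. Returns (labels 1..k aligned to the input order, medoid
    positional indices).
    """
    D = np.asarray(dist, float)
    n = D.shape[0]
    if D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (np.diag(D) != 0).any() or (D < 0).any():
        raise ValueError("distances must be nonnegative with a zero diagonal")
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")

    if method == "auto":
        import math
        method = "exact" if math.comb(n, k) <= exact_limit else "swap"
    if method == "exact":
        import itertools
        best_cost, best = np.inf, None
        for m in itertools.combinations(range(n), k):
            c = _pam_cost(D, list(m))
            if c < best_cost - 1e-12:
                best_cost, best = c, list(m)
        medoids = best
        labels = np.argmin(D[:, medoids], axis=1) + 1
        return labels, medoids

    # BUILD: first medoid minimizes total distance; then greedy max gain
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        best_gain, best_j = -np.inf, None
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0.0).sum()
            if gain > best_gain + 1e-12:
                best_gain, best_j = gain, j
        medoids.append(best_j)

    # SWAP: steepest-descent swaps until no improvement
    cost = _pam_cost(D, medoids)
    for _ in range(max_iter):
        best_delta, best_swap = -1e-12, None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                delta = cost - _pam_cost(D, trial)
                if delta > best_delta + 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        cost -= best_delta
    medoids = sorted(medoids)
    labels = np.argmin(D[:, medoids], axis=1) + 1
    return labels, medoids


class PAM(BaseEstimator, ClusterMixin):
    """sklearn-style k-medoids on a precomputed distance matrix.

    Fitted attributes: ``labels_`` (1..k), ``medoid_indices_``,
    ``inertia_`` (total distance to medoids).
    """

    def __init__(self, n_clusters: int = 2, random_state: int = 0):
        self.n_clusters = n_clusters
        self.random_state = random_state

    def fit(self, X, y=None):
        D = np.asarray(X, float)
        labels, medoids = pam_cluster(D, self.n_clusters, seed=self.random_state)
        self.labels_ = labels
        self.medoid_indices_ = medoids
        self.inertia_ = _pam_cost(D, medoids)
        return self


def silhouette_select_k(
    dist: pd.DataFrame | np.ndarray,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Run PAM per k and return the k with the highest average silhouette.

    Silhouette s(i) = (b - a) / max(a, b) on the supplied distances;
    singleton-cluster members take s(i) = 0 by convention (warned). Ties
    break toward the smallest k.
    """
    D = np.asarray(dist, float)
    n = D.shape[0]
    if min(k_range) < 2 or max(k_range) > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    widths = {}
    for k in k_range:
        labels, _ = pam_cluster(D, k, seed=seed)
        sizes = np.bincount(labels)[1:]
        if (sizes == 1).any():
            warnings.warn(f"k={k}: singleton cluster(s); members get s(i) = 0")
        s = silhouette_samples(D, labels, metric="precomputed")
        widths[k] = float(s.mean())
    best = max(sorted(widths), key=lambda k: widths[k])
    return best, widths


# ---------------------------------------------------------------------------
# Condition enrichment

def _fisher_rxc_montecarlo(table: np.ndarray, n_sim: int, rng) -> float:
    """Monte-Carlo exact test: probability-ordering of k x 2 tables with
    fixed margins, estimated by permuting case labels."""
    k = table.shape[0]
    cluster_sizes = table.sum(axis=1)
    cases = int(table[:, 0].sum())
    n = int(cluster_sizes.sum())
    labels = np.repeat(np.arange(k), cluster_sizes)
    obs_logp = _table_logprob(table)
    flags = np.zeros(n, bool)
    flags[:cases] = True
    hits = 0
    for _ in range(n_sim):
        rng.shuffle(flags)
        sim = np.zeros_like(table)
        for c in range(k):
            in_c = labels == c
            sim[c, 0] = flags[in_c].sum()
            sim[c, 1] = in_c.sum() - sim[c, 0]
        if _table_logprob(sim) <= obs_logp + 1e-12:
            hits += 1
    return (hits + 1) / (n_sim + 1)


def _table_logprob(table: np.ndarray) -> float:
    """Log multivariate-hypergeometric probability of a k x 2 table."""
    from scipy.special import gammaln
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return float(gammaln(row + 1).sum() + gammaln(col + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def condition_enrichment(
    labels: pd.Series,
    conditions: pd.DataFrame,
    min_cases: int = 10,
    n_sim: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed/expected case ratios and Fisher tests per condition.

    ``labels`` maps sample -> cluster (1..k); ``conditions`` is sample x
    condition boolean flags, pre-filtered to conditions with at least
    ``min_cases`` cases and controls. Returns (tests, oe): per-condition
    odds ratio (2x2 only), p and BH q; and the condition x cluster O/E
    matrix, where E assumes equal occurrence rates in every cluster. For
    k > 2 clusters the exact test is Monte-Carlo with a seed.
    """
    conditions = conditions.loc[labels.index]
    clusters = np.sort(pd.unique(labels))
    k = len(clusters)
    sizes = labels.value_counts().loc[clusters].to_numpy()
    rng = np.random.default_rng(seed)

    oe = pd.DataFrame(index=conditions.columns,
                      columns=[f"cluster_{c}" for c in clusters], dtype=float)
    rows = []
    for cond in conditions.columns:
        flags = conditions[cond].astype(bool)
        n_cases = int(flags.sum())
        n_ctrl = int((~flags).sum())
        if n_cases < min_cases or n_ctrl < min_cases:
            raise ValueError(f"condition {cond!r} violates the >= {min_cases} "
                             "cases-and-controls contract")
        obs = np.array([int(flags[labels == c].sum()) for c in clusters])
        rate = n_cases / len(labels)
        expected = sizes * rate
        oe.loc[cond] = obs / expected
        table = np.column_stack([obs, sizes - obs])
        if k == 2:
            odds, p = stats.fisher_exact(table, alternative="two-sided")
        else:
            odds = np.nan
            p = _fisher_rxc_montecarlo(table, n_sim, rng)
        rows.append((cond, odds, p, n_cases))
    tests = pd.DataFrame(rows, columns=["condition", "odds_ratio", "p", "n_cases"])
    tests["q"] = bh_adjust(tests["p"].to_numpy())
    return tests.set_index("condition"), oe


def compare_scores_across_groups(
    scores: pd.Series,
    groups: pd.Series,
    reference=None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U comparisons of score distributions.

    With a ``reference`` group label, each other group is compared against
    it; with exactly two groups and no reference, the single pairwise
    comparison is made. BH across comparisons when several are made; exact
    p for small tie-free groups, normal approximation with tie correction
    otherwise. Empty groups are skipped with a warning.
    """
    groups = groups.loc[scores.index]
    levels = sorted(pd.unique(groups.dropna()), key=str)
    if reference is None:
        if len(levels) != 2:
            raise ValueError("supply a reference group when more than two exist")
        pairs = [(levels[0], levels[1])]
    else:
        pairs = [(reference, g) for g in levels if g != reference]

    rows = []
    for ref, other in pairs:
        a = scores[groups == ref].dropna().to_numpy()
        b = scores[groups == other].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"empty group in comparison {ref!r} vs {other!r}; skipped")
            continue
        res = stats.mannwhitneyu(b, a, alternative="two-sided", method="auto")
        rows.append((f"{other}_vs_{ref}", float(res.statistic), float(res.pvalue),
                     len(b), len(a)))
    out = pd.DataFrame(rows, columns=["comparison", "U", "p", "n_group", "n_ref"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.set_index("comparison")
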