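"""Association screens linking IFN scores and group status to omics layers.

* :func:`spearman_screen` — rank correlation of a per-sample score against
  every feature of a layer, BH-adjusted within the screen.
* :func:`differential_abundance` — per-analyte linear model of
  log2(abundance) on karyotype + age + sex + source; the karyotype
  coefficient is the log2 fold change.
* :class:`BetaRegression` — maximum-likelihood beta regression with a logit
  mean link and constant precision phi, fit by Fisher scoring; the tool for
  compositional immune-cell frequencies, whose exponentiated coefficients
  read as fold changes per unit predictor.
* :func:`preranked_gsea` — weighted Kolmogorov-Smirnov running-sum
  enrichment with a gene-label permutation null.

Every screen's BH family is that screen alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from statsmodels.stats.multitest import multipletests

from .preprocess import _check_full_rank, _design

__all__ = [
    "BetaRegFit", "BetaRegression", "GseaResult",
    "spearman_screen", "differential_abundance", "fit_beta_regression",
    "beta_screen", "preranked_gsea", "read_gmt",
]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaNs pass through untouched."""
    p = np.asarray(p, float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# Spearman screen

def spearman_screen(
    scores: pd.Series,
    features: pd.DataFrame,
    min_pairs: int = 4,
) -> pd.DataFrame:
    """Average-rank Spearman rho of ``scores`` against each feature row.

    Pairwise-complete per feature; p from the t-approximation; BH q across
    the screen. Constant features (or fewer than ``min_pairs`` pairs) get
    missing rho and are excluded from the BH family.
    """
    scores = scores.loc[features.columns]
    rho = np.full(len(features), np.nan)
    pval = np.full(len(features), np.nan)
    nused = np.zeros(len(features), int)
    s = scores.to_numpy(float)
    F = features.to_numpy(float)
    for i in range(len(features)):
        ok = np.isfinite(F[i]) & np.isfinite(s)
        nused[i] = ok.sum()
        if nused[i] < min_pairs:
            continue
        x, y = F[i, ok], s[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            continue
        r, p = stats.spearmanr(x, y)
        rho[i], pval[i] = r, p
    out = pd.DataFrame({
        "kind": "spearman_rho", "estimate": rho, "p": pval,
        "q": bh_adjust(pval), "n": nused,
    }, index=features.index)
    return out


# ---------------------------------------------------------------------------
# Differential abundance

def differential_abundance(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "source"),
    group: str = "karyotype",
) -> pd.DataFrame:
    """Per-analyte linear model log2(abundance) ~ group + covariates.

    Estimate is the group (T21 vs control) coefficient, i.e. the log2 fold
    change; BH across analytes. Non-positive abundances are a QC-contract
    violation and raise; analytes constant across samples are dropped with
    a warning.
    """
    V = values.to_numpy(float)
    if np.nanmin(V) <= 0:
        raise ValueError("non-positive abundance reached differential_abundance; "
                         "run preprocessing first")
    samples = list(values.columns)
    meta = metadata.loc[samples]
    X, names = _design(meta, [group] + list(covariates))
    _check_full_rank(X, names)
    gcols = [i for i, nm in enumerate(names) if nm.startswith(f"{group}[")]
    t21 = [i for i in gcols if names[i] == f"{group}[T21]"]
    gi = t21[0] if t21 else gcols[0]
    sign = 1.0 if t21 or "T21" not in set(meta[group]) else -1.0

    Y = np.log2(V)
    const = np.nanvar(Y, axis=1) == 0
    if const.any():
        warnings.warn(f"dropped constant analyte(s): {list(values.index[const])}")

    est = np.full(len(values), np.nan)
    pval = np.full(len(values), np.nan)
    nused = np.zeros(len(values), int)
    finite = np.isfinite(Y)
    n, p = X.shape

    def _fit_block(idx, Xb, Yb):
        XtX_inv = np.linalg.inv(Xb.T @ Xb)
        beta = XtX_inv @ Xb.T @ Yb.T
        resid = Yb.T - Xb @ beta
        dof = Xb.shape[0] - p
        sigma2 = (resid ** 2).sum(axis=0) / dof
        se = np.sqrt(sigma2 * XtX_inv[gi, gi])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[gi] / se
        est[idx] = sign * beta[gi]
        ok = se > 0
        pv = np.full(len(idx), np.nan)
        pv[ok] = 2 * stats.t.sf(np.abs(t[ok]), dof)
        pval[idx] = pv

    complete = finite.all(axis=1) & ~const
    if complete.any():
        idx = np.where(complete)[0]
        _fit_block(idx, X, Y[idx])
        nused[idx] = n
    for i in np.where(~complete & ~const)[0]:
        ok = finite[i]
        nused[i] = int(ok.sum())
        if ok.sum() <= p:
            continue
        _fit_block(np.array([i]), X[ok], Y[i, ok][None, :])

    return pd.DataFrame({
        "kind": "log2fc", "estimate": est, "p": pval,
        "q": bh_adjust(pval), "n": nused,
    }, index=values.index)


# ---------------------------------------------------------------------------
# Beta regression

@dataclass
class BetaRegFit:
    """Maximum-likelihood beta regression fit (logit link, constant phi)."""

    coef: pd.Series            # logit-scale coefficients
    phi: float                 # precision
    se: pd.Series              # coefficient standard errors
    se_phi: float
    loglik: float
    converged: bool
    iterations: int
    pvalues: pd.Series         # two-sided Wald per coefficient

    def fold_change(self, term: str) -> float:
        """exp(coefficient): multiplicative odds change per predictor unit."""
        return float(np.exp(self.coef[term]))


def _beta_loglik(y, mu, phi):
    a, b = mu * phi, (1 - mu) * phi
    return float(np.sum(special.gammaln(phi) - special.gammaln(a)
                        - special.gammaln(b) + (a - 1) * np.log(y)
                        + (b - 1) * np.log1p(-y)))


def fit_beta_regression(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
    boundary_transform: bool = False,
) -> BetaRegFit:
    """Fisher-scoring ML fit of Beta(mu*phi, (1-mu)*phi), logit(mu) = X b.

    Standard errors come from the inverse expected information; the log
    likelihood is non-decreasing across accepted iterations (step-halving).
    ``boundary_transform`` applies the Smithson-Verkuilen shrink
    y' = (y(n-1) + 0.5)/n so exact 0/1 frequencies become interior.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    if np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    if np.any((y <= 0) | (y >= 1)):
        if not boundary_transform:
            raise ValueError("responses on the boundary; enable boundary_transform")
        y = (y * (n - 1) + 0.5) / n

    # start: OLS on the empirical logit; phi from response-scale moments
    ylogit = np.log(y / (1 - y))
    beta, *_ = np.linalg.lstsq(X, ylogit, rcond=None)
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    resid_var = max(np.var(y - mu), 1e-12)
    phi = max(float(np.mean(mu * (1 - mu)) / resid_var - 1.0), 1.0)

    theta = np.append(beta, np.log(phi))
    ll = _beta_loglik(y, mu, phi)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta, logphi = theta[:p], theta[p]
        phi = np.exp(logphi)
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        t = mu * (1 - mu)                      # dmu/deta for logit
        ystar = np.log(y / (1 - y))
        mustar = special.digamma(mu * phi) - special.digamma((1 - mu) * phi)
        score_b = phi * (X.T @ (t * (ystar - mustar)))
        score_phi = np.sum(mu * (ystar - mustar) + np.log1p(-y)
                           - special.digamma((1 - mu) * phi) + special.digamma(phi))
        tri_a = special.polygamma(1, mu * phi)
        tri_b = special.polygamma(1, (1 - mu) * phi)
        w = phi * (tri_a + tri_b) * t ** 2
        K_bb = phi * (X.T @ (X * w[:, None]))
        c = phi * (tri_a * mu - tri_b * (1 - mu))
        K_bphi = X.T @ (t * c)
        K_phiphi = np.sum(tri_a * mu ** 2 + tri_b * (1 - mu) ** 2
                          - special.polygamma(1, phi))
        K = np.zeros((p + 1, p + 1))
        K[:p, :p] = K_bb
        K[:p, p] = K[p, :p] = phi * K_bphi      # chain rule for log phi
        K[p, p] = phi ** 2 * K_phiphi
        score = np.append(score_b, phi * score_phi)
        try:
            step = np.linalg.solve(K, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(K, score, rcond=None)[0]
        # step-halving keeps the accepted log-likelihood non-decreasing
        ll_new, lam = -np.inf, 1.0
        for _ in range(30):
            cand = theta + lam * step
            mu_c = 1.0 / (1.0 + np.exp(-(X @ cand[:p])))
            phi_c = np.exp(cand[p])
            ll_new = _beta_loglik(y, mu_c, phi_c)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            lam /= 2
        if not np.isfinite(ll_new) or ll_new < ll - 1e-12:
            break
        theta = theta + lam * step
        if abs(ll_new - ll) < tol:
            ll = ll_new
            converged = True
            break
        ll = ll_new

    beta, phi = theta[:p], float(np.exp(theta[p]))
    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    # expected information at the optimum, on the (beta, phi) scale
    t = mu * (1 - mu)
    tri_a = special.polygamma(1, mu * phi)
    tri_b = special.polygamma(1, (1 - mu) * phi)
    w = phi * (tri_a + tri_b) * t ** 2
    K = np.zeros((p + 1, p + 1))
    K[:p, :p] = phi * (X.T @ (X * w[:, None]))
    c = phi * (tri_a * mu - tri_b * (1 - mu))
    K[:p, p] = K[p, :p] = X.T @ (t * c)
    K[p, p] = np.sum(tri_a * mu ** 2 + tri_b * (1 - mu) ** 2
                     - special.polygamma(1, phi))
    cov = np.linalg.pinv(K)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = np.where(se[:p] > 0, beta / se[:p], np.nan)
    pvals = 2 * stats.norm.sf(np.abs(z))
    return BetaRegFit(
        coef=pd.Series(beta, index=names),
        phi=phi,
        se=pd.Series(se[:p], index=names),
        se_phi=float(se[p]),
        loglik=float(_beta_loglik(y, mu, phi)),
        converged=converged,
        iterations=it,
        pvalues=pd.Series(pvals, index=names),
    )


class BetaRegression(BaseEstimator, RegressorMixin):
    """sklearn-style estimator over :func:`fit_beta_regression`.

    fit(X, y) expects y strictly inside (0, 1) unless
    ``boundary_transform``; an intercept column is added automatically.
    Fitted attributes: ``coef_``, ``intercept_``, ``phi_``, ``se_``,
    ``pvalues_``, ``loglik_``, ``converged_``, ``n_iter_``.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-10,
                 boundary_transform: bool = False):
        self.max_iter = max_iter
        self.tol = tol
        self.boundary_transform = boundary_transform

    def fit(self, X, y):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        names = ["intercept"] + [f"x{i}" for i in range(X.shape[1])]
        Xd = np.column_stack([np.ones(len(X)), X])
        fit = fit_beta_regression(np.asarray(y, float), Xd, names=names,
                                  max_iter=self.max_iter, tol=self.tol,
                                  boundary_transform=self.boundary_transform)
        self.result_ = fit
        self.intercept_ = float(fit.coef.iloc[0])
        self.coef_ = fit.coef.iloc[1:].to_numpy()
        self.phi_ = fit.phi
        self.se_ = fit.se.to_numpy()
        self.pvalues_ = fit.pvalues.to_numpy()
        self.loglik_ = fit.loglik
        self.converged_ = fit.converged
        self.n_iter_ = fit.iterations
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[:, None]
        eta = self.intercept_ + X @ self.coef_
        return 1.0 / (1.0 + np.exp(-eta))


def beta_screen(
    cells: pd.DataFrame,
    predictor: pd.Series,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    boundary_transform: bool = False,
) -> pd.DataFrame:
    """One beta regression per cell cluster; BH across clusters.

    ``cells`` is cluster x sample relative frequencies (outlier exclusion
    already applied, excluded values missing); ``predictor`` is the IFN
    score (or any per-sample numeric). The estimate is
    exp(predictor coefficient), the fold change in the mean frequency per
    unit predictor. Non-convergent fits are flagged and excluded from the
    BH family with a warning.
    """
    samples = list(cells.columns)
    pred = predictor.loc[samples].to_numpy(float)
    if np.ptp(pred[np.isfinite(pred)]) == 0:
        raise ValueError("constant predictor: no identifiable slope")
    meta = metadata.loc[samples]
    Xcov, names = _design(meta, list(covariates))
    design = np.column_stack([Xcov, pred])
    names = names + ["predictor"]
    _check_full_rank(design, names)

    est = np.full(len(cells), np.nan)
    pval = np.full(len(cells), np.nan)
    nused = np.zeros(len(cells), int)
    bad = []
    for i, cluster in enumerate(cells.index):
        y = cells.iloc[i].to_numpy(float)
        ok = np.isfinite(y) & np.isfinite(pred)
        if ok.sum() == 0 or np.all(y[ok] == 0):
            warnings.warn(f"cluster {cluster!r} all-zero or empty; skipped")
            continue
        try:
            fit = fit_beta_regression(y[ok], design[ok], names=names,
                                      boundary_transform=boundary_transform)
        except ValueError as e:
            warnings.warn(f"cluster {cluster!r} not fit: {e}")
            continue
        nused[i] = int(ok.sum())
        if not fit.converged:
            bad.append(cluster)
            continue
        est[i] = np.exp(fit.coef["predictor"])
        pval[i] = fit.pvalues["predictor"]
    if bad:
        warnings.warn(f"non-convergent beta regression for cluster(s) {bad}; excluded")
    return pd.DataFrame({
        "kind": "fold_change_per_unit", "estimate": est, "p": pval,
        "q": bh_adjust(pval), "n": nused,
    }, index=cells.index)


# ---------------------------------------------------------------------------
# Preranked GSEA

@dataclass
class GseaResult:
    table: pd.DataFrame            # gene_set, ES, NES, p, q, size
    leading_edge: dict[str, list[str]]


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set reader: name <tab> description <tab> genes..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def _es_running(r_sorted: np.ndarray, hit: np.ndarray, weight: float = 1.0):
    """Weighted KS running sum over a descending ranking; returns (ES, peak)."""
    w = np.abs(r_sorted) ** weight
    hit_w = np.where(hit, w, 0.0)
    denom_hit = hit_w.sum()
    n_miss = len(r_sorted) - int(hit.sum())
    if denom_hit == 0 or n_miss == 0:
        return 0.0, -1
    p_hit = np.cumsum(hit_w) / denom_hit
    p_miss = np.cumsum(~hit) / n_miss
    running = p_hit - p_miss
    # extreme deviation from zero; an exact +/- tie resolves positive
    mx, mn = running.max(), running.min()
    if mx >= -mn - 1e-12:
        peak = int(np.argmax(running))
        return float(mx), peak
    peak = int(np.argmin(running))
    return float(mn), peak


def preranked_gsea(
    ranking: pd.Series,
    gene_sets: dict[str, list[str]],
    n_perm: int = 10_000,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 500,
    weight: float = 1.0,
) -> GseaResult:
    """Preranked gene-set enrichment with a gene-label permutation null.

    The ranking metric is whatever the caller supplies (log2 fold change,
    log2FC x -log10 p, Spearman rho, ...) and must have no missing values.
    ES is the extreme of the weighted KS running sum (weight exponent 1);
    the null permutes gene labels (equivalently, draws random same-size
    sets); NES = ES / mean(|same-sign null ES|); p is the same-sign
    permutation tail with add-one smoothing; BH q across the reported sets.
    Ranking ties are broken by stable gene-ID order for determinism.
    """
    if ranking.isna().any():
        raise ValueError("ranking contains missing values")
    ranking = ranking.sort_index(kind="stable")
    order = np.argsort(-ranking.to_numpy(), kind="stable")
    genes = ranking.index.to_numpy()[order]
    r_sorted = ranking.to_numpy()[order]
    pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    rng = np.random.default_rng(seed)

    rows, leading = [], {}
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(gene_sets):
        members = [g for g in gene_sets[name] if g in pos]
        m = len(members)
        if m < min_size or m > max_size:
            continue
        hit = np.zeros(N, bool)
        hit[[pos[g] for g in members]] = True
        es, peak = _es_running(r_sorted, hit, weight)
        if m not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                h = np.zeros(N, bool)
                h[rng.choice(N, size=m, replace=False)] = True
                null[b], _ = _es_running(r_sorted, h, weight)
            null_cache[m] = null
        null = null_cache[m]
        if es >= 0:
            same = null[null >= 0]
            p = (1 + np.sum(same >= es)) / (1 + len(same))
            scale = same[same > 0].mean() if np.any(same > 0) else np.nan
        else:
            same = null[null <= 0]
            p = (1 + np.sum(same <= es)) / (1 + len(same))
            scale = -same[same < 0].mean() if np.any(same < 0) else np.nan
        nes = es / scale if np.isfinite(scale) and scale > 0 else np.nan
        if es >= 0:
            le = [g for g in genes[: peak + 1] if g in set(members)]
        else:
            le = [g for g in genes[peak:] if g in set(members)]
        leading[name] = le
        rows.append((name, es, nes, p, m))

    table = pd.DataFrame(rows, columns=["gene_set", "ES", "NES", "p", "size"])
    table["q"] = bh_adjust(table["p"].to_numpy())
    table = table[["gene_set", "ES", "NES", "p", "q", "size"]]
    return GseaResult(table=table.set_index("gene_set"), leading_edge=leading)
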