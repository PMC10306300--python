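"""Platform-specific cleaning of plasma panels and covariate adjustment.

Implements the four cleaning steps every downstream analysis assumes:

* extreme-outlier exclusion (3x interquartile-range fences, per karyotype
  per analyte, single pass);
* immunoassay out-of-range resolution (below-range values take the
  per-plate minimum calculated concentration, above-range the maximum;
  duplicate wells averaged; analytes with >10% out-of-range flagged);
* metabolite zero replacement (Uniform(0, 0.5 x min nonzero)) and
  per-sample median normalization to the global median;
* linear-model covariate adjustment that removes nuisance terms (age, sex,
  source) while protecting the karyotype contrast.

Quantiles use linear interpolation between order statistics (the "type 7"
convention). Missing values propagate; nothing outside the immunoassay
rule is imputed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg
from sklearn.base import BaseEstimator, TransformerMixin

from .synthetic import AnalytePanel

__all__ = [
    "OutlierMask",
    "ExtremeOutlierFilter",
    "MetaboliteNormalizer",
    "CovariateAdjuster",
    "exclude_extreme_outliers",
    "resolve_out_of_range",
    "normalize_metabolites",
    "adjust_covariates",
]


class OutlierMask:
    """Boolean exclusion flags plus the per-stratum fence statistics."""

    def __init__(self, mask: pd.DataFrame, fences: pd.DataFrame):
        self.mask = mask          # analyte x sample bool, True = excluded
        self.fences = fences      # rows (analyte, stratum): Q1, Q3, IQR, lower, upper

    def apply(self, values: pd.DataFrame) -> pd.DataFrame:
        """Excluded values become missing downstream."""
        return values.mask(self.mask)


def exclude_extreme_outliers(
    values: pd.DataFrame,
    strata: pd.Series,
    k: float = 3.0,
    min_stratum: int = 4,
) -> OutlierMask:
    """Flag values beyond Q1 - k*IQR or Q3 + k*IQR within each stratum.

    ``values`` is analyte x sample; ``strata`` maps sample -> karyotype (or
    any grouping). Fences are computed once from all non-missing values of
    the stratum (single pass). Strata with fewer than ``min_stratum``
    non-missing values are left untouched with a warning.
    """
    missing = set(values.columns) - set(strata.index)
    if missing:
        raise ValueError(f"samples without stratum label: {sorted(missing)[:5]}")
    strata = strata.loc[values.columns]

    mask = pd.DataFrame(False, index=values.index, columns=values.columns)
    rows = []
    for stratum in pd.unique(strata):
        cols = values.columns[(strata == stratum).to_numpy()]
        block = values[cols]
        n_ok = block.notna().sum(axis=1)
        q1 = block.quantile(0.25, axis=1, interpolation="linear")
        q3 = block.quantile(0.75, axis=1, interpolation="linear")
        iqr = q3 - q1
        lower, upper = q1 - k * iqr, q3 + k * iqr
        flag = block.lt(lower, axis=0) | block.gt(upper, axis=0)
        small = n_ok < min_stratum
        if small.any():
            warnings.warn(
                f"{int(small.sum())} analyte(s) have < {min_stratum} values in "
                f"stratum {stratum!r}; no exclusion applied there"
            )
            flag.loc[small] = False
        mask.loc[:, cols] = flag
        rows.append(pd.DataFrame({
            "analyte": values.index, "stratum": stratum,
            "Q1": q1.to_numpy(), "Q3": q3.to_numpy(), "IQR": iqr.to_numpy(),
            "lower": lower.to_numpy(), "upper": upper.to_numpy(),
        }))
    fences = pd.concat(rows, ignore_index=True)
    return OutlierMask(mask=mask, fences=fences)


class ExtremeOutlierFilter(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper: fit learns the fences, transform masks.

    Parameters
    ----------
    k : fence multiplier on the IQR (3 = "extreme" outliers).
    min_stratum : minimum non-missing values per stratum to act at all.
    """

    def __init__(self, k: float = 3.0, min_stratum: int = 4):
        self.k = k
        self.min_stratum = min_stratum

    def fit(self, X: pd.DataFrame, strata: pd.Series):
        self.mask_ = exclude_extreme_outliers(X, strata, k=self.k,
                                              min_stratum=self.min_stratum)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.mask_.apply(X)


def resolve_out_of_range(
    panel: AnalytePanel,
    flag_fraction: float = 0.10,
) -> tuple[AnalytePanel, list[str]]:
    """Resolve immunoassay fit-range misses and average duplicate wells.

    Below-range values are replaced by the minimum in-range calculated
    concentration of that analyte on the same plate, above-range values by
    the maximum; duplicate wells of a sample are then averaged. Analytes
    with more than ``flag_fraction`` of their values out of range are
    returned in the flag list. In-range values pass through bit-identical.
    """
    if panel.platform != "immunoassay":
        raise ValueError("resolve_out_of_range applies to the immunoassay platform")
    if panel.plate_ids is None or panel.range_flags is None or panel.well_samples is None:
        raise ValueError("immunoassay panel needs plate IDs, range flags and well->sample map")

    values = panel.values.copy()
    flags = panel.range_flags
    plates = panel.plate_ids

    oor = flags.isin(["below_range", "above_range"])
    measured = flags.ne("missing")
    with np.errstate(invalid="ignore"):
        frac = oor.sum(axis=1) / measured.sum(axis=1).replace(0, np.nan)
    flagged = list(values.index[frac > flag_fraction])

    for plate in pd.unique(plates):
        cols = values.columns[(plates == plate).to_numpy()]
        block = values[cols]
        lo = block.min(axis=1)
        hi = block.max(axis=1)
        sub = flags[cols]
        all_out = block.isna().all(axis=1) & sub.isin(["below_range", "above_range"]).any(axis=1)
        if all_out.any():
            warnings.warn(
                f"analyte(s) {list(values.index[all_out])} entirely out of range "
                f"on {plate}; left missing"
            )
        below = sub.eq("below_range")
        above = sub.eq("above_range")
        filled = block.where(~below, lo, axis=0).where(~above, hi, axis=0)
        values.loc[:, cols] = filled

    # average duplicate wells into per-sample columns (stable sample order)
    sample_order = pd.unique(panel.well_samples)
    averaged = values.T.groupby(panel.well_samples, sort=False).mean().T
    averaged = averaged[sample_order]
    sample_plates = plates.groupby(panel.well_samples, sort=False).first()[sample_order]
    out = AnalytePanel(values=averaged, platform="immunoassay",
                       plate_ids=sample_plates)
    return out, flagged


def normalize_metabolites(panel: AnalytePanel, seed: int) -> AnalytePanel:
    """Replace zero intensities and median-normalize each sample.

    Zeros become Uniform(0, 0.5 x min nonzero intensity of that metabolite),
    reproducibly from ``seed``; each sample is then scaled by
    (global median intensity over all values) / (sample median), so every
    sample's median equals the global median afterwards. All-zero
    metabolites are left missing with a warning. A zero-free matrix whose
    sample medians already equal the global median passes through unchanged.
    """
    if panel.platform != "metabolomics":
        raise ValueError("normalize_metabolites applies to the metabolomics platform")
    values = panel.values.copy().astype(float)
    if (values < 0).any().any():
        raise ValueError("metabolite intensities must be >= 0")

    rng = np.random.default_rng(seed)
    zero = values.eq(0.0)
    all_zero = zero.all(axis=1)
    if all_zero.any():
        warnings.warn(f"all-zero metabolite(s) left missing: {list(values.index[all_zero])}")
        values.loc[all_zero] = np.nan
        zero.loc[all_zero] = False
    for met in values.index[zero.any(axis=1)]:
        row = values.loc[met]
        min_nonzero = row[row > 0].min()
        idx = zero.loc[met]
        values.loc[met, idx] = rng.uniform(0.0, 0.5 * min_nonzero, size=int(idx.sum()))

    global_median = np.nanmedian(values.to_numpy())
    sample_median = values.median(axis=0)
    if (sample_median <= 0).any():
        raise ValueError("sample(s) with non-positive median intensity cannot be scaled")
    scaled = values.mul(global_median / sample_median, axis=1)
    return AnalytePanel(values=scaled, platform="metabolomics")


class MetaboliteNormalizer(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper over :func:`normalize_metabolites`."""

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X: AnalytePanel, y=None):
        return self

    def transform(self, X: AnalytePanel) -> AnalytePanel:
        return normalize_metabolites(X, seed=self.seed)


def _design(metadata: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept + dummy-coded design for the named metadata columns."""
    cols, names = [np.ones(len(metadata))], ["intercept"]
    for term in terms:
        v = metadata[term]
        if pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(float))
            names.append(term)
        else:
            levels = sorted(pd.unique(v.astype(str)))
            for lvl in levels[1:]:
                cols.append((v.astype(str) == lvl).to_numpy(float))
                names.append(f"{term}[{lvl}]")
    return np.column_stack(cols), names


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # QR with pivoting points at the dependent columns
        _, r, piv = scipy.linalg.qr(X, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        bad += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def adjust_covariates(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    nuisance: tuple[str, ...] = ("age", "sex", "source"),
    protect: tuple[str, ...] = ("karyotype",),
) -> pd.DataFrame:
    """Remove nuisance covariate contributions from a feature x sample matrix.

    Per feature, a linear model with nuisance and protected terms is fit
    jointly and only the fitted nuisance contributions (computed from
    mean-centered nuisance columns, so the overall level is kept) are
    subtracted. Protected effects — by default the karyotype contrast the
    analyses care about — survive adjustment intact, mirroring batch-effect
    removal with a protected design. Missing feature values are ignored in
    the fit and stay missing. Idempotent up to floating error.
    """
    samples = list(features.columns)
    meta = metadata.loc[samples]
    if meta[list(nuisance) + list(protect)].isna().any().any():
        raise ValueError("covariates contain missing values")
    X_full, names = _design(meta, list(protect) + list(nuisance))
    _check_full_rank(X_full, names)
    nuis_idx = [i for i, nm in enumerate(names)
                if any(nm == t or nm.startswith(f"{t}[") for t in nuisance)]

    Y = features.to_numpy(float)
    out = Y.copy()
    finite = np.isfinite(Y)
    X_nuis_centered = X_full[:, nuis_idx] - X_full[:, nuis_idx].mean(axis=0)
    if finite.all():
        beta, *_ = np.linalg.lstsq(X_full, Y.T, rcond=None)
        out = Y - (X_nuis_centered @ beta[nuis_idx, :]).T
    else:
        for i in range(Y.shape[0]):
            ok = finite[i]
            if ok.sum() <= X_full.shape[1]:
                continue
            beta, *_ = np.linalg.lstsq(X_full[ok], Y[i, ok], rcond=None)
            out[i, ok] = Y[i, ok] - X_nuis_centered[ok] @ beta[nuis_idx]
    return pd.DataFrame(out, index=features.index, columns=features.columns)


class CovariateAdjuster(BaseEstimator, TransformerMixin):
    """sklearn-style wrapper over :func:`adjust_covariates`.

    fit stores the metadata; transform adjusts any feature matrix over the
    same samples.
    """

    def __init__(self, nuisance: tuple[str, ...] = ("age", "sex", "source"),
                 protect: tuple[str, ...] = ("karyotype",)):
        self.nuisance = nuisance
        self.protect = protect

    def fit(self, metadata: pd.DataFrame, y=None):
        self.metadata_ = metadata
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        return adjust_covariates(features, self.metadata_,
                                 nuisance=self.nuisance, protect=self.protect)
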