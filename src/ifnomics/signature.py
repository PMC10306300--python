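"""ISG signature derivation.

Differential expression of T21 vs euploid control whole blood, then a
four-way filter: linear fold change at least ``fc_min`` (elevated only),
BH-adjusted ``q < q_max``, annotated interferon-stimulated gene, and not on
the excluded chromosome (chr21, whose ISGs rise with gene dosage rather
than downstream IFN signaling).

The differential test is a per-gene Gaussian linear model on
log2(RPKM + 0.5) with karyotype + age + sex terms and a Wald test on the
karyotype coefficient; the karyotype coefficient is the log2 fold change.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import _check_full_rank, _design

__all__ = ["DifferentialResult", "SignatureDefinition",
           "differential_expression", "select_isg_signature"]

#: fold-change presets loosening the signature to larger ISG panels
SIGNATURE_PRESETS = {"strict": 1.5, "intermediate": 1.2, "broad": 1.0}


@dataclass
class SignatureDefinition:
    """A selected ISG list plus the thresholds that produced it."""

    genes: list[str]
    fc_min: float = 1.5
    q_max: float = 0.1
    excluded_chrom: str = "chr21"
    log2fc: dict[str, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"gene": self.genes,
                           "log2fc": [self.log2fc.get(g, np.nan) for g in self.genes]})
        df.to_csv(path, sep="\t", index=False)
        with open(str(path) + ".json", "w") as fh:
            json.dump({"fc_min": self.fc_min, "q_max": self.q_max,
                       "excluded_chrom": self.excluded_chrom,
                       "n_genes": len(self.genes)}, fh, indent=2)

    @classmethod
    def from_tsv(cls, path, **thresholds) -> "SignatureDefinition":
        df = pd.read_csv(path, sep="\t")
        return cls(genes=list(df["gene"]),
                   log2fc=dict(zip(df["gene"], df["log2fc"])), **thresholds)


def differential_expression(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex"),
    group: str = "karyotype",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-gene linear-model differential expression, T21 vs control.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (the group
    coefficient), ``p`` (two-sided Wald) and ``q`` (BH across genes).
    Zero-variance genes get missing p and are excluded from the BH
    denominator.
    """
    samples = list(expr.columns)
    meta = metadata.loc[samples]
    groups = pd.unique(meta[group])
    if len(groups) < 2:
        raise ValueError("both karyotype groups must be present")
    if (expr.to_numpy() < 0).any():
        raise ValueError("expression must be nonnegative")

    X, names = _design(meta, [group] + list(covariates))
    _check_full_rank(X, names)
    # group coefficient: T21 level if present, else the first non-reference level
    gcols = [i for i, nm in enumerate(names) if nm.startswith(f"{group}[")]
    if not gcols:
        raise ValueError(f"{group} has a single level")
    t21 = [i for i in gcols if names[i] == f"{group}[T21]"]
    gi = t21[0] if t21 else gcols[0]
    sign = 1.0
    if not t21 and "T21" in groups:
        # reference level is T21: flip the contrast so log2fc is T21/control
        sign = -1.0

    Y = np.log2(expr.to_numpy(float) + pseudocount)
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y.T                      # p x genes
    resid = Y.T - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * XtX_inv[gi, gi])
    log2fc = sign * beta[gi]

    zero_var = Y.var(axis=1) == 0
    pvals = np.full(Y.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, np.inf * np.sign(log2fc))
    ok = ~zero_var & (se > 0)
    pvals[ok] = 2 * stats.t.sf(np.abs(t[ok]), dof)
    log2fc = np.where(zero_var, 0.0, log2fc)

    q = np.full_like(pvals, np.nan)
    if ok.any():
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": log2fc, "p": pvals, "q": q}, index=expr.index)


def select_isg_signature(
    de: pd.DataFrame,
    annotations: pd.DataFrame,
    fc_min: float = 1.5,
    q_max: float = 0.1,
    excluded_chrom: str = "chr21",
) -> SignatureDefinition:
    """Filter the differential result down to the score signature.

    Keeps genes with linear fold change >= ``fc_min`` (elevated only),
    ``q < q_max``, an ISG annotation, and a chromosome other than
    ``excluded_chrom``; the result is sorted by gene ID and therefore
    invariant to input ordering.
    """
    ann = annotations.loc[de.index]
    fc = 2.0 ** de["log2fc"]
    keep = (
        (fc >= fc_min)
        & (de["q"] < q_max)
        & ann["is_isg"].astype(bool)
        & (ann["chrom"] != excluded_chrom)
    )
    genes = sorted(de.index[keep.fillna(False)])
    if not genes:
        warnings.warn("signature selection returned no genes")
    return SignatureDefinition(
        genes=genes, fc_min=fc_min, q_max=q_max, excluded_chrom=excluded_chrom,
        log2fc={g: float(de.loc[g, "log2fc"]) for g in genes},
    )
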