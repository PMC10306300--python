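"""Per-sample interferon (IFN) scores and derived metabolic metrics.

The IFN score of a sample is the sum over signature genes of z-scores
computed against the euploid-control mean and sample SD of
covariate-adjusted expression. By construction the control cohort has mean
score 0 and per-gene z SD 1, a hypothetical sample sitting at the control
mean of every gene scores 0, and one sitting +1 control-SD on all genes
scores exactly the signature size.

Scores default to the log2(RPKM + pseudocount) adjusted scale; a linear
switch is provided because linear-scale SDs are dominated by high-abundance
outliers.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .signature import SignatureDefinition
from .synthetic import AnalytePanel

__all__ = ["ReferenceStats", "reference_stats", "compute_ifn_score",
           "IFNScorer", "kyn_trp_ratio"]


@dataclass
class ReferenceStats:
    """Per-signature-gene control mean and SD (sample SD, n-1)."""

    mean: pd.Series
    sd: pd.Series
    n_controls: int
    dropped: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"mean": self.mean.to_dict(), "sd": self.sd.to_dict(),
                       "n_controls": self.n_controls, "dropped": self.dropped},
                      fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ReferenceStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(mean=pd.Series(d["mean"]), sd=pd.Series(d["sd"]),
                   n_controls=d["n_controls"], dropped=d["dropped"])


def reference_stats(
    adjusted_expr: pd.DataFrame,
    control_ids: list[str],
    signature: SignatureDefinition,
) -> ReferenceStats:
    """Control mean and sample SD per signature gene.

    Uses only the listed control samples; zero-SD genes are dropped with a
    warning and recorded so the score's gene count is explicit.
    """
    if len(control_ids) < 2:
        raise ValueError("need at least 2 control samples for reference stats")
    missing = [g for g in signature.genes if g not in adjusted_expr.index]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    block = adjusted_expr.loc[signature.genes, list(control_ids)]
    mean = block.mean(axis=1)
    sd = block.std(axis=1, ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        warnings.warn(f"dropped zero-SD signature gene(s): {dropped}")
        mean, sd = mean.drop(dropped), sd.drop(dropped)
    return ReferenceStats(mean=mean, sd=sd, n_controls=len(control_ids),
                          dropped=dropped)


def compute_ifn_score(
    adjusted_expr: pd.DataFrame,
    signature: SignatureDefinition,
    ref: ReferenceStats,
) -> pd.DataFrame:
    """Sum of per-gene z-scores against the control reference.

    Any sample on the same adjusted scale may be scored, including external
    or longitudinal draws scored against a frozen reference.
    """
    genes = list(ref.mean.index)
    missing = [g for g in genes if g not in adjusted_expr.index]
    if missing:
        raise KeyError(f"signature genes missing from matrix: {missing}")
    block = adjusted_expr.loc[genes]
    z = block.sub(ref.mean, axis=0).div(ref.sd, axis=0)
    scores = z.sum(axis=0)
    return pd.DataFrame({"ifn_score": scores, "n_genes": len(genes)})


class IFNScorer(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: fit freezes control reference stats,
    transform scores any expression matrix on the same adjusted scale.

    Parameters
    ----------
    signature : the selected ISG list.
    log_scale : compute z-scores on log2(x + pseudocount) (default) or on
        the linear scale.
    pseudocount : added before the log2 when ``log_scale``.
    """

    def __init__(self, signature: SignatureDefinition | None = None,
                 log_scale: bool = True, pseudocount: float = 0.5):
        self.signature = signature
        self.log_scale = log_scale
        self.pseudocount = pseudocount

    def _scale(self, expr: pd.DataFrame) -> pd.DataFrame:
        if self.log_scale:
            return np.log2(expr + self.pseudocount)
        return expr

    def fit(self, adjusted_expr: pd.DataFrame, control_ids: list[str]):
        if self.signature is None:
            raise ValueError("IFNScorer needs a signature")
        self.reference_ = reference_stats(self._scale(adjusted_expr),
                                          list(control_ids), self.signature)
        return self

    def transform(self, expr: pd.DataFrame) -> pd.DataFrame:
        return compute_ifn_score(self._scale(expr), self.signature, self.reference_)


def kyn_trp_ratio(
    metabolites: AnalytePanel | pd.DataFrame,
    kynurenine: str = "kynurenine",
    tryptophan: str = "tryptophan",
) -> pd.Series:
    """Kynurenine / tryptophan per sample — an index of IDO1-driven,
    interferon-inducible tryptophan catabolism.

    Missing if either metabolite is missing; non-positive tryptophan gives
    a missing ratio with a warning. Invariant to any common per-sample
    scaling, so it can be taken before or after median normalization.
    """
    values = metabolites.values if isinstance(metabolites, AnalytePanel) else metabolites
    for m in (kynurenine, tryptophan):
        if m not in values.index:
            raise KeyError(f"metabolite {m!r} not in panel")
    kyn = values.loc[kynurenine].astype(float)
    trp = values.loc[tryptophan].astype(float)
    bad = trp.notna() & (trp <= 0)
    if bad.any():
        warnings.warn(f"non-positive tryptophan in {int(bad.sum())} sample(s); ratio missing")
    ratio = kyn / trp.where(trp > 0)
    ratio.name = "kyn_trp_ratio"
    return ratio
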