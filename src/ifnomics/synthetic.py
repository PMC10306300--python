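"""Synthetic multi-omics cohort generator.

Emulates a trisomy 21 (T21) vs euploid whole-blood cohort with a latent
per-individual interferon (IFN) activity variable driving every layer:

* gene expression (RPKM-like) with a ~1.5x chromosome-21 dosage effect and
  interferon-stimulated genes (ISGs) induced proportionally to latent
  activity;
* three plasma analyte panels (proteomics relative fluorescence,
  immunoassay pg/ml with plates / duplicate wells / fit-range flags,
  metabolite intensities with a configurable zero fraction);
* immune-cell-cluster relative frequencies (logistic-normal, per-cluster
  logit slopes on latent activity);
* clinical condition flags whose log-odds load on latent activity;
* one longitudinal subject with on-drug and off-drug blood draws.

The latent activity is the unobserved quantity the IFN score estimates; it
is returned for truth-recovery tests and never consumed by analysis stages.
Expression is generated on the log2 scale (Gaussian noise) and
exponentiated, so configured effects are multiplicative fold changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "Cohort",
    "LatentState",
    "LongitudinalSeries",
    "generate_cohort",
    "generate_longitudinal_subject",
    "default_immunoassay_names",
    "default_cell_cluster_names",
    "default_condition_names",
]

# immune factors measured on multiplexed electrochemiluminescence panels
_IMMUNOASSAY_CORE = [
    "IFNG", "IFNL1", "IFNA2", "IFNB1", "IP10", "TNFa", "IL6", "CRP",
    "SAA", "MIP1a", "MIP3a", "TSLP", "VEGFC", "IL10", "IL1b", "IL8",
]

_CELL_CLUSTERS = [
    "CD8_TEM", "CD8_naive", "CD4_TCM", "CD4_naive", "B_cells",
    "B_CD27pos", "NK_cells", "basophils", "classical_monocytes",
    "nonclassical_monocytes", "mDC_CD1c", "pDC", "Tregs", "gdT",
    "PMN_MDSC", "eosinophil_like", "NKT", "CD8_TCM", "CD4_TEM",
    "plasmablasts",
]

_CONDITIONS = [
    "congenital_heart_defect", "autoimmune_thyroid_disease",
    "alopecia_areata", "celiac_disease", "obstructive_sleep_apnea",
    "recurrent_otitis_media", "obesity", "anxiety", "seizure_disorder",
    "asthma", "gerd", "eczema",
]

_METABOLITE_CORE = ["kynurenine", "tryptophan", "quinolinic_acid", "serotonin_5HIAA"]


def default_immunoassay_names(n: int) -> list[str]:
    extra = [f"CYT{i:03d}" for i in range(n - len(_IMMUNOASSAY_CORE))]
    return (_IMMUNOASSAY_CORE + extra)[:n]


def default_cell_cluster_names(n: int) -> list[str]:
    extra = [f"cluster_{i:02d}" for i in range(n - len(_CELL_CLUSTERS))]
    return (_CELL_CLUSTERS + extra)[:n]


def default_condition_names(n: int) -> list[str]:
    extra = [f"condition_{i:02d}" for i in range(n - len(_CONDITIONS))]
    return (_CONDITIONS + extra)[:n]


def _default_analyte_effects() -> dict[str, float]:
    return {
        "IP10": 0.40, "IFNG": 0.35, "IFNL1": 0.35, "TNFa": 0.30,
        "IL6": 0.30, "CRP": 0.25, "SAA": 0.25,
        "PROT0001": 0.35, "PROT0002": 0.30, "PROT0003": -0.25,
        "kynurenine": 0.30, "quinolinic_acid": 0.25, "tryptophan": -0.20,
    }


def _default_cell_effects() -> dict[str, float]:
    return {
        "CD8_TEM": 0.30, "CD8_naive": -0.30, "CD4_naive": -0.25,
        "B_cells": -0.25, "nonclassical_monocytes": 0.25, "basophils": 0.20,
    }


def _default_condition_enrichment() -> dict[str, float]:
    return {
        "congenital_heart_defect": 0.6,
        "autoimmune_thyroid_disease": 0.6,
        "alopecia_areata": 0.5,
    }


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Effects are slopes on the standardized latent IFN activity: gene/analyte
    effects act on the log2 scale (a slope b means a 2**b fold change per
    latent unit), cell-cluster effects on the logit scale, condition
    enrichments on the log-odds scale.
    """

    n_t21: int = 300
    n_control: int = 100
    n_genes: int = 2000
    n_chr21_genes: int = 120
    n_isg_true: int = 18          # planted signature size
    n_isg_null: int = 30          # ISG-annotated but not induced
    n_isg_chr21: int = 3          # induced ISGs on chr21 (must be excluded)
    dosage_fold: float = 1.5      # chr21 multiplicative dosage effect in T21
    isg_effect: float = 0.5       # log2 expression slope per latent unit
    latent_shift: float = 2.0     # T21 mean latent activity minus control mean
    latent_sd: float = 1.0
    expr_noise_sd: float = 0.5    # log2-scale residual SD
    n_proteins: int = 60
    n_immunoassay: int = 54
    n_metabolites: int = 80
    n_cell_clusters: int = 20
    n_conditions: int = 12
    analyte_effects: dict[str, float] = field(default_factory=_default_analyte_effects)
    cell_cluster_effects: dict[str, float] = field(default_factory=_default_cell_effects)
    condition_enrichment: dict[str, float] = field(default_factory=_default_condition_enrichment)
    analyte_noise_sd: float = 0.4
    cell_noise_sd: float = 0.3
    condition_baseline: float = -1.5   # log-odds intercept of condition flags
    immunoassay_oor_fraction: float = 0.03
    metabolite_zero_fraction: float = 0.02
    n_plates: int = 4
    age_mean: float = 25.0
    age_sd: float = 10.0
    sex_female_prob: float = 0.5
    sources: tuple[str, ...] = ("siteA", "siteB")
    source_probs: tuple[float, ...] = (0.6, 0.4)
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_t21": self.n_t21, "n_control": self.n_control,
            "n_genes": self.n_genes, "n_chr21_genes": self.n_chr21_genes,
            "n_isg_true": self.n_isg_true, "n_isg_null": self.n_isg_null,
            "n_isg_chr21": self.n_isg_chr21,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_isg_true + self.n_isg_null > self.n_genes - self.n_chr21_genes:
            raise ValueError(
                "n_isg_true + n_isg_null exceeds the number of non-chr21 genes"
            )
        if self.n_isg_chr21 > self.n_chr21_genes:
            raise ValueError("n_isg_chr21 exceeds n_chr21_genes")
        for name in ("dosage_fold",):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("latent_sd", "expr_noise_sd", "analyte_noise_sd", "cell_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.immunoassay_oor_fraction < 1:
            raise ValueError("immunoassay_oor_fraction must be in [0, 1)")
        if not 0 <= self.metabolite_zero_fraction < 1:
            raise ValueError("metabolite_zero_fraction must be in [0, 1)")

    def replace(self, **kw) -> "CohortConfig":
        return dataclasses.replace(self, **kw)

    def null(self, **kw) -> "CohortConfig":
        """A copy with every effect switched off: no latent-driven
        induction, no chr21 dosage, no analyte/cell/condition loading."""
        return self.replace(
            isg_effect=0.0, latent_shift=0.0, latent_sd=0.0, dosage_fold=1.0,
            analyte_effects={}, cell_cluster_effects={},
            condition_enrichment={}, **kw,
        )


@dataclass
class LatentState:
    """Per-sample latent IFN activity plus the planted truth.

    Consumed only by truth-recovery tests; analysis stages never see it.
    """

    activity: pd.Series
    planted_isgs: list[str]
    null_isgs: list[str]
    chr21_isgs: list[str]

    def to_dict(self) -> dict:
        return {
            "activity": self.activity.round(10).to_dict(),
            "planted_isgs": self.planted_isgs,
            "null_isgs": self.null_isgs,
            "chr21_isgs": self.chr21_isgs,
        }


@dataclass
class AnalytePanel:
    """Analyte x sample panel with platform-specific side information.

    ``values`` rows are analytes, columns samples (or wells for the
    immunoassay platform before duplicate averaging). ``range_flags`` uses
    {"in_range", "below_range", "above_range", "missing"}; below/above flags
    occur only on the immunoassay platform, where flagged values are missing
    until :func:`ifnomics.preprocess.resolve_out_of_range` fills them in.
    """

    values: pd.DataFrame
    platform: str
    plate_ids: pd.Series | None = None          # per column
    range_flags: pd.DataFrame | None = None     # same shape as values
    well_samples: pd.Series | None = None       # well -> sample (immunoassay)

    def __post_init__(self):
        if self.platform not in {"proteomics", "immunoassay", "metabolomics"}:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.range_flags is not None and self.platform != "immunoassay":
            bad = self.range_flags.isin(["below_range", "above_range"]).any().any()
            if bad:
                raise ValueError("fit-range flags are only valid on the immunoassay platform")

    def copy(self) -> "AnalytePanel":
        return AnalytePanel(
            values=self.values.copy(),
            platform=self.platform,
            plate_ids=None if self.plate_ids is None else self.plate_ids.copy(),
            range_flags=None if self.range_flags is None else self.range_flags.copy(),
            well_samples=None if self.well_samples is None else self.well_samples.copy(),
        )


@dataclass
class Cohort:
    """All layers of one synthetic cohort, sharing sample IDs."""

    expression: pd.DataFrame            # gene x sample, RPKM-like
    gene_annotation: pd.DataFrame       # gene, chrom, is_isg
    proteomics: AnalytePanel
    immunoassay: AnalytePanel
    metabolites: AnalytePanel
    cell_frequencies: pd.DataFrame      # cluster x sample, sums to 1
    metadata: pd.DataFrame              # sample x (karyotype, age, sex, source, conditions)
    latent: LatentState
    config: CohortConfig


@dataclass
class LongitudinalSeries:
    """Ordered blood draws of one subject with on/off treatment labels."""

    expression: pd.DataFrame        # gene x draw
    status: pd.Series               # draw -> "on" | "off"
    timepoints: pd.Series           # draw -> float (months)
    subject_id: str
    latent_off: float               # subject's untreated latent activity

    def __post_init__(self):
        bad = set(self.status) - {"on", "off"}
        if bad:
            raise ValueError(f"invalid treatment statuses: {sorted(bad)}")


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw one cross-sectional multi-omics cohort.

    All randomness flows from ``config.seed`` through named per-layer
    substreams, so identical configs give byte-identical cohorts and adding
    a layer-specific parameter never perturbs other layers.
    """
    config.validate()
    if config.n_t21 == 0 or config.n_control == 0:
        raise ValueError("both karyotype groups need at least one sample")

    rng = _streams(config.seed, [
        "latent", "covariates", "expression", "proteomics",
        "immunoassay", "metabolites", "cells", "conditions",
    ])

    n = config.n_t21 + config.n_control
    samples = [f"S{i:04d}" for i in range(n)]
    karyotype = np.array(["T21"] * config.n_t21 + ["control"] * config.n_control)

    # latent IFN activity: elevated but overlapping in T21
    mu = np.where(karyotype == "T21", config.latent_shift, 0.0)
    activity = mu + rng["latent"].normal(0.0, config.latent_sd, size=n)

    # covariates
    age = np.clip(rng["covariates"].normal(config.age_mean, config.age_sd, size=n), 1, 80)
    sex = np.where(rng["covariates"].random(n) < config.sex_female_prob, "female", "male")
    source = rng["covariates"].choice(config.sources, size=n, p=config.source_probs)

    genes, annotation, expr = _expression_layer(config, rng["expression"], activity, karyotype, samples)
    latent = LatentState(
        activity=pd.Series(activity, index=samples, name="latent_activity"),
        planted_isgs=list(annotation.index[annotation["planted"]]),
        null_isgs=list(annotation.index[annotation["is_isg"] & ~annotation["planted"]
                                        & (annotation["chrom"] != "chr21")]),
        chr21_isgs=list(annotation.index[annotation["is_isg"] & (annotation["chrom"] == "chr21")]),
    )

    prot_names = [f"PROT{i:04d}" for i in range(1, config.n_proteins + 1)]
    cyt_names = default_immunoassay_names(config.n_immunoassay)
    met_names = (_METABOLITE_CORE + [f"MET{i:03d}" for i in range(config.n_metabolites)])[: config.n_metabolites]
    cluster_names = default_cell_cluster_names(config.n_cell_clusters)
    condition_names = default_condition_names(config.n_conditions)

    known = set(prot_names) | set(cyt_names) | set(met_names)
    unknown = set(config.analyte_effects) - known
    if unknown:
        raise ValueError(f"analyte_effects name unknown analytes: {sorted(unknown)}")
    unknown = set(config.cell_cluster_effects) - set(cluster_names)
    if unknown:
        raise ValueError(f"cell_cluster_effects name unknown clusters: {sorted(unknown)}")
    unknown = set(config.condition_enrichment) - set(condition_names)
    if unknown:
        raise ValueError(f"condition_enrichment name unknown conditions: {sorted(unknown)}")

    proteomics = _analyte_layer(config, rng["proteomics"], activity, samples,
                                prot_names, "proteomics", base_log2=(8, 14))
    immunoassay = _immunoassay_layer(config, rng["immunoassay"], activity, samples, cyt_names)
    metabolites = _metabolite_layer(config, rng["metabolites"], activity, samples, met_names)
    cells = _cell_layer(config, rng["cells"], activity, samples, cluster_names)

    meta = pd.DataFrame({
        "karyotype": karyotype, "age": age, "sex": sex, "source": source,
    }, index=pd.Index(samples, name="sample"))
    logit = config.condition_baseline + np.zeros((len(condition_names), n))
    for i, cond in enumerate(condition_names):
        logit[i] += config.condition_enrichment.get(cond, 0.0) * activity
    p = 1.0 / (1.0 + np.exp(-logit))
    flags = rng["conditions"].random((len(condition_names), n)) < p
    for i, cond in enumerate(condition_names):
        meta[cond] = flags[i]

    return Cohort(
        expression=expr, gene_annotation=annotation[["chrom", "is_isg"]],
        proteomics=proteomics, immunoassay=immunoassay, metabolites=metabolites,
        cell_frequencies=cells, metadata=meta, latent=latent, config=config,
    )


def _expression_layer(config, rng, activity, karyotype, samples):
    g = config.n_genes
    genes = [f"GENE{i:05d}" for i in range(1, g + 1)]
    chrom = np.array(["chr21"] * config.n_chr21_genes + ["other"] * (g - config.n_chr21_genes))
    planted = np.zeros(g, bool)
    planted[config.n_chr21_genes: config.n_chr21_genes + config.n_isg_true] = True
    is_isg = planted.copy()
    lo = config.n_chr21_genes + config.n_isg_true
    is_isg[lo: lo + config.n_isg_null] = True
    is_isg[: config.n_isg_chr21] = True  # induced ISGs sitting on chr21

    baseline = rng.uniform(2.0, 8.0, size=g)
    is_t21 = (karyotype == "T21").astype(float)
    dosage = np.log2(config.dosage_fold) * np.outer(chrom == "chr21", is_t21)
    induced = planted | (is_isg & (chrom == "chr21"))
    induction = config.isg_effect * np.outer(induced, activity)
    noise = rng.normal(0.0, config.expr_noise_sd, size=(g, len(samples)))
    log2_expr = baseline[:, None] + dosage + induction + noise
    expr = pd.DataFrame(2.0 ** log2_expr, index=pd.Index(genes, name="gene"), columns=samples)
    annotation = pd.DataFrame(
        {"chrom": chrom, "is_isg": is_isg, "planted": planted},
        index=pd.Index(genes, name="gene"),
    )
    return genes, annotation, expr


def _analyte_layer(config, rng, activity, samples, names, platform, base_log2):
    baseline = rng.uniform(*base_log2, size=len(names))
    slopes = np.array([config.analyte_effects.get(a, 0.0) for a in names])
    log2v = (baseline[:, None] + np.outer(slopes, activity)
             + rng.normal(0.0, config.analyte_noise_sd, size=(len(names), len(samples))))
    values = pd.DataFrame(2.0 ** log2v, index=pd.Index(names, name="analyte"), columns=samples)
    return AnalytePanel(values=values, platform=platform)


def _immunoassay_layer(config, rng, activity, samples, names):
    # two duplicate wells per sample; both land on the sample's plate
    n = len(samples)
    plates = [f"plate{1 + i % config.n_plates}" for i in range(n)]
    wells, well_sample, well_plate = [], [], []
    for s, pl in zip(samples, plates):
        for d in ("a", "b"):
            wells.append(f"{s}_{d}")
            well_sample.append(s)
            well_plate.append(pl)
    baseline = rng.uniform(-2.0, 8.0, size=len(names))  # log2 pg/ml
    slopes = np.array([config.analyte_effects.get(a, 0.0) for a in names])
    per_sample = baseline[:, None] + np.outer(slopes, activity) \
        + rng.normal(0.0, config.analyte_noise_sd, size=(len(names), n))
    well_noise = rng.normal(0.0, 0.05, size=(len(names), 2 * n))
    log2v = np.repeat(per_sample, 2, axis=1) + well_noise
    values = pd.DataFrame(2.0 ** log2v, index=pd.Index(names, name="analyte"), columns=wells)
    flags = pd.DataFrame("in_range", index=values.index, columns=values.columns)
    if config.immunoassay_oor_fraction > 0:
        # censor tails: lowest fraction below range, a thin upper tail above
        f = config.immunoassay_oor_fraction
        lo_q = values.quantile(f * 0.75, axis=1)
        hi_q = values.quantile(1 - f * 0.25, axis=1)
        below = values.lt(lo_q, axis=0)
        above = values.gt(hi_q, axis=0)
        flags = flags.mask(below, "below_range").mask(above, "above_range")
        values = values.mask(below | above)
    return AnalytePanel(
        values=values, platform="immunoassay",
        plate_ids=pd.Series(well_plate, index=wells, name="plate"),
        range_flags=flags,
        well_samples=pd.Series(well_sample, index=wells, name="sample"),
    )


def _metabolite_layer(config, rng, activity, samples, names):
    panel = _analyte_layer(config, rng, activity, samples, names,
                           "metabolomics", base_log2=(4, 16))
    values = panel.values
    if config.metabolite_zero_fraction > 0:
        # detection-limit censoring: lowest values per metabolite become 0
        thresh = values.quantile(config.metabolite_zero_fraction, axis=1)
        values = values.mask(values.lt(thresh, axis=0), 0.0)
    # never censor the named ratio metabolites entirely
    panel.values = values
    return panel


def _cell_layer(config, rng, activity, samples, cluster_names):
    k = len(cluster_names)
    base = rng.normal(0.0, 1.0, size=k)
    base -= base.mean()
    slopes = np.array([config.cell_cluster_effects.get(c, 0.0) for c in cluster_names])
    logits = base[:, None] + np.outer(slopes, activity) \
        + rng.normal(0.0, config.cell_noise_sd, size=(k, len(samples)))
    z = np.exp(logits - logits.max(axis=0, keepdims=True))
    freq = z / z.sum(axis=0, keepdims=True)
    return pd.DataFrame(freq, index=pd.Index(cluster_names, name="cluster"), columns=samples)


def _schedule(n_on: int, n_off: int) -> list[str]:
    """Interleave off draws evenly among on draws (off first, as untreated baseline)."""
    total = n_on + n_off
    statuses = ["on"] * total
    positions = np.linspace(0, total - 1, n_off).round().astype(int)
    for p in positions:
        statuses[p] = "off"
    # rounding collisions: push duplicates to the next free slot
    while statuses.count("off") < n_off:
        for i, s in enumerate(statuses):
            if s == "on":
                statuses[i] = "off"
                break
    return statuses


def generate_longitudinal_subject(
    config: CohortConfig,
    n_on: int = 7,
    n_off: int = 4,
    drug_effect: float = 0.8,
    subject_id: str = "LONG01",
    seed: int | None = None,
) -> LongitudinalSeries:
    """Simulate a high-activity T21 subject sampled on and off a JAK inhibitor.

    Off-drug draws are taken at the subject's (high) latent activity; on-drug
    draws shrink the ISG induction toward the euploid-control mean by the
    fraction ``drug_effect`` (0 = no effect, 1 = full normalization). The
    chr21 dosage effect is never touched by the drug.
    """
    config.validate()
    if n_on < 1 or n_off < 1:
        raise ValueError("need at least one draw in each treatment status")
    if not 0.0 <= drug_effect <= 1.0:
        raise ValueError(f"drug_effect must be in [0, 1], got {drug_effect}")

    rng = _streams(config.seed if seed is None else seed,
                   ["subject", "draws"])["draws"]
    # untreated activity in the upper T21 range
    latent_off = config.latent_shift + 1.5 * config.latent_sd

    g = config.n_genes
    genes = [f"GENE{i:05d}" for i in range(1, g + 1)]
    chrom = np.array(["chr21"] * config.n_chr21_genes + ["other"] * (g - config.n_chr21_genes))
    planted = np.zeros(g, bool)
    planted[config.n_chr21_genes: config.n_chr21_genes + config.n_isg_true] = True
    is_isg_chr21 = np.zeros(g, bool)
    is_isg_chr21[: config.n_isg_chr21] = True
    induced = planted | is_isg_chr21

    # the same per-gene baselines the cross-sectional generator would draw
    base_rng = _streams(config.seed, [
        "latent", "covariates", "expression", "proteomics",
        "immunoassay", "metabolites", "cells", "conditions",
    ])["expression"]
    baseline = base_rng.uniform(2.0, 8.0, size=g)

    statuses = _schedule(n_on, n_off)
    draws = [f"{subject_id}_d{i:02d}" for i in range(1, len(statuses) + 1)]
    log2 = np.empty((g, len(draws)))
    for j, status in enumerate(statuses):
        latent = latent_off * (1.0 - drug_effect) if status == "on" else latent_off
        mean = (baseline
                + np.log2(config.dosage_fold) * (chrom == "chr21")
                + config.isg_effect * latent * induced)
        log2[:, j] = mean + rng.normal(0.0, config.expr_noise_sd, size=g)
    expr = pd.DataFrame(2.0 ** log2, index=pd.Index(genes, name="gene"), columns=draws)
    months = np.arange(len(draws)) * 3.0
    return LongitudinalSeries(
        expression=expr,
        status=pd.Series(statuses, index=draws, name="status"),
        timepoints=pd.Series(months, index=draws, name="months"),
        subject_id=subject_id,
        latent_off=latent_off,
    )
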