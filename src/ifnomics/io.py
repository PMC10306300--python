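"""Tab-separated readers/writers for the pipeline's standard files.

Matrices are feature x sample TSVs with a one-line header of sample IDs;
flags live in sidecar TSVs; the synthetic truth (latent activity and
planted effects) goes to JSON so truth-recovery checks can run on disk
artifacts as well as in memory.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import AnalytePanel, Cohort

__all__ = ["read_matrix", "write_matrix", "write_cohort", "read_panel"]


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def read_panel(path, platform: str) -> AnalytePanel:
    values = read_matrix(path)
    plate_ids = range_flags = well_samples = None
    side = Path(str(path).removesuffix(".tsv") + ".flags.tsv")
    if side.exists():
        range_flags = read_matrix(side)
    side = Path(str(path).removesuffix(".tsv") + ".wells.tsv")
    if side.exists():
        wells = pd.read_csv(side, sep="\t", index_col=0)
        plate_ids = wells["plate"]
        well_samples = wells["sample"]
    return AnalytePanel(values=values, platform=platform, plate_ids=plate_ids,
                        range_flags=range_flags, well_samples=well_samples)


def write_panel(panel: AnalytePanel, path) -> None:
    write_matrix(panel.values, path)
    base = str(path).removesuffix(".tsv")
    if panel.range_flags is not None:
        write_matrix(panel.range_flags, base + ".flags.tsv")
    if panel.well_samples is not None:
        wells = pd.DataFrame({"sample": panel.well_samples,
                              "plate": panel.plate_ids})
        wells.index.name = "well"
        wells.to_csv(base + ".wells.tsv", sep="\t")


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write every layer of a synthetic cohort as pipeline input files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(cohort.expression, out / "expression.tsv")
    cohort.gene_annotation.to_csv(out / "gene_annotation.tsv", sep="\t")
    write_panel(cohort.proteomics, out / "proteomics.tsv")
    write_panel(cohort.immunoassay, out / "immunoassay.tsv")
    write_panel(cohort.metabolites, out / "metabolites.tsv")
    write_matrix(cohort.cell_frequencies, out / "cell_frequencies.tsv")
    cohort.metadata.to_csv(out / "metadata.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort.latent.to_dict(), fh, indent=2)
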