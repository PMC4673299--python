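"""Bundled published data: the top-30 differentially expressed probes.

A three-pair TNBC cohort (tumor samples C1-C3, patient-matched normals
N1-N3) was profiled on a combined lncRNA/mRNA microarray; the published
report prints the per-sample log2 intensities, absolute fold change,
t-test p value and regulation direction for the 30 most differential
lncRNA probes and the 30 most differential mRNA probes.  Those two
tables ship with the package as TSV files and serve as reference inputs
for desk-scale checks of the fold-change and clustering machinery.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_formats import DesignEntry, ExpressionMatrix, StudyDesign

SAMPLE_IDS = ["C1", "C2", "C3", "N1", "N2", "N3"]


def three_pair_design() -> StudyDesign:
    """The printed design: tumor C_i paired with normal N_i per patient."""
    entries = [DesignEntry(f"C{i}", f"patient{i}", "tumor") for i in (1, 2, 3)]
    entries += [DesignEntry(f"N{i}", f"patient{i}", "normal") for i in (1, 2, 3)]
    return StudyDesign(entries)


def _load(name: str) -> pd.DataFrame:
    with resources.files("lncoexp.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"probe_id": str})


def load_top30_lncrna() -> pd.DataFrame:
    """Published top-30 lncRNA table (per-sample log2 values + printed stats)."""
    return _load("tnbc_top30_lncrna.tsv")


def load_top30_mrna() -> pd.DataFrame:
    """Published top-30 mRNA table (per-sample log2 values + printed stats)."""
    return _load("tnbc_top30_mrna.tsv")


def as_expression_matrix(table: pd.DataFrame) -> ExpressionMatrix:
    """Per-sample columns of a bundled table as an all-present matrix."""
    values = table[SAMPLE_IDS].to_numpy(dtype=float)
    return ExpressionMatrix(table["probe_id"].tolist(), list(SAMPLE_IDS),
                            values, None)


def load_top30_lncrna_matrix() -> ExpressionMatrix:
    return as_expression_matrix(load_top30_lncrna())


def load_top30_mrna_matrix() -> ExpressionMatrix:
    return as_expression_matrix(load_top30_mrna())
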