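"""Relative qPCR quantification by the 2^-ddCt method.

Per patient, replicate Ct values are averaged, the target gene is
normalized to a reference gene (dCt = Ct_target - Ct_reference), the
tumor sample is calibrated against the patient-matched normal
(ddCt = dCt_tumor - dCt_normal), and relative expression is
fold = 2^-ddCt.  Patient-level folds are summarized as the median log2
fold with its standard error, and checked for direction agreement with
the microarray DE call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import logger


@dataclass(frozen=True)
class RelativeExpression:
    patient_id: str
    gene_id: str
    delta_delta_ct: float
    fold_change: float   # 2^-ddCt
    log2_fold: float     # -ddCt


def _rep_cols(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("ct_rep")]
    if not cols:
        raise ValueError("no ct_rep* columns in qPCR table")
    return cols


def _mean_ct(df: pd.DataFrame, patient: str, condition: str,
             gene: str) -> float | None:
    rows = df[(df["patient_id"] == patient) & (df["condition"] == condition)
              & (df["gene_id"] == gene)]
    if rows.empty:
        return None
    vals = rows[_rep_cols(df)].to_numpy(dtype=float).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return None
    return float(vals.mean())


def delta_delta_ct(measurements: pd.DataFrame, reference_gene: str,
                   target_gene: str) -> list[RelativeExpression]:
    """Per-patient relative expression of ``target_gene``.

    ``measurements`` follows the Ct-table layout of
    :func:`lncoexp.io_formats.read_qpcr_table`.  Patients missing the
    target or the reference in either condition are skipped with a
    logged warning.
    """
    out: list[RelativeExpression] = []
    for patient in measurements["patient_id"].drop_duplicates():
        cts = {}
        complete = True
        for condition in ("tumor", "normal"):
            for gene in (target_gene, reference_gene):
                ct = _mean_ct(measurements, patient, condition, gene)
                if ct is None:
                    logger.warning(
                        "patient %s: missing %s Ct for %s; skipped",
                        patient, condition, gene)
                    complete = False
                cts[(condition, gene)] = ct
        if not complete:
            continue
        dct_t = cts[("tumor", target_gene)] - cts[("tumor", reference_gene)]
        dct_n = cts[("normal", target_gene)] - cts[("normal", reference_gene)]
        ddct = dct_t - dct_n
        out.append(RelativeExpression(str(patient), target_gene, ddct,
                                      2.0 ** -ddct, -ddct))
    return out


def summarize_patients(results: list[RelativeExpression]
                       ) -> tuple[float, float, int]:
    """(median log2 fold, standard error, n) across patients.

    The standard error is sd(log2 fold)/sqrt(n); with a single patient
    it is reported as 0.
    """
    if not results:
        raise ValueError("no patient-level results to summarize")
    folds = np.array([r.log2_fold for r in results])
    n = len(folds)
    se = float(folds.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return float(np.median(folds)), se, n


def concordance_check(qpcr_summaries: dict[str, float],
                      de_table: pd.DataFrame) -> pd.DataFrame:
    """Direction agreement between qPCR and microarray per gene.

    ``qpcr_summaries`` maps gene_id -> median log2 fold; ``de_table``
    is indexed by probe_id with a ``regulation`` column.  Genes absent
    from either side are excluded with a logged warning.
    """
    rows = []
    for gene, log2_fold in qpcr_summaries.items():
        if gene not in de_table.index:
            logger.warning("gene %s absent from DE table; excluded", gene)
            continue
        array_dir = de_table.loc[gene, "regulation"]
        qpcr_dir = "up" if log2_fold > 0 else "down"
        rows.append((gene, log2_fold, qpcr_dir, array_dir,
                     qpcr_dir == array_dir))
    return pd.DataFrame(rows, columns=["gene_id", "qpcr_log2_fold",
                                       "qpcr_direction", "array_direction",
                                       "concordant"])
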