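"""Normalization and detection-flag filtering of expression matrices.

Quantile normalization forces every sample column onto the common
reference distribution (the across-sample mean of order statistics);
the flag filter keeps probes reliably detected ("P") in at least one of
the two conditions.
"""

from __future__ import annotations

import numpy as np

from .io_formats import ExpressionMatrix, StudyDesign


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize sample columns.

    Every column is mapped onto the reference distribution formed by
    averaging the columns' order statistics, so all columns share one
    sorted value vector afterwards while each column's internal ranking
    is preserved.  Ties within a column receive the mean of the
    reference values at the tied ranks, which keeps the map idempotent.
    Detection flags pass through unchanged.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError("cannot quantile-normalize an empty matrix")
    values = matrix.values
    reference = np.sort(values, axis=0).mean(axis=1)
    # cumulative means let a run of tied ranks [i, j) average to
    # (csum[j] - csum[i]) / (j - i) in O(1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(values)
    n = values.shape[0]
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j], kind="stable")
        col_sorted = values[order, j]
        mapped = reference.copy()
        i = 0
        while i < n:
            k = i + 1
            while k < n and col_sorted[k] == col_sorted[i]:
                k += 1
            if k - i > 1:
                mapped[i:k] = (csum[k] - csum[i]) / (k - i)
            i = k
        out[order, j] = mapped
    return ExpressionMatrix(list(matrix.probe_ids), list(matrix.sample_ids),
                            out, matrix.flags.copy())


def filter_by_flags(matrix: ExpressionMatrix, design: StudyDesign,
                    min_fraction: float = 1.0) -> ExpressionMatrix:
    """Keep probes detected in at least one condition.

    A probe is retained when, for tumor or for normal samples, the
    fraction of cells flagged "P" reaches ``min_fraction`` (default 1.0:
    every sample of that condition present).
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in [0, 1]")
    cols = {c: [matrix.sample_ids.index(s) for s in design.samples(c)]
            for c in ("tumor", "normal")}
    for cond, idx in cols.items():
        if not idx:
            raise ValueError(f"no {cond} samples in design")
    present = matrix.flags == "P"
    keep = np.zeros(matrix.shape[0], dtype=bool)
    for idx in cols.values():
        frac = present[:, idx].mean(axis=1)
        keep |= frac >= min_fraction
    kept = [p for p, k in zip(matrix.probe_ids, keep) if k]
    return ExpressionMatrix(kept, list(matrix.sample_ids),
                            matrix.values[keep], matrix.flags[keep])
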