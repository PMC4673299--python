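"""Fold change, t-tests, BH adjustment, DE calling and clustering.

Differential expression between tumor and normal follows the classic
microarray recipe: per-probe fold change on the log2 scale, a two-sided
t test (pooled-variance unpaired by default; Welch and paired variants
selectable), Benjamini-Hochberg q values reported alongside, and a call
at |FC| >= 2 and p <= 0.05.  The DE set is summarized by agglomerative
average-linkage clustering on 1 - Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix, StudyDesign, logger

T_TEST_MODES = ("pooled_unpaired", "welch", "paired")


def fold_change(matrix: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    """Per-probe group means and fold change on log2 values.

    Returns a frame indexed by probe_id with columns mean_tumor,
    mean_normal, log2fc (tumor - normal), fc_abs = 2^|log2fc| and
    regulation ("up" iff tumor mean exceeds normal mean).
    """
    t_idx = [matrix.sample_ids.index(s) for s in design.samples("tumor")]
    n_idx = [matrix.sample_ids.index(s) for s in design.samples("normal")]
    if not t_idx or not n_idx:
        raise ValueError("need at least one sample per condition")
    mean_t = matrix.values[:, t_idx].mean(axis=1)
    mean_n = matrix.values[:, n_idx].mean(axis=1)
    log2fc = mean_t - mean_n
    return pd.DataFrame({
        "mean_tumor": mean_t,
        "mean_normal": mean_n,
        "log2fc": log2fc,
        "fc_abs": 2.0 ** np.abs(log2fc),
        "regulation": np.where(log2fc > 0, "up", "down"),
    }, index=pd.Index(matrix.probe_ids, name="probe_id"))


def t_test(tumor_values: np.ndarray, normal_values: np.ndarray,
           mode: str = "pooled_unpaired") -> float:
    """Two-sided t-test p-value for one probe.

    ``pooled_unpaired`` assumes equal variances (df = n1 + n2 - 2),
    ``welch`` uses the Satterthwaite approximation, ``paired`` tests the
    mean of within-patient differences (inputs must be patient-aligned).
    Two identical constant groups yield p = 1 by convention.
    """
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(normal_values, dtype=float)
    if mode not in T_TEST_MODES:
        raise ValueError(f"unknown t-test mode {mode!r}")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 values per group")
    if mode == "paired":
        if len(x) != len(y):
            raise ValueError("paired mode needs equal, patient-aligned groups")
        d = x - y
        if np.ptp(d) == 0:
            return 1.0 if d[0] == 0 else 0.0
        p = stats.ttest_rel(x, y).pvalue
    else:
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            return 1.0 if x[0] == y[0] else 0.0
        p = stats.ttest_ind(x, y, equal_var=(mode == "pooled_unpaired")).pvalue
    return float(p)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.min(p) < 0 or np.max(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def differential_table(matrix: ExpressionMatrix, design: StudyDesign,
                       mode: str = "pooled_unpaired") -> pd.DataFrame:
    """Fold changes plus per-probe p and BH q for every probe."""
    fc = fold_change(matrix, design)
    t_idx = [matrix.sample_ids.index(s) for s in design.samples("tumor")]
    n_idx = [matrix.sample_ids.index(s) for s in design.samples("normal")]
    if mode == "paired":
        pairs = design.pairs()
        t_idx = [matrix.sample_ids.index(t) for _, t, _ in pairs]
        n_idx = [matrix.sample_ids.index(n) for _, _, n in pairs]
    pvals = np.array([
        t_test(matrix.values[i, t_idx], matrix.values[i, n_idx], mode)
        for i in range(matrix.shape[0])
    ])
    fc["p"] = pvals
    fc["q"] = bh_adjust(pvals)
    return fc


def call_differential(results: pd.DataFrame, fc_threshold: float = 2.0,
                      p_threshold: float = 0.05) -> pd.DataFrame:
    """Rows passing fc_abs >= fc_threshold and p <= p_threshold."""
    de = results[(results["fc_abs"] >= fc_threshold)
                 & (results["p"] <= p_threshold)]
    n_up = int((de["regulation"] == "up").sum())
    logger.info("DE call: %d probes (%d up, %d down)",
                len(de), n_up, len(de) - n_up)
    return de


@dataclass
class ClusterResult:
    """Agglomerative merge tree: scipy linkage matrix plus leaf order."""

    linkage: np.ndarray            # (n-1, 4) scipy format
    labels: list[str]
    leaf_order: list[int]

    def top_split(self) -> tuple[set[str], set[str]]:
        """Item labels of the two clusters below the final merge."""
        n = len(self.labels)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for step, (a, b, _, _) in enumerate(self.linkage):
            members[n + step] = members[int(a)] | members[int(b)]
        a, b = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        return ({self.labels[i] for i in members[a]},
                {self.labels[i] for i in members[b]})


def hierarchical_cluster(matrix: ExpressionMatrix, axis: str = "samples",
                         center_probes: bool = True) -> ClusterResult:
    """Average-linkage clustering on 1 - centered Pearson correlation.

    ``axis`` picks whether probes or samples are the clustered items;
    correlation is computed between item profiles across the other axis.
    When samples are clustered, each probe profile is mean-centered
    first (``center_probes``), the heat-map convention: sample
    similarity then reflects shared up/down deviations rather than
    absolute intensity, which is what visually separates condition
    groups.  Constant (zero-variance) profiles have undefined
    correlation and are assigned dissimilarity 1 to every other item.
    """
    if axis not in ("probes", "samples"):
        raise ValueError(f"axis must be 'probes' or 'samples', got {axis!r}")
    if axis == "probes":
        data, labels = matrix.values, matrix.probe_ids
    else:
        data = matrix.values
        if center_probes:
            data = data - data.mean(axis=1, keepdims=True)
        data, labels = data.T, matrix.sample_ids
    n = data.shape[0]
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    sd = data.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant profiles: correlation undefined, "
                       "using dissimilarity 1", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    d = 1.0 - corr
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    condensed = d[np.triu_indices(n, k=1)]
    linkage = hierarchy.linkage(condensed, method="average")
    leaf_order = hierarchy.leaves_list(linkage).tolist()
    return ClusterResult(linkage, list(labels), leaf_order)


def write_cluster_result(result: ClusterResult, path) -> None:
    """Plain-text merge list (child ids + height) and leaf order."""
    with open(path, "w") as fh:
        fh.write("# leaves\t" + "\t".join(result.labels) + "\n")
        fh.write("# leaf_order\t"
                 + "\t".join(str(i) for i in result.leaf_order) + "\n")
        for a, b, h, size in result.linkage:
            fh.write(f"{int(a)}\t{int(b)}\t{h:.6g}\t{int(size)}\n")
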