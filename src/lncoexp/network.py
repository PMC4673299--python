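"""lncRNA-mRNA co-expression network and cis/trans classification.

Edges connect differentially expressed lncRNA and mRNA probes whose
expression profiles across all samples correlate at |r| >= 0.99 (or
r >= threshold in signed mode).  Each edge is labelled *cis* when the
two genes lie within 100 kb on the same chromosome and *trans* when
they are farther apart or on different chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, ProbeAnnotation, logger

#: distance value used when two probes sit on different chromosomes
DIFFERENT_CHROM = -1


@dataclass(frozen=True)
class CoexpressionEdge:
    lncrna_probe_id: str
    mrna_probe_id: str
    r: float
    distance_bp: int = DIFFERENT_CHROM
    mode: str = "unknown"   # cis | trans | unknown


def pearson_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Centered product-moment correlation; nan for a constant vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need >= 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def genomic_distance(a: ProbeAnnotation, b: ProbeAnnotation) -> int:
    """Gap in bp between two gene spans (closest ends).

    0 when the spans overlap or abut; :data:`DIFFERENT_CHROM` when the
    genes sit on different chromosomes.
    """
    if a.chrom != b.chrom:
        return DIFFERENT_CHROM
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end, 0)


def classify_cis_trans(distance_bp: int,
                       trans_distance_bp: int = 100_000) -> str:
    """trans iff different chromosomes or gap beyond the threshold."""
    if distance_bp == DIFFERENT_CHROM or distance_bp > trans_distance_bp:
        return "trans"
    return "cis"


def build_coexpression_edges(
    matrix: ExpressionMatrix,
    annotation: list[ProbeAnnotation],
    de_probes: list[str],
    r_threshold: float = 0.99,
    signed: bool = False,
    trans_distance_bp: int = 100_000,
) -> list[CoexpressionEdge]:
    """All qualifying (DE lncRNA, DE mRNA) edges with cis/trans labels.

    Correlation is computed across every sample column of ``matrix``.
    Constant profiles are excluded (their correlation is undefined) with
    a logged warning; probes lacking a biotype annotation raise.
    """
    ann_by_probe = {a.probe_id: a for a in annotation}
    missing = [p for p in de_probes if p not in ann_by_probe]
    if missing:
        raise ValueError(f"probes without annotation: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    lnc = [p for p in de_probes if ann_by_probe[p].biotype == "lncRNA"]
    mrna = [p for p in de_probes if ann_by_probe[p].biotype == "mRNA"]
    if not lnc or not mrna:
        return []
    sub = matrix.subset_probes(lnc + mrna)
    values = sub.values
    sd = values.std(axis=1)
    if (sd == 0).any():
        dropped = [p for p, s in zip(sub.probe_ids, sd) if s == 0]
        logger.warning("excluding %d constant profiles from correlation: %s",
                       len(dropped), dropped[:5])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    n_lnc = len(lnc)
    edges: list[CoexpressionEdge] = []
    for i, lp in enumerate(lnc):
        for j, mp in enumerate(mrna):
            r = corr[i, n_lnc + j]
            if not np.isfinite(r):
                continue
            keep = r >= r_threshold if signed else abs(r) >= r_threshold
            if not keep:
                continue
            dist = genomic_distance(ann_by_probe[lp], ann_by_probe[mp])
            edges.append(CoexpressionEdge(
                lp, mp, float(np.clip(r, -1, 1)), dist,
                classify_cis_trans(dist, trans_distance_bp)))
    logger.info("co-expression network: %d edges (%d lncRNA x %d mRNA DE "
                "probes)", len(edges), n_lnc, len(mrna))
    return edges


def degree_summary(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    """Edge count per node, both partitions (handshake: sum = 2|E|)."""
    counts: dict[str, int] = {}
    kind: dict[str, str] = {}
    for e in edges:
        counts[e.lncrna_probe_id] = counts.get(e.lncrna_probe_id, 0) + 1
        counts[e.mrna_probe_id] = counts.get(e.mrna_probe_id, 0) + 1
        kind[e.lncrna_probe_id] = "lncRNA"
        kind[e.mrna_probe_id] = "mRNA"
    df = pd.DataFrame({
        "node_id": list(counts),
        "biotype": [kind[n] for n in counts],
        "degree": list(counts.values()),
    })
    return df.sort_values(["degree", "node_id"],
                          ascending=[False, True]).reset_index(drop=True)


def edges_to_frame(edges: list[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.lncrna_probe_id, e.mrna_probe_id, e.r, e.distance_bp, e.mode)
         for e in edges],
        columns=["lncrna_probe_id", "mrna_probe_id", "r", "distance_bp",
                 "mode"])


def write_edges(edges: list[CoexpressionEdge], path) -> None:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False,
                                 float_format="%.6f")


def to_networkx(edges: list[CoexpressionEdge]):
    """Bipartite graph for export or downstream graph statistics."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.lncrna_probe_id, biotype="lncRNA")
        g.add_node(e.mrna_probe_id, biotype="mRNA")
        g.add_edge(e.lncrna_probe_id, e.mrna_probe_id, r=e.r,
                   distance_bp=e.distance_bp, mode=e.mode)
    return g
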