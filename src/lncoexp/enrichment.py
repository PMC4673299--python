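"""Hypergeometric over-representation machinery.

Two consumers share this module: guilt-by-association functional
annotation (terms enriched among the mRNAs co-expressed with an lncRNA
become that lncRNA's predicted functions) and the lncRNA-TF association
network (a TF is linked to an lncRNA when the TF's regulatory targets
overlap the lncRNA's co-expressed mRNAs more than chance allows,
p < 0.01 and BH FDR < 0.01).

The test is the upper tail P(X >= k) of the hypergeometric
distribution: drawing n genes (an lncRNA's partners) from a universe of
N genes of which K belong to the set, and observing k in the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_formats import GeneSetCollection, logger
from .diffexpr import bh_adjust
from .network import CoexpressionEdge


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    k: int   # overlap
    n: int   # query size
    K: int   # set size within universe
    N: int   # universe size
    p: float
    q: float = float("nan")
    significant: bool = False


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed via the survival function in log-space internally (scipy),
    stable for large counts.  k = 0 returns exactly 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid bounds: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_sets(query: set[str], universe: set[str],
                sets: GeneSetCollection,
                p_cutoff: float = 0.05) -> list[EnrichmentResult]:
    """Test every gene set for over-representation in ``query``.

    Sets are intersected with the universe before counting; sets with
    zero overlap with the query are omitted.  BH q-values are computed
    across all sets actually tested (k >= 1).  Results are sorted by
    ascending p, ties by set_id.
    """
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & set(universe)
    N = len(universe)
    n = len(query)
    raw: list[EnrichmentResult] = []
    for set_id, members in sets:
        members = members & universe
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        if k == 0:
            continue
        p = hypergeom_upper_tail(k, K, n, N)
        raw.append(EnrichmentResult(set_id, k, n, K, N, p))
    if not raw:
        return []
    qvals = bh_adjust([r.p for r in raw])
    out = [EnrichmentResult(r.set_id, r.k, r.n, r.K, r.N, r.p, float(q),
                            r.p <= p_cutoff)
           for r, q in zip(raw, qvals)]
    out.sort(key=lambda r: (r.p, r.set_id))
    return out


def partners_by_lncrna(edges: list[CoexpressionEdge],
                       trans_only: bool = False) -> dict[str, set[str]]:
    """Co-expressed mRNA partner set per lncRNA."""
    partners: dict[str, set[str]] = {}
    for e in edges:
        if trans_only and e.mode != "trans":
            continue
        partners.setdefault(e.lncrna_probe_id, set()).add(e.mrna_probe_id)
    return partners


def predict_lncrna_functions(
    edges: list[CoexpressionEdge],
    sets: GeneSetCollection,
    universe: set[str],
    p_cutoff: float = 0.05,
) -> dict[str, list[EnrichmentResult]]:
    """Guilt-by-association annotation of lncRNAs.

    For each lncRNA with co-expressed mRNA partners, its partner set is
    tested against every annotation term; terms significant at
    ``p_cutoff`` become that lncRNA's predicted functions.  lncRNAs
    without partners map to an empty list.
    """
    predictions: dict[str, list[EnrichmentResult]] = {}
    for lnc, partners in partners_by_lncrna(edges).items():
        results = enrich_sets(partners, universe, sets, p_cutoff)
        predictions[lnc] = [r for r in results if r.significant]
    return predictions


def tf_lncrna_network(
    edges: list[CoexpressionEdge],
    tf_targets: GeneSetCollection,
    universe: set[str],
    p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.01,
    trans_only: bool = False,
) -> pd.DataFrame:
    """Associate lncRNAs with TFs by target-set overlap.

    For every (TF, lncRNA) pair the overlap between the TF's regulatory
    targets and the lncRNA's co-expressed mRNAs is scored with the
    hypergeometric upper tail; BH adjustment runs jointly across the
    full TF x lncRNA test matrix.  Pairs with p < p_cutoff and
    q < fdr_cutoff are reported.
    """
    if not universe:
        raise ValueError("empty universe")
    N = len(universe)
    partners = partners_by_lncrna(edges, trans_only=trans_only)
    rows = []
    for tf_id, targets in tf_targets:
        targets = targets & universe
        if not targets:
            logger.warning("TF set %s disjoint from universe, skipped", tf_id)
            continue
        K = len(targets)
        for lnc, part in partners.items():
            n = len(part)
            k = len(part & targets)
            if k == 0:
                continue
            p = hypergeom_upper_tail(k, K, n, N)
            rows.append((tf_id, lnc, k, n, K, N, p))
    df = pd.DataFrame(rows, columns=["tf_id", "lncrna_probe_id", "k", "n",
                                     "K", "N", "p"])
    if df.empty:
        df["q"] = pd.Series(dtype=float)
        return df
    df["q"] = bh_adjust(df["p"].to_numpy())
    df = df[(df["p"] < p_cutoff) & (df["q"] < fdr_cutoff)]
    return df.sort_values(["p", "tf_id", "lncrna_probe_id"]
                          ).reset_index(drop=True)


def rank_tfs(associations: pd.DataFrame) -> pd.DataFrame:
    """Order TFs by how many lncRNAs they associate with.

    Descending lncRNA count, ties by smaller median p then tf_id — the
    head of this table names the hub TFs of the lncRNA-TF network.
    """
    if associations.empty:
        return pd.DataFrame(columns=["tf_id", "n_lncrnas", "median_p"])
    grouped = associations.groupby("tf_id").agg(
        n_lncrnas=("lncrna_probe_id", "nunique"),
        median_p=("p", "median"))
    grouped = grouped.reset_index().sort_values(
        ["n_lncrnas", "median_p", "tf_id"], ascending=[False, True, True])
    return grouped.reset_index(drop=True)


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.set_id, r.k, r.n, r.K, r.N, r.p, r.q, r.significant)
         for r in results],
        columns=["set_id", "k", "n", "K", "N", "p", "q", "significant"])
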