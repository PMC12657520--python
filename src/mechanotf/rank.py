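"""TF identification and ranking from an optimized regulatory network.

A TF's evidence of being a force-responsive regulator is (i) the number
of prized target transcripts it reaches inside the PCST solution and
(ii) its own expression change under load. A transparent hypergeometric
set-overlap enrichment is provided as plumbing for regulon lists; it is
a deliberately simple substitute for motif-based tools and is labelled
``method=hypergeometric`` in its output.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from mechanotf.network import RegulatoryNetwork
from mechanotf.pcst import PCSTSolution


def count_tf_targets(
    sol: PCSTSolution, net: RegulatoryNetwork, within_solution: bool = True
) -> dict[str, int]:
    """Per selected TF node: number of prized RNA targets it regulates.

    By default only TF->target edges inside the optimized solution
    count; with ``within_solution=False`` every prized RNA node the TF
    can reach in the full network counts, whether selected or not.
    """
    selected = set(sol.nodes)
    sel_edges = set(sol.edges)
    counts: dict[str, int] = {
        n.id: 0 for n in net.nodes.values() if n.node_class == "TF" and n.id in selected
    }
    for e in net.edges:
        if e.edge_class != "TF_target":
            continue
        key = (e.u, e.v) if e.u <= e.v else (e.v, e.u)
        if within_solution and key not in sel_edges:
            continue
        tf = e.u if net.nodes[e.u].node_class == "TF" else e.v
        if tf in counts:
            counts[tf] += 1
    return counts


def rank_tfs(
    counts: Mapping[str, int],
    expression_values: Mapping[str, float] | None = None,
    deg_list: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Rank TFs by target count, then by absolute expression change
    (load log2FC), then alphabetically.

    Returns a DataFrame with columns ``tf``, ``n_targets``,
    ``expression_change`` (NaN when the TF is not load-upregulated) and
    ``in_deg_list``.
    """
    expression_values = expression_values or {}
    deg = set(deg_list or [])
    rows = []
    for tf, n in counts.items():
        expr = expression_values.get(tf)
        rows.append(
            {
                "tf": tf,
                "n_targets": int(n),
                "expression_change": float(expr) if expr is not None else float("nan"),
                "in_deg_list": tf in deg,
            }
        )
    df = pd.DataFrame(rows, columns=["tf", "n_targets", "expression_change", "in_deg_list"])
    if df.empty:
        return df
    sort_key = df["expression_change"].abs().fillna(-1.0)
    df = (
        df.assign(_k=sort_key)
        .sort_values(["n_targets", "_k", "tf"], ascending=[False, False, True])
        .drop(columns="_k")
        .reset_index(drop=True)
    )
    return df


def enrich_tf_targets(
    regulons: Mapping[str, Iterable[str]],
    query: Iterable[str],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of each TF's regulon in a
    query gene set, with Benjamini-Hochberg adjustment.

    For a universe of M genes, a regulon of K and a query of n with
    overlap k, ``p = P(X >= k)`` for X ~ Hypergeom(M, K, n) and
    ``z = (k - nK/M) / sd(X)``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query) & universe
    M, n = len(universe), len(query)
    rows = []
    for tf in sorted(regulons):
        regulon = set(regulons[tf]) & universe
        K = len(regulon)
        k = len(regulon & query)
        if K == 0 or n == 0:
            p, z = 1.0, 0.0
        else:
            p = float(sps.hypergeom.sf(k - 1, M, K, n))
            mean = n * K / M
            var = n * (K / M) * (1 - K / M) * (M - n) / (M - 1) if M > 1 else 0.0
            z = (k - mean) / var**0.5 if var > 0 else 0.0
        rows.append(
            {"tf": tf, "overlap": k, "regulon_size": K, "p_value": min(p, 1.0), "z_score": z}
        )
    df = pd.DataFrame(
        rows, columns=["tf", "overlap", "regulon_size", "p_value", "z_score"]
    )
    if not df.empty:
        df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
        # BH can only raise a p-value
        df["adjusted_p"] = df[["adjusted_p", "p_value"]].max(axis=1)
    else:
        df["adjusted_p"] = []
    df["method"] = "hypergeometric"
    return df[["tf", "overlap", "regulon_size", "p_value", "adjusted_p", "z_score", "method"]]
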