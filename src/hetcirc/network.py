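"""CircRNA-mRNA correlation networks and heterosis candidate selection.

Edges are Spearman correlations between circRNAs and genes co-assigned to
a module significantly associated with feed intake or residual feed
intake; an edge is stored only when r > 0.6 and p < 0.05.  Candidate
pairs additionally require both endpoints to be nonadditively expressed
in the cross under study; a circRNA whose pattern differs between the two
cross directions is flagged cross-divergent (the signature consistent
with divergent RFI heterosis between reciprocal crosses).
"""

from __future__ import annotations

import itertools
import warnings
from functools import lru_cache

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .config import CROSSES
from .modules import UNASSIGNED
from .patterns import NONADDITIVE_CLASSES

EDGE_R = 0.6
EDGE_P = 0.05
EXACT_PERMUTATION_MAX_N = 9


class NetworkError(ValueError):
    pass


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """Sorted |rho| values over all rank permutations of size n."""
    ranks = np.arange(n, dtype=float)
    perms = np.array(list(itertools.permutations(range(n))), dtype=float)
    d2 = ((perms - ranks[None, :]) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n * n - 1.0))
    return np.sort(np.abs(rho))


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman correlation with an exact permutation p for small n.

    For n <= 9 without ties the two-sided p is the exact fraction of rank
    permutations with |rho| at least as large as observed; otherwise (or
    with ties) the t approximation from scipy is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    r, p_approx = stats.spearmanr(x, y)
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if n <= EXACT_PERMUTATION_MAX_N and not ties and np.isfinite(r):
        null = _exact_spearman_null(n)
        p = float(np.mean(null >= abs(r) - 1e-12))
        return float(r), p
    return float(r), float(p_approx)


def correlate_pairs(
    circ_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    assignment: pd.DataFrame,
    trait_correlations: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    tissue: str = "",
    cross: str = "",
    qualifying_traits: tuple[str, ...] = ("RFI", "DFC"),
    trait_alpha: float = 0.01,
) -> pd.DataFrame:
    """Spearman edges within feed-efficiency-associated modules.

    Only modules with p < ``trait_alpha`` for RFI or DFC qualify; all
    circ x gene pairs co-assigned to a qualifying module are tested and
    stored iff r > 0.6 and p < 0.05.  When ``meta`` and ``cross`` are
    given, correlations are computed over that cross's samples (plus the
    parents' samples when ``include_parents`` applies upstream); here the
    sample subset is whatever columns the caller passes, restricted to the
    cross if requested.
    """
    qual = trait_correlations[
        trait_correlations["trait"].isin(qualifying_traits)
        & (trait_correlations["p"] < trait_alpha)]["module"].unique()
    qual = [m for m in qual if m != UNASSIGNED]
    if len(qual) == 0:
        warnings.warn("no module qualifies for the trait association gate; "
                      "returning an empty network")
    cols = list(circ_expr.columns)
    if meta is not None and cross:
        m = meta.set_index("sample_id") if "sample_id" in meta.columns \
            else meta
        cols = [s for s in cols
                if m.loc[s, "group"] == cross
                and (not tissue or m.loc[s, "tissue"] == tissue)]
        if len(cols) < 4:
            raise NetworkError(
                f"only {len(cols)} samples for cross {cross}")
    amap = assignment.set_index("feature_id")["module"]
    rows = []
    for mod in qual:
        members = amap.index[amap == mod]
        circs = [f for f in members if f in circ_expr.index]
        genes = [f for f in members if f in gene_expr.index]
        for cid in circs:
            x = circ_expr.loc[cid, cols].to_numpy(float)
            if np.ptp(x) == 0:
                continue
            for gid in genes:
                y = gene_expr.loc[gid, cols].to_numpy(float)
                if np.ptp(y) == 0:
                    continue
                r, p = spearman_with_p(x, y)
                if r > EDGE_R and p < EDGE_P:
                    rows.append({
                        "circ_id": cid, "gene_id": gid,
                        "spearman_r": r, "p": p, "module": mod,
                        "tissue": tissue, "cross": cross,
                    })
    return pd.DataFrame(
        rows, columns=["circ_id", "gene_id", "spearman_r", "p",
                       "module", "tissue", "cross"])


def select_candidates(
    edges: pd.DataFrame, pattern_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Nonadditive circRNA-gene candidate pairs from the edge set.

    Keeps edges whose circRNA and gene are both nonadditive (dominant,
    overdominant or underdominant) in the edge's cross.  ``same_pattern``
    marks identical pattern labels; ``cross_divergent`` marks circRNAs
    whose pattern label differs between WY and YW.
    """
    calls = pattern_calls.set_index(["feature_id", "cross"])
    rows = []
    for _, edge in edges.iterrows():
        cross = edge["cross"]
        keyed = []
        for fid in (edge["circ_id"], edge["gene_id"]):
            try:
                keyed.append(calls.loc[(fid, cross)])
            except KeyError:
                warnings.warn(
                    f"no pattern call for {fid} in {cross}; edge skipped")
                keyed = None
                break
        if keyed is None:
            continue
        circ_call, gene_call = keyed
        if (circ_call["pattern_class"] not in NONADDITIVE_CLASSES
                or gene_call["pattern_class"] not in NONADDITIVE_CLASSES):
            continue
        other = [c for c in CROSSES if c != cross][0]
        try:
            circ_other = calls.loc[(edge["circ_id"], other)]["pattern"]
        except KeyError:
            circ_other = None
        rows.append({
            "circ_id": edge["circ_id"], "gene_id": edge["gene_id"],
            "tissue": edge["tissue"], "cross": cross,
            "module": edge["module"],
            "spearman_r": edge["spearman_r"], "p": edge["p"],
            "circ_pattern": circ_call["pattern"],
            "gene_pattern": gene_call["pattern"],
            "same_pattern": circ_call["pattern"] == gene_call["pattern"],
            "cross_divergent": (circ_other is not None
                                and circ_other != circ_call["pattern"]),
        })
    return pd.DataFrame(
        rows, columns=["circ_id", "gene_id", "tissue", "cross", "module",
                       "spearman_r", "p", "circ_pattern", "gene_pattern",
                       "same_pattern", "cross_divergent"])


# ---------------------------------------------------------------------------
# export


def build_graph(
    edges: pd.DataFrame, candidates: pd.DataFrame | None = None,
) -> nx.Graph:
    g = nx.Graph()
    cand_pairs = set()
    pattern_of = {}
    if candidates is not None and len(candidates):
        cand_pairs = set(zip(candidates["circ_id"], candidates["gene_id"]))
        for _, row in candidates.iterrows():
            pattern_of[row["circ_id"]] = row["circ_pattern"]
            pattern_of[row["gene_id"]] = row["gene_pattern"]
    for _, e in edges.iterrows():
        for fid, kind in ((e["circ_id"], "circ"), (e["gene_id"], "gene")):
            if fid not in g:
                g.add_node(fid, kind=kind, module=str(e["module"]),
                           pattern=str(pattern_of.get(fid, "")))
        g.add_edge(e["circ_id"], e["gene_id"],
                   spearman_r=float(e["spearman_r"]), p=float(e["p"]),
                   candidate=(e["circ_id"], e["gene_id"]) in cand_pairs)
    return g


def export_network(
    edges: pd.DataFrame,
    candidates: pd.DataFrame | None,
    graphml_path: str,
    sif_path: str,
) -> None:
    """Write the network as GraphML and SIF (circ correlates_with gene)."""
    g = build_graph(edges, candidates)
    nx.write_graphml(g, graphml_path)
    with open(sif_path, "w") as fh:
        for _, e in edges.sort_values(
                ["circ_id", "gene_id"]).iterrows():
            fh.write(f"{e['circ_id']}\tcorrelates_with\t{e['gene_id']}\n")


def read_sif(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                continue
            rows.append({"circ_id": parts[0], "interaction": parts[1],
                         "gene_id": parts[2]})
    return pd.DataFrame(rows, columns=["circ_id", "interaction", "gene_id"])
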