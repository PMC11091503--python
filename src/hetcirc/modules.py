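"""Signed weighted co-expression modules and module-trait correlation.

Per tissue, circRNA and gene expression are filtered by median absolute
deviation, combined into one matrix, turned into a signed adjacency
a_ij = ((1 + cor_ij)/2)^beta with a soft threshold picked by scale-free
fit (fallback powers 18/16/14/12 by sample size), normalized with the
topological overlap measure, clustered by average linkage, cut into
modules of at least 50 members, and merged when module eigengenes are
strongly correlated.  Eigengenes (first principal component of the
standardized module expression) are then correlated with the feed-
efficiency traits; p < 0.01 marks a trait-associated module.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

MIN_MODULE_SIZE = 50
MERGE_COR = 0.75
TRAIT_ALPHA = 0.01
SCALE_FREE_R2 = 0.85

#: WGCNA-style color labels, assigned to modules in decreasing size order
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)
UNASSIGNED = "grey"


class ModuleError(ValueError):
    pass


def mad_filter(
    circ_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    gene_top_fraction: float = 0.25,
) -> pd.DataFrame:
    """Keep circRNAs with MAD > 0 and genes in the top fraction by MAD.

    Returns the two filtered matrices concatenated (features x samples).
    """
    if not circ_expr.columns.equals(gene_expr.columns):
        raise ModuleError("circ and gene matrices must share samples")
    circ_mad = stats.median_abs_deviation(circ_expr, axis=1)
    keep_circ = circ_expr.loc[circ_mad > 0]
    gene_mad = pd.Series(stats.median_abs_deviation(gene_expr, axis=1),
                         index=gene_expr.index)
    k = int(np.ceil(gene_top_fraction * len(gene_mad)))
    keep_gene = gene_expr.loc[
        gene_mad.sort_values(ascending=False, kind="stable").index[:k]]
    out = pd.concat([keep_circ, keep_gene])
    if len(out) < MIN_MODULE_SIZE:
        warnings.warn(
            f"only {len(out)} features retained; module detection "
            "will be degenerate")
    return out


def signed_adjacency(expr: pd.DataFrame | np.ndarray,
                     beta: float) -> np.ndarray:
    """Signed adjacency ((1 + Pearson cor)/2)^beta over feature rows."""
    X = expr.to_numpy(float) if isinstance(expr, pd.DataFrame) else expr
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(X)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    return ((1.0 + np.clip(cor, -1.0, 1.0)) / 2.0) ** beta


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of log10 frequency vs log10 mean connectivity."""
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / k.size))
    if len(xs) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(r ** 2), float(slope)


def fallback_power(n_samples: int) -> int:
    """Soft-threshold fallback by sample size when no power fits."""
    if n_samples < 20:
        return 18
    if n_samples < 30:
        return 16
    if n_samples < 40:
        return 14
    return 12


def pick_soft_threshold(
    expr: pd.DataFrame | np.ndarray,
    n_samples: int | None = None,
    powers: range = range(1, 31),
    r2_threshold: float = SCALE_FREE_R2,
) -> tuple[int, pd.DataFrame]:
    """Smallest power with scale-free fit R^2 >= threshold, negative slope.

    Scans signed adjacencies over ``powers``; if no power qualifies,
    returns the sample-size fallback (18 below 20 samples, 16 below 30,
    14 below 40, 12 otherwise).  Also returns the per-power scan table.
    """
    X = expr.to_numpy(float) if isinstance(expr, pd.DataFrame) else expr
    if X.shape[0] <= 2:
        raise ModuleError("need more than 2 features to pick a power")
    if n_samples is None:
        n_samples = X.shape[1]
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(X)
    cor = np.nan_to_num(cor, nan=0.0)
    np.fill_diagonal(cor, 1.0)
    base = (1.0 + np.clip(cor, -1.0, 1.0)) / 2.0
    rows = []
    chosen = None
    for beta in powers:
        adj = base ** beta
        k = adj.sum(axis=1) - 1.0
        r2, slope = _scale_free_fit(k)
        rows.append({"power": beta, "r2": r2, "slope": slope,
                     "mean_k": float(k.mean())})
        if chosen is None and r2 >= r2_threshold and slope < 0:
            chosen = int(beta)
    scan = pd.DataFrame(rows)
    if chosen is None:
        chosen = fallback_power(n_samples)
    return chosen, scan


def compute_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a signed adjacency.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_{u != i,j} a_iu a_uj and k_i = sum_{u != i} a_iu;
    diagonal fixed at 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ModuleError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ModuleError("adjacency must be symmetric")
    d = np.diag(A).copy()
    # l_ij excludes u in {i, j}; with the actual diagonal d:
    # (A@A)_ij = l_ij + d_i a_ij + a_ij d_j
    L = A @ A - (d[:, None] + d[None, :]) * A
    k = A.sum(axis=1) - d
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigengene(
    expr: pd.DataFrame, members: list[str] | pd.Index,
) -> tuple[np.ndarray, float]:
    """First principal component of the standardized module expression.

    Returns (eigengene over samples, fraction of variance explained).
    The eigengene has unit norm and is sign-aligned so its correlation
    with the module's mean standardized profile is nonnegative.
    """
    sub = expr.loc[list(members)].to_numpy(float)
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).all():
        raise ModuleError("module expression is constant")
    sub = sub[sd > 0]
    sd = sd[sd > 0]
    Z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = Vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    var = S ** 2
    return eig, float(var[0] / var.sum())


def _pick_cut_height(Z: np.ndarray, min_size: int,
                     max_candidates: int = 200) -> float:
    """Cut height maximizing the number of clusters of size >= min_size.

    Scans midpoints between consecutive merge heights (the distinct cut
    outcomes), preferring more valid modules and, on ties, the lower
    height (loosely attached background features then stay unassigned;
    fragments of one true module re-merge later through the eigengene
    merge step).  A fixed-height or fixed-quantile cut cannot separate
    planted modules once unrelated background features attach near the
    dendrogram top, because all late merges bunch together.
    """
    heights = np.sort(np.unique(Z[:, 2]))
    if heights.size == 1:
        return float(heights[0]) + 1e-12
    mids = (heights[1:] + heights[:-1]) / 2.0
    if mids.size > max_candidates:
        step = max(1, mids.size // max_candidates)
        mids = mids[::step]
    best = (-1, 0.0)
    best_cut = float(heights[-1]) + 1e-12
    for cut in mids:
        labels = hierarchy.fcluster(Z, t=cut, criterion="distance")
        sizes = np.bincount(labels)
        big = sizes[sizes >= min_size]
        score = (big.size, -cut)
        if score > best:
            best = score
            best_cut = float(cut)
    return best_cut


def detect_modules(
    tom: np.ndarray,
    expr: pd.DataFrame,
    min_size: int = MIN_MODULE_SIZE,
    merge_cor: float = MERGE_COR,
    cut_height: float | None = None,
    rescue_kme: float = 0.5,
    prune_kme: float = 0.3,
) -> pd.DataFrame:
    """Average-linkage clustering on 1 - TOM with a scanned static cut.

    The dendrogram is cut at ``cut_height`` if given, otherwise at the
    lowest height that maximizes the number of clusters with at least
    ``min_size`` members (a static-cut stand-in for the adaptive tree
    cut).  Clusters below ``min_size`` go to the unassigned ('grey')
    label; unassigned features whose correlation with a module eigengene
    reaches ``rescue_kme`` are then pulled into the closest module (the
    analogue of the reference algorithm's label-assignment stage), and
    module pairs whose eigengenes correlate at >= ``merge_cor`` are
    merged iteratively.  Returns feature_id, module (color label) and
    kME (correlation of the feature with its module eigengene).
    """
    n = tom.shape[0]
    if len(expr) != n:
        raise ModuleError("TOM and expression matrices disagree in size")
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = _pick_cut_height(Z, min_size) if cut_height is None \
        else float(cut_height)
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")

    labels = raw.astype(object)
    sizes = pd.Series(raw).value_counts()
    for lab, size in sizes.items():
        if size < min_size:
            labels[raw == lab] = 0

    def eigengenes(lbls: np.ndarray) -> dict:
        return {
            lab: module_eigengene(
                expr, expr.index[np.flatnonzero(lbls == lab)])[0]
            for lab in set(lbls) if lab != 0
        }

    # rescue unassigned features strongly correlated with a module
    egs = eigengenes(labels)
    if egs and rescue_kme is not None:
        X = expr.to_numpy(float)
        sd = X.std(axis=1, ddof=0)
        Zx = np.where(sd[:, None] > 0,
                      (X - X.mean(axis=1, keepdims=True))
                      / np.where(sd[:, None] > 0, sd[:, None], 1.0), 0.0)
        mods = list(egs)
        E = np.array([(egs[m_] - egs[m_].mean()) / egs[m_].std(ddof=0)
                      for m_ in mods])
        kall = Zx @ E.T / X.shape[1]
        grey = np.flatnonzero(labels == 0)
        for i in grey:
            j = int(np.argmax(kall[i]))
            if kall[i, j] >= rescue_kme:
                labels[i] = mods[j]

    # iterative eigengene merging
    while True:
        egs = eigengenes(labels)
        mods = sorted(egs, key=lambda m: (labels == m).sum(), reverse=True)
        merged = False
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                r = np.corrcoef(egs[mods[i]], egs[mods[j]])[0, 1]
                if r >= merge_cor:
                    labels[labels == mods[j]] = mods[i]
                    merged = True
                    break
            if merged:
                break
        if not merged:
            break

    # prune weakly connected members (kME below threshold), then drop
    # modules that fall under the size minimum
    if prune_kme is not None:
        egs = eigengenes(labels)
        for lab, eig in egs.items():
            sel = np.flatnonzero(labels == lab)
            sub = expr.iloc[sel].to_numpy(float)
            sd = sub.std(axis=1, ddof=0)
            z = np.where(sd[:, None] > 0,
                         (sub - sub.mean(axis=1, keepdims=True))
                         / np.where(sd[:, None] > 0, sd[:, None], 1.0),
                         0.0)
            ez = (eig - eig.mean()) / eig.std(ddof=0)
            kme_mod = z @ ez / z.shape[1]
            labels[sel[kme_mod < prune_kme]] = 0
        for lab in set(labels) - {0}:
            if (labels == lab).sum() < min_size:
                labels[labels == lab] = 0

    # color labels by decreasing size
    final = sorted((lab for lab in set(labels) if lab != 0),
                   key=lambda m: (-(labels == m).sum(), str(m)))
    color_of = {lab: MODULE_COLORS[i % len(MODULE_COLORS)]
                + ("" if i < len(MODULE_COLORS)
                   else str(i // len(MODULE_COLORS)))
                for i, lab in enumerate(final)}
    colors = np.array([color_of.get(lab, UNASSIGNED) for lab in labels],
                      dtype=object)

    kme = np.full(n, np.nan)
    for lab in final:
        sel = np.flatnonzero(labels == lab)
        eig, _ = module_eigengene(expr, expr.index[sel])
        sub = expr.iloc[sel].to_numpy(float)
        sd = sub.std(axis=1, ddof=0)
        ok = sd > 0
        z = (sub[ok] - sub[ok].mean(axis=1, keepdims=True)) / \
            sd[ok][:, None]
        ez = (eig - eig.mean()) / eig.std(ddof=0)
        kme[sel[ok]] = z @ ez / z.shape[1]
    return pd.DataFrame({
        "feature_id": expr.index, "module": colors, "kme": kme,
    })


def eigengene_matrix(
    expr: pd.DataFrame, assignment: pd.DataFrame,
) -> pd.DataFrame:
    """Samples x modules matrix of eigengenes (unassigned excluded)."""
    out = {}
    for lab, sub in assignment.groupby("module"):
        if lab == UNASSIGNED:
            continue
        eig, _ = module_eigengene(expr, sub["feature_id"].tolist())
        out[lab] = eig
    return pd.DataFrame(out, index=expr.columns)


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    alpha: float = TRAIT_ALPHA,
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each trait.

    p-values follow the Student-t transform t = r*sqrt(n-2)/sqrt(1-r^2)
    with n-2 degrees of freedom, two-sided.  Constant traits are reported
    with missing correlation.
    """
    common = eigengenes.index.intersection(traits.index)
    if len(common) < 4:
        raise ModuleError(
            f"only {len(common)} samples align between eigengenes "
            "and traits; need >= 4")
    E = eigengenes.loc[common]
    T = traits.loc[common]
    n = len(common)
    rows = []
    for mod in E.columns:
        for trait in T.columns:
            x = E[mod].to_numpy(float)
            y = T[trait].to_numpy(float)
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                rows.append({"module": mod, "trait": trait, "r": np.nan,
                             "p": np.nan, "n": n, "significant": False})
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(min(r, 1.0), -1.0)
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
                p = float(2.0 * stats.t.sf(abs(t), n - 2))
            rows.append({"module": mod, "trait": trait, "r": r, "p": p,
                         "n": n, "significant": p < alpha})
    return pd.DataFrame(rows)
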