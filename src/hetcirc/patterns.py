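"""Differential expression across the cross design and inheritance-pattern
classification.

Five group contrasts (WW vs YY, each cross vs each parent) plus a
cross-vs-mid-parent contrast feed a rule-based classifier that assigns each
feature one of twelve directional inheritance patterns:

    additivity      IV (WW-higher), X (YY-higher)
    dominance       V, XI (cross tracks WW), III, IX (cross tracks YY)
    overdominance   I (parents equal), II (WW high parent), XII (YY high)
    underdominance  VII (parents equal), VI (WW high parent), VIII (YY high)

Differential expression uses a size-factor-normalized negative-binomial
model with method-of-moments dispersion and a Wald test on the group
log2 fold change.  A feature counts as *differentially expressed* in a
contrast at p < 0.05 together with |log2FC| > 1 (strict inequalities);
the pattern rules themselves gate on p alone, because a dominance call
like "cross equal to one parent but different from the other" compares
the cross against a mid-parent level only half the parental gap away —
a |log2FC| > 1 requirement there would silently erase dominance calls
whenever the parents differ by less than two log2 units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CROSSES, PARENTS
from .simulate import CLASS_OF_PATTERN

DEFAULT_ALPHA = 0.05
DE_LFC = 1.0          # |log2FC| gate defining "differentially expressed"
DEFAULT_LFC = 0.0     # pattern rules gate on p only (direction from sign)
_DISPERSION_FLOOR = 1e-8
_PSEUDO = 0.5  # pseudo normalized count for fold-change stability

CONTRASTS = ("WW_vs_YY", "WY_vs_WW", "WY_vs_YY", "YW_vs_WW", "YW_vs_YY")

#: label mapping induced by relabeling the parents WW <-> YY
RELABEL_INVOLUTION = {
    "IV": "X", "X": "IV", "V": "IX", "IX": "V", "XI": "III", "III": "XI",
    "II": "XII", "XII": "II", "VI": "VIII", "VIII": "VI",
    "I": "I", "VII": "VII",
    "conserved": "conserved", "unclassified": "unclassified",
}


class PatternError(ValueError):
    pass


@dataclass
class Contrast:
    """One feature's differential-expression result for one contrast."""

    log2fc: float
    p: float


def normalize_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors against a geometric-mean reference.

    Computed over features with positive counts in every sample; if none
    exist, falls back to total-count factors (scaled to geometric mean 1)
    with a warning.
    """
    if counts.shape[1] < 2:
        raise PatternError("need at least 2 samples for size factors")
    X = counts.to_numpy(float)
    pos = (X > 0).all(axis=1)
    if pos.sum() == 0:
        warnings.warn(
            "no feature has positive counts in all samples; "
            "falling back to total-count size factors")
        tot = X.sum(axis=0)
        if (tot <= 0).any():
            raise PatternError("a sample has zero total counts")
        f = tot / np.exp(np.mean(np.log(tot)))
        return pd.Series(f, index=counts.columns, name="size_factor")
    logX = np.log(X[pos])
    ref = logX.mean(axis=1)
    factors = np.exp(np.median(logX - ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _nb_wald(
    A: np.ndarray, B: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NB Wald test on two normalized count matrices (features x samples).

    Dispersion is a pooled within-group method-of-moments estimate,
    floored at 1e-8.  The Wald statistic for the log2 fold change is
    referred to a t distribution with nA + nB - 2 degrees of freedom
    (small per-group sample sizes make the normal reference
    anticonservative).
    """
    nA, nB = A.shape[1], B.shape[1]
    muA, muB = A.mean(axis=1), B.mean(axis=1)
    vA = A.var(axis=1, ddof=1)
    vB = B.var(axis=1, ddof=1)
    pooled_v = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
    mu = (nA * muA + nB * muB) / (nA + nB)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_v - mu) / mu ** 2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, _DISPERSION_FLOOR)

    lfc = np.log2((muA + _PSEUDO) / (muB + _PSEUDO))
    varA = muA + alpha * muA ** 2
    varB = muB + alpha * muB ** 2
    se = np.sqrt(varA / (nA * (muA + _PSEUDO) ** 2)
                 + varB / (nB * (muB + _PSEUDO) ** 2)) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    p = 2.0 * stats.t.sf(np.abs(wald), nA + nB - 2)
    zero = (muA == 0) & (muB == 0)
    lfc[zero] = 0.0
    p[zero] = 1.0
    p = np.where(np.isfinite(p), p, 1.0)
    return lfc, p, muA, muB


def nb_differential_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    group_a: str,
    group_b: str,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB differential test of group_a over group_b.

    log2FC is oriented first-named over second (positive = higher in
    group_a).  Returns feature_id, log2FC, p, base_mean_a, base_mean_b.
    """
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    sa = [s for s in counts.columns if m.loc[s, "group"] == group_a]
    sb = [s for s in counts.columns if m.loc[s, "group"] == group_b]
    for g, ss in ((group_a, sa), (group_b, sb)):
        if len(ss) < 3:
            raise PatternError(
                f"group {g} has {len(ss)} samples; need >= 3")
    if size_factors is None:
        size_factors = normalize_size_factors(counts[sa + sb])
    A = counts[sa].to_numpy(float) / size_factors[sa].to_numpy()[None, :]
    B = counts[sb].to_numpy(float) / size_factors[sb].to_numpy()[None, :]
    lfc, p, muA, muB = _nb_wald(A, B)
    return pd.DataFrame({
        "feature_id": counts.index, "log2FC": lfc, "p": p,
        "base_mean_a": muA, "base_mean_b": muB,
    })


def midparent_test(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    cross: str,
    seed: int = 0,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Cross vs pseudo-mid-parent differential test.

    Pseudo-mid-parent samples are formed by averaging the normalized
    counts of randomly paired WW and YY samples (pairing under ``seed``);
    the NB Wald test then compares the cross to those pseudo-samples.
    """
    if cross not in CROSSES:
        raise PatternError(f"unknown cross {cross!r}")
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    sc = [s for s in counts.columns if m.loc[s, "group"] == cross]
    sw = [s for s in counts.columns if m.loc[s, "group"] == "WW"]
    sy = [s for s in counts.columns if m.loc[s, "group"] == "YY"]
    for g, ss in ((cross, sc), ("WW", sw), ("YY", sy)):
        if len(ss) < 3:
            raise PatternError(f"group {g} has {len(ss)} samples; need >= 3")
    if len(sw) != len(sy):
        warnings.warn(
            f"unequal parental sample counts ({len(sw)} WW, {len(sy)} YY); "
            "pairing down to the minimum")
    k = min(len(sw), len(sy))
    rng = np.random.default_rng(seed)
    pw = rng.permutation(len(sw))[:k]
    py = rng.permutation(len(sy))[:k]
    if size_factors is None:
        size_factors = normalize_size_factors(counts[sc + sw + sy])
    C = counts[sc].to_numpy(float) / size_factors[sc].to_numpy()[None, :]
    W = counts[sw].to_numpy(float) / size_factors[sw].to_numpy()[None, :]
    Y = counts[sy].to_numpy(float) / size_factors[sy].to_numpy()[None, :]
    MP = 0.5 * (W[:, pw] + Y[:, py])

    # dispersion from the three real groups; the pseudo group's variance is
    # the NB model propagated through the pairwise averaging,
    # Var(MP) = (Var(W) + Var(Y)) / 4, not the NB variance at its mean
    mats = (C, W, Y)
    ns = np.array([m_.shape[1] for m_ in mats], float)
    pooled_v = sum((m_.shape[1] - 1) * m_.var(axis=1, ddof=1)
                   for m_ in mats) / (ns.sum() - len(mats))
    mu_all = sum(m_.shape[1] * m_.mean(axis=1) for m_ in mats) / ns.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_v - mu_all) / mu_all ** 2
    alpha = np.maximum(np.where(np.isfinite(alpha), alpha, 0.0),
                       _DISPERSION_FLOOR)

    muC, muW, muY = C.mean(axis=1), W.mean(axis=1), Y.mean(axis=1)
    muMP = MP.mean(axis=1)
    varC = muC + alpha * muC ** 2
    varMP = ((muW + alpha * muW ** 2) + (muY + alpha * muY ** 2)) / 4.0
    lfc = np.log2((muC + _PSEUDO) / (muMP + _PSEUDO))
    se = np.sqrt(varC / (len(sc) * (muC + _PSEUDO) ** 2)
                 + varMP / (k * (muMP + _PSEUDO) ** 2)) / np.log(2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = lfc / se
    p = 2.0 * stats.t.sf(np.abs(wald), len(sc) + k - 2)
    zero = (muC == 0) & (muMP == 0)
    lfc[zero] = 0.0
    p[zero] = 1.0
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame({
        "feature_id": counts.index, "log2FC": lfc, "p": p,
        "base_mean_a": muC, "base_mean_b": muMP,
    })


# ---------------------------------------------------------------------------
# pattern classification


def classify_pattern(
    parents: Contrast,
    vs_ww: Contrast,
    vs_yy: Contrast,
    midparent: Contrast,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
) -> str:
    """Assign one inheritance-pattern label from the four contrasts.

    Significance everywhere means p < alpha AND |log2FC| > lfc_threshold
    (strict).  Rules are applied in a fixed order (additivity, dominance,
    over/under-dominance), making the mapping a partition of all
    significance/direction states.  Features with no significant contrast
    and no rule fired are 'conserved'; anything else left over is
    'unclassified'.
    """
    for name, c in (("parents", parents), ("vs_ww", vs_ww),
                    ("vs_yy", vs_yy), ("midparent", midparent)):
        if c is None or not np.isfinite(c.p):
            raise PatternError(f"missing contrast: {name}")

    def sig(c: Contrast) -> bool:
        return c.p < alpha and abs(c.log2fc) > lfc_threshold

    sp, swp, syp, smp = sig(parents), sig(vs_ww), sig(vs_yy), sig(midparent)

    if sp and not smp:
        return "IV" if parents.log2fc > 0 else "X"
    if not swp and syp:
        return "V" if vs_yy.log2fc < 0 else "XI"
    if not syp and swp:
        return "III" if vs_ww.log2fc > 0 else "IX"
    if swp and syp and vs_ww.log2fc > 0 and vs_yy.log2fc > 0:
        if sp:
            return "II" if parents.log2fc > 0 else "XII"
        return "I"
    if swp and syp and vs_ww.log2fc < 0 and vs_yy.log2fc < 0:
        if sp:
            return "VI" if parents.log2fc > 0 else "VIII"
        return "VII"
    if not (sp or swp or syp or smp):
        return "conserved"
    return "unclassified"


def pattern_class(pattern: str) -> str:
    return CLASS_OF_PATTERN.get(pattern, pattern)


def classify_patterns(
    contrasts: dict[str, pd.DataFrame],
    cross: str,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
) -> pd.DataFrame:
    """Vectorized classification for one cross.

    ``contrasts`` maps {'parents', 'vs_ww', 'vs_yy', 'midparent'} to
    DataFrames with feature_id, log2FC, p (as produced by the test
    functions), all covering the same features.
    """
    needed = ("parents", "vs_ww", "vs_yy", "midparent")
    for name in needed:
        if name not in contrasts:
            raise PatternError(f"missing contrast: {name}")
    idx = contrasts["parents"]["feature_id"]
    frames = {n: contrasts[n].set_index("feature_id").loc[idx]
              for n in needed}
    rows = []
    for fid in idx:
        label = classify_pattern(
            Contrast(frames["parents"].loc[fid, "log2FC"],
                     frames["parents"].loc[fid, "p"]),
            Contrast(frames["vs_ww"].loc[fid, "log2FC"],
                     frames["vs_ww"].loc[fid, "p"]),
            Contrast(frames["vs_yy"].loc[fid, "log2FC"],
                     frames["vs_yy"].loc[fid, "p"]),
            Contrast(frames["midparent"].loc[fid, "log2FC"],
                     frames["midparent"].loc[fid, "p"]),
            alpha=alpha, lfc_threshold=lfc_threshold)
        rows.append({"feature_id": fid, "cross": cross, "pattern": label,
                     "pattern_class": pattern_class(label)})
    return pd.DataFrame(rows)


def run_pattern_analysis(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
    alpha: float = DEFAULT_ALPHA,
    lfc_threshold: float = DEFAULT_LFC,
    seed: int = 0,
) -> pd.DataFrame:
    """All contrasts and pattern calls for one tissue, both crosses."""
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    samples = [s for s in counts.columns if m.loc[s, "tissue"] == tissue]
    sub = counts[samples]
    sf = normalize_size_factors(sub)
    calls = []
    parents = nb_differential_test(sub, m, "WW", "YY", size_factors=sf)
    for cross in CROSSES:
        contrasts = {
            "parents": parents,
            "vs_ww": nb_differential_test(sub, m, cross, "WW",
                                          size_factors=sf),
            "vs_yy": nb_differential_test(sub, m, cross, "YY",
                                          size_factors=sf),
            "midparent": midparent_test(sub, m, cross, seed=seed,
                                        size_factors=sf),
        }
        df = classify_patterns(contrasts, cross, alpha=alpha,
                               lfc_threshold=lfc_threshold)
        df.insert(1, "tissue", tissue)
        calls.append(df)
    return pd.concat(calls, ignore_index=True)


NONADDITIVE_CLASSES = ("dominant", "overdominant", "underdominant")
_WW_BIASED = ("V", "XI")   # cross tracks the WW parent
_YY_BIASED = ("III", "IX")  # cross tracks the YY parent


def summarize_patterns(calls: pd.DataFrame) -> pd.DataFrame:
    """Per tissue x cross counts and proportions of inheritance classes.

    Also splits nonadditive features into breed-common (nonadditive in
    both crosses) vs cross-specific, and counts WW- vs YY-biased
    dominance.
    """
    rows = []
    for (tissue, cross), sub in calls.groupby(["tissue", "cross"]):
        n = len(sub)
        cls = sub["pattern_class"].value_counts()
        nonadd_here = set(
            sub.loc[sub["pattern_class"].isin(NONADDITIVE_CLASSES),
                    "feature_id"])
        other = [c for c in CROSSES if c != cross][0]
        o = calls[(calls["tissue"] == tissue) & (calls["cross"] == other)]
        nonadd_other = set(
            o.loc[o["pattern_class"].isin(NONADDITIVE_CLASSES),
                  "feature_id"])
        common = nonadd_here & nonadd_other
        row = {"tissue": tissue, "cross": cross, "n_features": n}
        for c in ("additive", "dominant", "overdominant", "underdominant",
                  "conserved", "unclassified"):
            row[f"n_{c}"] = int(cls.get(c, 0))
            row[f"prop_{c}"] = cls.get(c, 0) / n if n else np.nan
        row["n_nonadditive"] = len(nonadd_here)
        row["n_breed_common"] = len(common)
        row["n_cross_specific"] = len(nonadd_here - common)
        row["n_WW_biased_dominant"] = int(
            sub["pattern"].isin(_WW_BIASED).sum())
        row["n_YY_biased_dominant"] = int(
            sub["pattern"].isin(_YY_BIASED).sum())
        rows.append(row)
    return pd.DataFrame(rows)
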