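"""CPM normalization, expression filters, SPE calls, genomic region
classification and circRNA / host-gene co-expression.

The expression filters follow the study's thresholds: a feature is
*expressed* with CPM > 0.01 in at least one sample, *tissue-expressed*
with CPM > 0.01 in strictly more than 30% of one tissue's samples, and
*highly expressed* with CPM > 0.01 in at least half of all samples.
Single-parent-expressed (SPE) circRNAs have parental group-mean
CPM >= 1 in one purebred and < 0.1 in the other, evaluated per tissue.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .config import CROSSES, PARENTS

CPM_EXPRESSED = 0.01
SPE_HIGH = 1.0
SPE_LOW = 0.1


class ExpressionError(ValueError):
    pass


def _check_meta(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns \
        else meta
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ExpressionError(f"samples missing from metadata: {missing[:5]}")
    bad = meta.loc[list(counts.columns)]
    if "mapped_reads" not in bad.columns:
        raise ExpressionError("metadata lacks a mapped_reads column")
    nul = bad.index[bad["mapped_reads"].isna()
                    | (bad["mapped_reads"] <= 0)].tolist()
    if nul:
        raise ExpressionError(
            f"nonpositive/missing mapped_reads for samples: {nul[:5]}")
    return bad


def compute_cpm(counts: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Counts per million mapped reads: counts / mapped_reads * 1e6."""
    m = _check_meta(counts, meta)
    depth = m["mapped_reads"].astype(float).to_numpy()
    return counts.astype(float) / depth[None, :] * 1.0e6


def flag_expressed(cpm: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Expressed / tissue-expressed / highly-expressed flags per feature.

    Returns a DataFrame indexed by feature with boolean columns
    ``expressed``, ``highly_expressed`` and one ``tissue_<t>`` per tissue.
    """
    m = _check_meta(cpm, meta)
    det = cpm.to_numpy() > CPM_EXPRESSED
    out = pd.DataFrame(index=cpm.index)
    out["expressed"] = det.any(axis=1)
    n = cpm.shape[1]
    out["highly_expressed"] = det.sum(axis=1) >= int(np.ceil(n / 2))
    for tissue, sub in m.groupby("tissue", sort=True):
        cols = [cpm.columns.get_loc(s) for s in sub.index]
        if not cols:
            raise ExpressionError(f"tissue {tissue} has no samples")
        frac = det[:, cols].sum(axis=1) / len(cols)
        out[f"tissue_{tissue}"] = frac > 0.30
    return out


def classify_spe(
    cpm: pd.DataFrame, meta: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single-parent-expressed labels per feature x tissue.

    A feature is SPE_W in a tissue when its WW group-mean CPM >= 1 and its
    YY group-mean CPM < 0.1 (SPE_Y with the parents swapped).  Also
    returns a per-tissue summary counting SPE features detected in each
    cross (CPM > 0.01 in more than 30% of that cross's samples).
    """
    m = _check_meta(cpm, meta)
    tissues = sorted(m["tissue"].unique())
    labels = pd.DataFrame("none", index=cpm.index, columns=tissues)
    summary_rows = []
    for tissue in tissues:
        sub = m[m["tissue"] == tissue]
        cols = {g: sub.index[sub["group"] == g].tolist()
                for g in (*PARENTS, *CROSSES)}
        for parent in PARENTS:
            if not cols[parent]:
                raise ExpressionError(
                    f"parental group {parent} absent from tissue {tissue}")
        mean_w = cpm[cols["WW"]].mean(axis=1)
        mean_y = cpm[cols["YY"]].mean(axis=1)
        spe_w = (mean_w >= SPE_HIGH) & (mean_y < SPE_LOW)
        spe_y = (mean_y >= SPE_HIGH) & (mean_w < SPE_LOW)
        labels.loc[spe_w, tissue] = "SPE_W"
        labels.loc[spe_y, tissue] = "SPE_Y"
        for cross in CROSSES:
            if not cols[cross]:
                continue
            det = (cpm[cols[cross]] > CPM_EXPRESSED).sum(axis=1) \
                / len(cols[cross]) > 0.30
            summary_rows.append({
                "tissue": tissue, "cross": cross,
                "n_SPE_W": int(spe_w.sum()), "n_SPE_Y": int(spe_y.sum()),
                "SPE_W_in_cross": int((spe_w & det).sum()),
                "SPE_Y_in_cross": int((spe_y & det).sum()),
            })
    return labels, pd.DataFrame(summary_rows)


# ---------------------------------------------------------------------------
# genomic region classification


class GeneModels:
    """Interval lookup over gene bodies and exons, 0-based half-open."""

    def __init__(self, table: pd.DataFrame):
        need = {"gene_id", "chrom", "start", "end", "strand", "feature"}
        if not need <= set(table.columns):
            raise ExpressionError(
                f"gene model table needs columns {sorted(need)}")
        self.genes: dict[str, IntervalTree] = {}
        self.exons: dict[str, IntervalTree] = {}
        for _, row in table.iterrows():
            tree = self.genes if row["feature"] == "gene" else self.exons
            tree.setdefault(row["chrom"], IntervalTree()).addi(
                int(row["start"]), int(row["end"]),
                (row["gene_id"], row["strand"]))


def classify_region(
    circ: pd.Series | dict, models: GeneModels,
) -> tuple[str, str | None]:
    """Classify one circRNA interval against gene models.

    Returns ``(region_class, host_gene)``.  Same-strand exon overlap ->
    exonic; same-strand gene-body overlap without exon overlap -> intronic
    (containment or partial overlap — the latter cannot be antisense or
    intergenic, so it is folded into intronic to keep the four classes a
    partition); overlap only with opposite-strand genes -> antisense; no
    overlap -> intergenic.  Strand '.' matches either strand for
    exonic/intronic but never produces an antisense call.
    """
    chrom, start, end = circ["chrom"], int(circ["start"]), int(circ["end"])
    strand = circ.get("strand", ".") if isinstance(circ, dict) \
        else circ.get("strand", ".")
    if start >= end:
        raise ExpressionError(
            f"malformed interval {chrom}:{start}-{end} (start >= end)")

    def same(s: str) -> bool:
        return strand == "." or s == "." or strand == s

    exon_hits = models.exons.get(chrom, IntervalTree()).overlap(start, end)
    for hit in sorted(exon_hits, key=lambda h: (h.begin, h.data[0])):
        gid, gstrand = hit.data
        if same(gstrand):
            return "exonic", gid
    gene_hits = models.genes.get(chrom, IntervalTree()).overlap(start, end)
    opposite = None
    for hit in sorted(gene_hits, key=lambda h: (h.begin, h.data[0])):
        gid, gstrand = hit.data
        if same(gstrand):
            return "intronic", gid
        if opposite is None:
            opposite = gid
    if opposite is not None:
        # strand '.' matches either strand, so it can only reach here when
        # there was no gene overlap at all; an antisense call therefore
        # always carries a definite strand
        return "antisense", opposite
    return "intergenic", None


def classify_regions(
    annotation: pd.DataFrame, models: GeneModels,
) -> pd.DataFrame:
    """Vectorized wrapper: adds region_class and host_gene columns."""
    out = annotation.copy()
    res = [classify_region(row, models) for _, row in annotation.iterrows()]
    out["region_class"] = [r[0] for r in res]
    out["host_gene"] = [r[1] or "" for r in res]
    return out


# ---------------------------------------------------------------------------
# circRNA / host-gene co-expression


def host_gene_correlation(
    circ_cpm: pd.DataFrame,
    gene_expr: pd.DataFrame,
    annotation: pd.DataFrame,
    meta: pd.DataFrame,
    tissue: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of exonic/intronic circRNAs with their hosts.

    Computed over one tissue's samples.  Returns per-pair results and a
    summary with the fraction of pairs positively correlated at p < 0.05,
    separately for exonic and intronic circRNAs.
    """
    m = _check_meta(circ_cpm, meta)
    samples = m.index[m["tissue"] == tissue].tolist()
    if len(samples) < 5:
        raise ExpressionError(
            f"tissue {tissue} has {len(samples)} samples; need >= 5")
    need = {"circ_id", "region_class", "host_gene"}
    if not need <= set(annotation.columns):
        raise ExpressionError(
            f"annotation needs columns {sorted(need)} "
            "(run classify_regions first)")
    rows = []
    skipped = []
    for _, row in annotation.iterrows():
        if row["region_class"] not in ("exonic", "intronic"):
            continue
        cid, gid = row["circ_id"], row["host_gene"]
        if cid not in circ_cpm.index or gid not in gene_expr.index:
            continue
        x = circ_cpm.loc[cid, samples].to_numpy(float)
        y = gene_expr.loc[gid, samples].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            skipped.append(f"{cid}/{gid}")
            continue
        r, p = stats.spearmanr(x, y)
        rows.append({"circ_id": cid, "host_gene": gid,
                     "region_class": row["region_class"],
                     "spearman_r": float(r), "p": float(p)})
    if skipped:
        warnings.warn(
            f"{len(skipped)} pair(s) with constant expression in "
            f"{tissue} skipped (first: {skipped[0]})")
    pairs = pd.DataFrame(
        rows, columns=["circ_id", "host_gene", "region_class",
                       "spearman_r", "p"])
    summ = []
    for cls in ("exonic", "intronic"):
        sub = pairs[pairs["region_class"] == cls]
        pos = ((sub["spearman_r"] > 0) & (sub["p"] < 0.05)).sum()
        summ.append({
            "tissue": tissue, "region_class": cls, "n_pairs": len(sub),
            "positive_significant": int(pos),
            "fraction_positive_significant":
                pos / len(sub) if len(sub) else np.nan,
        })
    return pairs, pd.DataFrame(summ)


def log_transform_pca(
    mat: pd.DataFrame, n_components: int = 2, log: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """log2(CPM+1), feature centering, PCA of samples by SVD.

    Returns sample coordinates on the first components and the fraction of
    variance explained per component.  A simple depth-stabilizing log is
    used in place of a model-based variance-stabilizing transform; the PCA
    here is descriptive.
    """
    if mat.shape[0] < 2:
        raise ExpressionError("need at least 2 features for PCA")
    if mat.shape[1] < 3:
        raise ExpressionError("need at least 3 samples for PCA")
    X = np.log2(mat.to_numpy(float) + 1.0) if log else mat.to_numpy(float)
    X = X - X.mean(axis=1, keepdims=True)
    # samples as observations: SVD of the centered features x samples matrix
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, S.size)
    coords = (Vt[:k, :].T * S[:k])
    var = S ** 2
    frac = var / var.sum() if var.sum() > 0 else var
    out = pd.DataFrame(coords, index=mat.columns,
                       columns=[f"PC{i+1}" for i in range(k)])
    return out, frac[:k]
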