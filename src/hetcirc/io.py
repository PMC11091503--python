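"""Readers and writers for the pipeline's plain-text interchange formats.

Counts and CPM are TSV with features as rows and samples as columns;
metadata and result tables are TSV/CSV; circRNA annotation is BED6
(0-based half-open); gene models are GTF (1-based closed, converted on
read/write); truth tables are JSON.
"""

from __future__ import annotations

import pandas as pd

from .expression import GeneModels


def write_counts(counts: pd.DataFrame, path: str) -> None:
    counts.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="feature_id")


def write_meta(meta: pd.DataFrame, path: str) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_meta(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_phenotypes(phen: pd.DataFrame, path: str) -> None:
    phen.to_csv(path, index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# annotation


def write_circ_bed(annot: pd.DataFrame, path: str) -> None:
    """BED6: chrom, start, end, name, score ('.'), strand; 0-based."""
    with open(path, "w") as fh:
        for _, row in annot.iterrows():
            fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                     f"{row['circ_id']}\t.\t{row['strand']}\n")


def read_circ_bed(path: str) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append({"circ_id": f[3], "chrom": f[0],
                         "start": int(f[1]), "end": int(f[2]),
                         "strand": f[5] if len(f) > 5 else "."})
    return pd.DataFrame(
        rows, columns=["circ_id", "chrom", "start", "end", "strand"])


def write_gtf(gene_models: pd.DataFrame, path: str) -> None:
    """Write gene/exon features as GTF (converting to 1-based closed)."""
    with open(path, "w") as fh:
        for _, row in gene_models.iterrows():
            attrs = (f'gene_id "{row["gene_id"]}"; '
                     f'gene_name "{row["gene_id"]}";')
            fh.write("\t".join([
                str(row["chrom"]), "hetcirc", str(row["feature"]),
                str(int(row["start"]) + 1), str(int(row["end"])),
                ".", str(row["strand"]), ".", attrs,
            ]) + "\n")


def read_gtf(path: str) -> pd.DataFrame:
    """Read gene/exon features from GTF into the internal 0-based table.

    Uses gffutils for attribute parsing when available records exist;
    only 'gene' and 'exon' features are retained.
    """
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True)
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "exon"):
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        rows.append({"gene_id": gene_id, "chrom": feat.seqid,
                     "start": feat.start - 1, "end": feat.end,
                     "strand": feat.strand, "feature": feat.featuretype})
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand",
                       "feature"])


def load_gene_models(path: str) -> GeneModels:
    return GeneModels(read_gtf(path))
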