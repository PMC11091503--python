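"""Synthetic reciprocal-cross study generator with planted ground truth.

Generates per-bird phenotypes, per-tissue circRNA (back-spliced junction)
and gene count matrices, and toy genome annotation, such that every
downstream stage of the pipeline — residual feed intake, mid-parent
heterosis, expression filters, inheritance-pattern classification, module
detection and network construction — has a fully known truth to recover.

All randomness flows from one seed, expanded into fixed per-stage
substreams so stages can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CROSSES,
    GROUPS,
    PARENTS,
    ConfigError,
    SimConfig,
)

# fixed substream indices: seed + stage id -> independent generator
_STAGE_PHENOTYPES = 0
_STAGE_FEATURES = 1
_STAGE_COUNTS = 2
_STAGE_ANNOTATION = 3

#: Roman-numeral inheritance patterns grouped by class.
PATTERNS_BY_CLASS: dict[str, tuple[str, ...]] = {
    "additive": ("IV", "X"),
    "dominant": ("III", "V", "IX", "XI"),
    "overdominant": ("I", "II", "XII"),
    "underdominant": ("VI", "VII", "VIII"),
}
CLASS_OF_PATTERN: dict[str, str] = {
    p: c for c, ps in PATTERNS_BY_CLASS.items() for p in ps
}

_REGION_CLASSES = ("exonic", "intronic", "antisense", "intergenic")


def _rng(seed: int, stage: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, stage, extra])


@dataclass
class TruthTable:
    """Planted ground truth for one simulated study.

    ``phenotype_heterosis``: one row per trait x cross with the planted
    fractional mid-parent deviation.  ``bird_effects``: the part of each
    bird's feed intake unexplained by the regression predictors (noise plus
    nonadditive shift) — the generative counterpart of RFI.  ``features``:
    one row per generated feature with its pattern label (planted
    identically for both crosses), tissue mask, SPE label, module
    membership, host gene and genomic region class.
    """

    phenotype_heterosis: pd.DataFrame
    bird_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["bird_id", "true_residual"]))
    features: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_json(self, path: str) -> None:
        payload = {
            "phenotype_heterosis": self.phenotype_heterosis.to_dict("records"),
            "bird_effects": self.bird_effects.to_dict("records"),
            "features": self.features.to_dict("records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            phenotype_heterosis=pd.DataFrame(payload["phenotype_heterosis"]),
            bird_effects=pd.DataFrame(payload["bird_effects"]),
            features=pd.DataFrame(payload["features"]),
        )


# ---------------------------------------------------------------------------
# phenotypes


def _deterministic_dfc(cfg: SimConfig, group: str) -> float:
    """Expected feed intake of a group from the generative linear model."""
    tp = cfg.trait_params
    b0, b1, b2, b3 = tp.dfc_coef
    bw = _group_mean(cfg, "BW", group)
    return (b0 + b1 * bw ** 0.75 + b2 * _group_mean(cfg, "BWG", group)
            + b3 * _group_mean(cfg, "DEM", group))


def _group_mean(cfg: SimConfig, trait: str, group: str) -> float:
    tp = cfg.trait_params
    base = {"BW": tp.bw_mean, "BWG": tp.bwg_mean, "DEM": tp.dem_mean}[trait]
    if group in PARENTS:
        return float(base[group])
    mp = 0.5 * (base["WW"] + base["YY"])
    return mp * (1.0 + cfg.delta_for(trait, group))


def generate_phenotypes(
    config: SimConfig,
) -> tuple[pd.DataFrame, TruthTable]:
    """Draw per-bird phenotypes from the generative feed-intake model.

    BW, BWG and DEM are drawn from group-level normals (cross groups at the
    mid-parent mean scaled by the configured heterosis delta); DFC is the
    linear model b0 + b1*MBW + b2*BWG + b3*DEM plus a cross-specific
    heterosis shift and Gaussian noise.  The noise-plus-shift component is
    recorded per bird as the true feed-intake residual.
    """
    config.validate()
    tp = config.trait_params
    if tp.bw_sd < 0 or tp.bwg_sd < 0 or tp.dem_sd < 0 or tp.dfc_noise_sd < 0:
        raise ConfigError("trait standard deviations must be nonnegative")
    rng = _rng(config.seed, _STAGE_PHENOTYPES)
    b0, b1, b2, b3 = tp.dfc_coef
    mp_dfc = 0.5 * (_deterministic_dfc(config, "WW")
                    + _deterministic_dfc(config, "YY"))

    frames = []
    effects = []
    for group in GROUPS:
        n = int(config.group_sizes.get(group, 0))
        if n == 0:
            continue
        bw = np.clip(rng.normal(_group_mean(config, "BW", group),
                                tp.bw_sd, n), 0.2, None)
        bwg = rng.normal(_group_mean(config, "BWG", group), tp.bwg_sd, n)
        dem = np.clip(rng.normal(_group_mean(config, "DEM", group),
                                 tp.dem_sd, n), 1.0, None)
        shift = (config.delta_for("DFC", group) * mp_dfc
                 if group in CROSSES else 0.0)
        noise = rng.normal(0.0, tp.dfc_noise_sd, n)
        dfc = b0 + b1 * bw ** 0.75 + b2 * bwg + b3 * dem + shift + noise
        ids = [f"{group}_{i:04d}" for i in range(n)]
        frames.append(pd.DataFrame({
            "bird_id": ids, "group": group,
            "BW": bw, "BWG": bwg, "DEM": dem, "DFC": dfc,
        }))
        effects.append(pd.DataFrame({
            "bird_id": ids, "true_residual": shift + noise,
        }))
    if not frames:
        raise ConfigError("no birds requested")
    phenotypes = pd.concat(frames, ignore_index=True)

    rows = []
    traits = sorted(set(config.heterosis_delta) | {"DFC", "DEM", "BW", "BWG"})
    for trait in traits:
        for cross in CROSSES:
            rows.append({"trait": trait, "cross": cross,
                         "delta": config.delta_for(trait, cross)})
    truth = TruthTable(
        phenotype_heterosis=pd.DataFrame(rows),
        bird_effects=pd.concat(effects, ignore_index=True),
    )
    return phenotypes, truth


# ---------------------------------------------------------------------------
# feature universe (shared by counts and annotation so they agree)


def feature_table(config: SimConfig) -> pd.DataFrame:
    """Deterministic per-feature truth attributes for a config.

    Derived from the config seed alone, so counts and annotation generated
    separately still describe the same feature universe.
    """
    rng = _rng(config.seed, _STAGE_FEATURES)
    n_circ, n_gene = config.n_circ, config.n_gene
    ids = ([f"circ_{i:04d}" for i in range(n_circ)]
           + [f"gene_{i:04d}" for i in range(n_gene)])
    kind = ["circ"] * n_circ + ["gene"] * n_gene
    n = n_circ + n_gene
    lo, hi = config.baseline_mean_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), n))

    # tissue masks
    tissue = np.array(["all"] * n, dtype=object)
    specific = rng.random(n) < config.tissue_specific_fraction
    tissue[specific] = rng.choice(config.tissues, specific.sum())

    # inheritance patterns: multinomial over classes, remainder conserved
    classes = list(config.pattern_proportions)
    probs = [config.pattern_proportions[c] for c in classes]
    probs.append(max(0.0, 1.0 - sum(probs)))
    classes.append("conserved")
    drawn = rng.choice(len(classes), n, p=np.asarray(probs) / sum(probs))
    # within each class, roman labels are planted in balanced proportions
    # (stratified round-robin, shuffled) so every rule variant is covered
    pattern = np.array(["conserved"] * n, dtype=object)
    for k, cls in enumerate(classes):
        if cls == "conserved":
            continue
        idx = np.flatnonzero(drawn == k)
        labels = np.resize(PATTERNS_BY_CLASS[cls], idx.size)
        rng.shuffle(labels)
        pattern[idx] = labels

    # SPE circRNAs drawn from conserved circ features so planted pattern
    # proportions are untouched
    spe = np.array(["none"] * n, dtype=object)
    conserved_circ = np.flatnonzero(
        (np.arange(n) < n_circ) & (pattern == "conserved"))
    n_spe = int(round(config.spe_fraction * n_circ))
    n_spe = min(n_spe, conserved_circ.size)
    if n_spe:
        picked = rng.choice(conserved_circ, n_spe, replace=False)
        spe[picked] = rng.choice(["SPE_W", "SPE_Y"], n_spe)

    # planted module members: expressed in the module tissue, not SPE
    module = np.zeros(n, dtype=bool)
    ms = config.module_spec
    elig = (np.isin(tissue, ["all", ms.tissue])) & (spe == "none")
    circ_pool = np.flatnonzero(elig & (np.arange(n) < n_circ))
    gene_pool = np.flatnonzero(elig & (np.arange(n) >= n_circ))
    n_mc = min(ms.n_circ_members, circ_pool.size)
    n_mg = min(ms.n_members - n_mc, gene_pool.size)
    if n_mc:
        module[rng.choice(circ_pool, n_mc, replace=False)] = True
    if n_mg:
        module[rng.choice(gene_pool, n_mg, replace=False)] = True

    # genomic region class and host gene for circRNAs
    region = np.array([""] * n, dtype=object)
    host = np.array([""] * n, dtype=object)
    if n_circ and n_gene:
        p_ex = 0.75 * config.host_fraction
        p_in = 0.25 * config.host_fraction
        rest = max(0.0, 1.0 - config.host_fraction)
        reg = rng.choice(_REGION_CLASSES, n_circ,
                         p=[p_ex, p_in, rest / 2, rest / 2])
        region[:n_circ] = reg
        hosted = np.flatnonzero(reg != "intergenic")
        gene_ids = np.array(ids[n_circ:], dtype=object)
        if hosted.size <= n_gene:
            host[hosted] = rng.choice(gene_ids, hosted.size, replace=False)
        else:
            host[hosted] = rng.choice(gene_ids, hosted.size, replace=True)
    elif n_circ:
        region[:n_circ] = "intergenic"

    return pd.DataFrame({
        "feature_id": ids, "kind": kind, "baseline": baseline,
        "tissue": tissue, "pattern": pattern,
        "pattern_class": [CLASS_OF_PATTERN.get(p, "conserved")
                          for p in pattern],
        "spe": spe, "module_member": module,
        "host_gene": host, "region_class": region,
    })


# ---------------------------------------------------------------------------
# counts


def _pattern_offsets(pattern: str, e: float) -> tuple[float, float, float]:
    """Planted log2 offsets (WW, YY, cross) realising a pattern at effect e.

    The cross offset applies to both WY and YW (patterns are planted
    breed-common).  Additive crosses sit at the linear-scale mid-parent.
    """
    mid = float(np.log2((2.0 ** e + 1.0) / 2.0))
    table = {
        "IV": (e, 0.0, mid), "X": (0.0, e, mid),
        "V": (0.0, e, 0.0), "XI": (e, 0.0, e),
        "III": (0.0, e, e), "IX": (e, 0.0, 0.0),
        "I": (0.0, 0.0, e), "II": (e, 0.0, 2 * e), "XII": (0.0, e, 2 * e),
        "VII": (e, e, 0.0), "VI": (2 * e, e, 0.0), "VIII": (e, 2 * e, 0.0),
        "conserved": (0.0, 0.0, 0.0),
    }
    return table[pattern]


def _exact_corr_factor(
    target: np.ndarray, r: float, rng: np.random.Generator,
) -> np.ndarray:
    """A vector with exact in-sample Pearson correlation ``r`` to target.

    Gram-Schmidt construction: standardize the target, draw noise,
    orthogonalize against the intercept and the target, recombine.  Returns
    a mean-zero, unit-SD vector.
    """
    n = target.size
    z = target - target.mean()
    nz = np.linalg.norm(z)
    if nz == 0:
        raise ConfigError("cannot couple a module to a constant residual")
    z = z / nz
    g = rng.normal(size=n)
    g = g - g.mean()
    g = g - (g @ z) * z
    ng = np.linalg.norm(g)
    if ng == 0:  # pathological draw; retry deterministically
        g = np.arange(n, dtype=float)
        g = g - g.mean()
        g = g - (g @ z) * z
        ng = np.linalg.norm(g)
    g = g / ng
    f = r * z + np.sqrt(max(0.0, 1.0 - r * r)) * g
    return f / f.std(ddof=0)


_SPE_HIGH = 150.0  # mean BSJ count in the expressing parent (CPM ~ 5 at 30M)
_SPE_LOW = 0.5     # mean in the silent parent (CPM ~ 0.017)


def generate_counts(
    config: SimConfig,
    phenotypes: pd.DataFrame,
    truth: TruthTable | None = None,
    noise: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate circRNA and gene count matrices for every tissue.

    Returns ``(circ_counts, gene_counts, meta, truth)`` where the count
    matrices are features x samples over all tissues, ``meta`` holds
    sample id, bird id, tissue, group and total mapped reads, and the truth
    table gains the per-feature attributes.

    Counts are negative binomial with Var = mu + alpha*mu^2.  Group mean
    multipliers encode the planted inheritance pattern; SPE features are
    near-silent in one parent; tissue-specific features have zero mean
    outside their tissue; planted-module members load on a latent factor
    constructed with the exact configured in-sample correlation to the
    birds' true feed-intake residuals; exonic/intronic circRNAs share a
    log-scale latent factor with their host gene.  With ``noise=False``
    the expected means are returned instead of draws (non-integer).
    """
    config.validate()
    feats = feature_table(config)
    if truth is None:
        truth = TruthTable(phenotype_heterosis=pd.DataFrame(
            columns=["trait", "cross", "delta"]))
    truth.features = feats
    if truth.bird_effects.empty:
        raise ConfigError(
            "phenotypes must be generated first (module members couple "
            "to the birds' true residuals)")
    resid = truth.bird_effects.set_index("bird_id")["true_residual"]

    ms = config.module_spec
    n_circ, n_gene = config.n_circ, config.n_gene
    n_feat = n_circ + n_gene
    is_circ = np.arange(n_feat) < n_circ
    base_log2 = np.log2(feats["baseline"].to_numpy())
    e = config.lfc_effect
    offsets = np.array([_pattern_offsets(p, e)
                        for p in feats["pattern"]])  # (n_feat, 3)
    group_off = {
        "WW": offsets[:, 0], "YY": offsets[:, 1],
        "WY": offsets[:, 2], "YW": offsets[:, 2],
    }
    spe = feats["spe"].to_numpy()
    member = feats["module_member"].to_numpy()
    host = feats["host_gene"].to_numpy()
    gene_pos = {fid: j for j, fid in enumerate(feats["feature_id"])
                if fid.startswith("gene_")}
    coupled = [(i, gene_pos[host[i]]) for i in range(n_circ)
               if host[i] and feats.loc[i, "region_class"]
               in ("exonic", "intronic")]

    by_group = {g: phenotypes.loc[phenotypes["group"] == g, "bird_id"]
                .tolist() for g in GROUPS}
    alpha = config.nb_dispersion
    r_nb = 1.0 / alpha

    circ_cols: dict[str, np.ndarray] = {}
    gene_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for t_idx, tissue in enumerate(config.tissues):
        rng = _rng(config.seed, _STAGE_COUNTS, t_idx)
        k = config.birds_for(tissue)
        samples: list[tuple[str, str, str]] = []  # (sample_id, bird, group)
        for group in GROUPS:
            birds = by_group.get(group, [])
            if len(birds) < k:
                raise ConfigError(
                    f"group {group} has {len(birds)} birds; "
                    f"{k} needed for tissue {tissue}")
            for j, bird in enumerate(birds[:k]):
                samples.append((f"{tissue[:3]}_{group}_{j:02d}", bird, group))
        n_s = len(samples)
        groups_arr = [s[2] for s in samples]

        log2mu = np.empty((n_feat, n_s))
        for s_i, g in enumerate(groups_arr):
            log2mu[:, s_i] = base_log2 + group_off[g]

        # SPE overrides: absolute group means independent of baseline
        for lab, hi_g, lo_g in (("SPE_W", "WW", "YY"), ("SPE_Y", "YY", "WW")):
            rows = np.flatnonzero(spe == lab)
            if not rows.size:
                continue
            for s_i, g in enumerate(groups_arr):
                mean = (_SPE_HIGH if g == hi_g else
                        _SPE_LOW if g == lo_g else _SPE_HIGH / 2.0)
                log2mu[rows, s_i] = np.log2(mean)

        # planted co-expression module tied to the feed-intake residual
        if tissue == ms.tissue and member.any():
            v = resid.loc[[s[1] for s in samples]].to_numpy(float)
            f = _exact_corr_factor(v, ms.target_r, rng)
            log2mu[member, :] += ms.effect_log2 * f[None, :]

        # circRNA / host-gene latent coupling
        if coupled:
            rho = config.host_coupling_rho
            sd_h = config.host_coupling_sd
            u = rng.normal(size=(len(coupled), n_s))
            w = rng.normal(size=(len(coupled), n_s))
            mix = rho * u + np.sqrt(max(0.0, 1.0 - rho * rho)) * w
            for p_i, (ci, gi) in enumerate(coupled):
                log2mu[gi, :] += sd_h * u[p_i]
                log2mu[ci, :] += sd_h * mix[p_i]

        mu = np.exp2(log2mu)
        mask = (feats["tissue"].to_numpy() != "all") & \
               (feats["tissue"].to_numpy() != tissue)
        mu[mask, :] = 0.0

        if noise:
            counts = np.zeros_like(mu)
            pos = mu > 0
            counts[pos] = rng.negative_binomial(
                r_nb, r_nb / (r_nb + mu[pos]))
        else:
            counts = mu

        depth = rng.lognormal(0.0, 0.05, n_s) * config.mean_mapped_reads
        for s_i, (sid, bird, group) in enumerate(samples):
            col = counts[:, s_i]
            mapped = int(max(np.round(depth[s_i]), np.ceil(col.sum())))
            circ_cols[sid] = col[is_circ]
            gene_cols[sid] = col[~is_circ]
            meta_rows.append({
                "sample_id": sid, "bird_id": bird, "tissue": tissue,
                "group": group, "mapped_reads": mapped,
            })

    circ_ids = feats.loc[is_circ, "feature_id"].tolist()
    gene_ids = feats.loc[~is_circ, "feature_id"].tolist()
    circ_counts = pd.DataFrame(circ_cols, index=circ_ids)
    gene_counts = pd.DataFrame(gene_cols, index=gene_ids)
    if noise:
        circ_counts = circ_counts.astype(np.int64)
        gene_counts = gene_counts.astype(np.int64)
    meta = pd.DataFrame(meta_rows)
    return circ_counts, gene_counts, meta, truth


# ---------------------------------------------------------------------------
# annotation

_GENE_SPACING = 10_000
_EXON_LEN = 300
_INTRON_LEN = 700
_GENES_PER_CHROM = 400


def generate_annotation(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build toy gene models and circRNA intervals with known region classes.

    Genes are laid on chromosomes at fixed spacing, three exons each,
    alternating strands.  Each circRNA is placed to realize its planted
    region class exactly: inside an exon (same strand), inside the first
    intron (same strand), overlapping its host on the opposite strand
    (antisense), or in the gap between genes (intergenic).

    Returns ``(circ_annotation, gene_models)``; ``circ_annotation`` uses
    0-based half-open intervals, ``gene_models`` has one row per gene/exon
    feature, also 0-based half-open (conversion to 1-based closed GTF
    happens at write time).
    """
    config.validate()
    feats = feature_table(config)
    rng = _rng(config.seed, _STAGE_ANNOTATION)

    gene_rows = []
    gene_coord: dict[str, tuple[str, int, int, str]] = {}
    gene_ids = feats.loc[feats["kind"] == "gene", "feature_id"].tolist()
    for j, gid in enumerate(gene_ids):
        chrom = f"chr{j // _GENES_PER_CHROM + 1}"
        start = 1_000 + (j % _GENES_PER_CHROM) * _GENE_SPACING
        strand = "+" if j % 2 == 0 else "-"
        exon_starts = [start + k * (_EXON_LEN + _INTRON_LEN)
                       for k in range(3)]
        end = exon_starts[-1] + _EXON_LEN
        gene_rows.append({"gene_id": gid, "chrom": chrom, "start": start,
                          "end": end, "strand": strand, "feature": "gene"})
        for es in exon_starts:
            gene_rows.append({"gene_id": gid, "chrom": chrom, "start": es,
                              "end": es + _EXON_LEN, "strand": strand,
                              "feature": "exon"})
        gene_coord[gid] = (chrom, start, end, strand)
    gene_models = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand",
                            "feature"])

    circ_rows = []
    circ = feats[feats["kind"] == "circ"]
    per_host_seen: dict[str, int] = {}
    for _, row in circ.iterrows():
        cls = row["region_class"]
        if cls != "intergenic" and row["host_gene"] in gene_coord:
            chrom, gstart, gend, gstrand = gene_coord[row["host_gene"]]
        elif gene_coord:
            gid = gene_ids[int(rng.integers(len(gene_ids)))]
            chrom, gstart, gend, gstrand = gene_coord[gid]
            cls = "intergenic"
        else:
            chrom, gstart, gstrand = "chr1", 1_000, "+"
            cls = "intergenic"
        # stagger multiple circRNAs sharing a host so intervals differ
        seen = per_host_seen.get(row["host_gene"] or chrom, 0)
        per_host_seen[row["host_gene"] or chrom] = seen + 1
        jitter = 4 * seen
        if cls == "exonic":
            start = gstart + 20 + min(jitter, 100)
            end = gstart + _EXON_LEN - 20
            strand = gstrand
        elif cls == "intronic":
            start = gstart + _EXON_LEN + 50 + min(jitter, 100)
            end = gstart + _EXON_LEN + _INTRON_LEN - 50
            strand = gstrand
        elif cls == "antisense":
            start = gstart + 100 + min(jitter, 100)
            end = gend - 100
            strand = "-" if gstrand == "+" else "+"
        else:  # intergenic: safely inside the inter-gene gap
            start = gstart + 2 * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN \
                + 2_000 + min(jitter, 1000)
            end = start + 350
            strand = "+" if rng.random() < 0.5 else "-"
        circ_rows.append({"circ_id": row["feature_id"], "chrom": chrom,
                          "start": int(start), "end": int(end),
                          "strand": strand})
    circ_annotation = pd.DataFrame(
        circ_rows, columns=["circ_id", "chrom", "start", "end", "strand"])
    return circ_annotation, gene_models
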