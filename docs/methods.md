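# Methods

`hetcirc` re-implements, as a tested pipeline over synthetic data with
planted truth, an analysis chain linking tissue-specific circRNA
expression to heterosis for feed intake and efficiency in a two-breed
reciprocal chicken cross (White Leghorn x Beijing You; purebreds WW and
YY, cross directions WY and YW). This note records the models, the
defaults and why they were chosen, and what the synthetic data does and
does not emulate.

## Phenotype model and residual feed intake

Per bird the generator draws body weight (BW, kg), daily body-weight
gain (BWG, g/d) and daily egg mass (DEM, g/d) from group-level normals;
cross groups sit at the mid-parent mean scaled by a configurable
fractional heterosis delta. Daily feed consumption is the linear model

    DFC = b0 + b1*MBW + b2*BWG + b3*DEM + shift_cross + N(0, sigma)

with MBW = BW^0.75 (metabolic body weight) and `shift_cross` a direct
feed-intake deviation (the generative counterpart of RFI heterosis).
Defaults: b = (35, 30, 0.5, 0.4), sigma = 3 g/d, BW means 1.55/1.85 kg,
DEM means 48/38 g/d, chosen so that group mean DFC lands inside
90.84–103.27 g/d — a realistic laying-hen range. The within-group
variances are package defaults, not measured population values: the
study populations this emulates report only trait ranges.

Residual feed intake is the residual of the ordinary least-squares
regression of DFC on MBW, BWG and DEM, pooled over all four groups (no
group indicators). OLS residual identities (zero sum, orthogonality to
each predictor) hold by construction and are tested to 1e-10.

## Mid-parent heterosis test

H = (F̄ − MP)/MP with MP = (P̄_W + P̄_Y)/2, computed per cross direction
against the same parental means. The default significance test is

    t = (F̄ − MP) / se,  se² = s_F²/n + s_W²/(4 n_W) + s_Y²/(4 n_Y)

with Welch–Satterthwaite degrees of freedom and a two-sided Student
p-value. The parental variance terms matter: treating MP as a known
constant (a one-sample t using only the cross's variance) rejects ~11%
of true nulls at the 5% level when the parental lines are samples of
comparable size, because the mid-parent estimate carries half the
sampling error of the cross mean. Calibration under the generator's
null (all deltas zero, 220 birds/group, 2000 replicates) is 4.9–5.8%.
A literal transcription of the alternative published formula
t = H²·[Σ(Fi−F̄)²/(n−1)] / [(P̄_W+P̄_Y)·n] is available via
`literal=True`; it has no type-I-error guarantee and exists for
comparison only. H is scale-invariant but not shift-invariant; for
traits with near-zero mid-parent mean (RFI itself) H is reported but
numerically unstable — the t-test remains well-defined.

## Counts and expression

Counts are negative binomial with Var = μ + αμ², α constant per run
(default 0.1 — a typical biological coefficient of variation of ~30%).
CPM = count / mapped reads × 10⁶ using the per-sample mapped-read
totals carried in the metadata. Filters: expressed = CPM > 0.01 in at
least one sample; tissue-expressed = CPM > 0.01 in strictly more than
30% of one tissue's samples; highly expressed = CPM > 0.01 in at least
⌈N/2⌉ samples. Single-parent expression is decided on parental
group-mean CPM per tissue (mean ≥ 1 in one purebred, < 0.1 in the
other); "detected in a cross" applies the tissue-expressed rule to the
cross's samples. Thresholds are strict inequalities exactly as printed
above.

Genomic region classes partition every circRNA: same-strand exon
overlap → exonic; same-strand gene-body overlap without exon overlap →
intronic (partial-overlap cases are folded into intronic so the four
classes stay a partition); overlap only with opposite-strand genes →
antisense (host = the overlapped gene); no overlap → intergenic. BED
inputs are 0-based half-open, GTF 1-based closed; everything is
normalized internally to 0-based half-open. Strand '.' matches either
strand for exonic/intronic calls and never yields antisense.

PCA uses log2(CPM+1) with per-feature centering and an SVD; this is a
descriptive stand-in for a model-based variance-stabilizing transform.

## Differential expression and inheritance patterns

Size factors are DESeq-style median-of-ratios against a geometric-mean
pseudo-reference over features positive in all samples (total-count
fallback with a warning otherwise). The per-feature test is a Wald test
on log2FC = log2((μ̂_A+0.5)/(μ̂_B+0.5)) of normalized counts, with a
pooled within-group method-of-moments dispersion floored at 1e-8 and a
t reference on n_A+n_B−2 df — the t reference, not the normal, keeps
the type-I error near nominal at n = 8 per group (measured 5.2–5.8% on
null NB data). There is no dispersion shrinkage, independent filtering,
or multiple-testing adjustment: pattern classification operates on raw
p-values, and the deliberately minimal model is validated by
calibration and planted-truth recovery rather than by agreement with a
reference implementation.

The cross-vs-mid-parent contrast averages the normalized counts of
randomly paired WW/YY samples (pairing under the run seed, truncating
to the smaller parent group) and tests the cross against these
pseudo-samples. The pseudo-group variance is modelled by propagating
the NB model through the averaging, Var(MP) = (Var(W)+Var(Y))/4;
modelling the pseudo-samples as NB at their own mean overstates their
variance by ~40% and costs real power on the dominance patterns.

Pattern rules (four contrasts: parents, cross-vs-WW, cross-vs-YY,
cross-vs-midparent; significance = p < 0.05, direction from the sign of
log2FC), applied in order:

1. additivity — parents differ, cross ≈ mid-parent: IV if WW > YY
   else X;
2. dominance — cross ≈ WW and below/above YY: V/XI; cross ≈ YY and
   above/below WW: III/IX;
3. overdominance — cross above both parents: II (WW the high parent),
   XII (YY the high parent), I (parents equal); underdominance — cross
   below both: VI, VIII, VII correspondingly;
4. otherwise conserved (nothing significant) or unclassified.

Two deliberate choices. First, the rules gate on p alone; the
|log2FC| > 1 condition defines "differentially expressed" for summary
proportions but is not applied inside the rules — the cross-vs-midparent
gap for "cross = high parent" dominance is log2(2·2^e/(2^e+1)) ≤ 1 for
any parental gap e, so a fold-change gate there would make patterns
III/XI structurally impossible. Second, first-match precedence makes
the mapping a partition; exhaustive enumeration of all 3⁴
significance/direction states confirms it, and relabeling WW↔YY
induces the involution IV↔X, V↔IX, XI↔III, II↔XII, VI↔VIII with I and
VII fixed — note V pairs with IX (and XI with III): relabeling the
parents turns "tracks WW, low side" into "tracks YY, low side".

Recovery at planted |log2FC| = 2, dispersion 0.1, n = 8 (baselines
50–500, balanced roman labels within each class): ≥ 93% for additive,
100% for over/underdominance, 83–87% for dominance — the III/XI
variants are intrinsically harder because their distance to the
mid-parent is only ~0.7 log2 units. Additive features are essentially
never called overdominant.

## Co-expression modules

Per tissue, circRNAs with MAD > 0 and the top 25% of genes by MAD enter
one joint matrix. Signed adjacency a_ij = ((1+cor_ij)/2)^β; β is the
smallest power in 1..30 whose connectivity distribution fits a
scale-free law (R² ≥ 0.85 over ≥ 10 log-binned points, negative slope),
falling back to 18/16/14 for fewer than 20/30/40 samples and 12
otherwise. The topological overlap TOM_ij = (l_ij + a_ij)/(min(k_i,k_j)
+ 1 − a_ij) is verified against a triple-loop oracle to 1e-12.

Modules come from average-linkage clustering on 1 − TOM with a
static-height cut chosen by scanning: the lowest height maximizing the
number of clusters with ≥ 50 members. A fixed quantile cut cannot work
here — once unrelated background features attach near the dendrogram
top, all late merges bunch within the top 1% of heights. Two cleanup
stages follow, mirroring the reference algorithm's label-assignment
steps: unassigned features with eigengene correlation ≥ 0.5 join their
closest module; after eigengene merging (modules merged while any pair
correlates ≥ 0.75; the literal "0.25" reading of the merge rule is
available via `merge_cor=0.25`), members with kME < 0.3 are pruned and
modules falling below 50 members dissolve. Planted two-block designs
(60+60, with or without background noise) are recovered at ARI 1.0 and
a planted 30-feature block stays unassigned.

The module eigengene is the first right singular vector of the
row-standardized module matrix, sign-aligned with the mean profile.
Module–trait association is the Pearson correlation of the eigengene
with MBW, BWG, DEM, DFC and RFI, with the Student transform
t = r√(n−2)/√(1−r²) (two-sided, significance at p < 0.01).

The planted module couples member expression to each bird's true
feed-intake residual through a latent factor constructed by
Gram–Schmidt to have *exactly* the configured in-sample correlation
(default −0.62) with the standardized residuals; member log2-means load
on it with amplitude 2.0. Exact construction makes the target
analytically controllable: the detected eigengene correlates with
fitted RFI at −0.59 to −0.63 under defaults and is declared significant
in ~100/100 seeds at n = 32.

## Candidate networks

Within modules significant for RFI or DFC (p < 0.01), every co-assigned
circRNA × gene pair is tested by Spearman correlation over the tissue ×
cross sample subset; an edge is stored iff r > 0.6 and p < 0.05. For
n ≤ 9 without ties the p-value is the exact two-sided permutation
probability (full enumeration of the rank-permutation null, cached per
n); the t approximation is used otherwise. At n = 8 the exact criterion
binds at |ρ| ≥ 0.738, so stored edges always exceed the r > 0.6 gate.
Candidate pairs additionally require both endpoints nonadditive
(dominant, over- or underdominant) in the edge's cross; `same_pattern`
flags identical labels and `cross_divergent` flags circRNAs whose
pattern differs between WY and YW — the signature consistent with
reciprocal crosses showing opposite RFI heterosis. Exports are GraphML
and SIF.

## What the generator emulates, and what it does not

Emulated: the 4 group × 4 tissue design (8 birds/group/tissue, 6 for
ovary), ~900 phenotyped hens in realistic trait ranges, NB counts with
planted inheritance patterns (balanced roman labels within each class),
tissue-restricted expression, single-parent-expressed circRNAs,
circRNA/host-gene log-scale coupling (ρ = 0.7 by default), a planted
RFI-linked module, and per-sample sequencing depths near 30M reads.

Not emulated: read-level artifacts (alignment, BSJ detection errors,
multimapping), isoform structure, GC/length biases, batch effects,
correlated dispersion across features, and any real genome coordinates
(the toy genome has uniform three-exon genes). Passing the planted
recovery tests therefore demonstrates correctness of the statistical
machinery under the stated generative model, not performance on real
libraries.

## Numerical notes and degenerate inputs

- All randomness flows from one seed through fixed per-stage
  substreams; fixed seed ⇒ byte-identical outputs.
- Fold changes use a 0.5 pseudo-normalized-count; all-zero features get
  p = 1, log2FC = 0.
- Boundary conventions: "more than 30%" strict, "at least half"
  inclusive (⌈N/2⌉), significance thresholds strict (< 0.05, > 0.6).
- Constant expression vectors: skipped with a warning (host
  correlation), reported missing (module–trait), or error (eigengene of
  an all-constant module).
- Rank-deficient RFI designs raise an error naming the collinear
  column; unequal parental group sizes in the mid-parent test pair down
  to the smaller group with a warning.

## Problem sizes used in the shipped checks

Calibration runs use 1000–2000 replicates (heterosis null at 220
birds/group; NB null at 2000 features, 8 vs 8); recovery runs use
1800 features × 32 samples (patterns), 150 × 32 (module blocks), and
100 seeds × 160 features (module–trait power). These sizes give
binomial standard errors well inside the asserted bands while keeping
the whole suite under a minute of compute.
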