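# Methods

This note records the models, parameter choices and numerical decisions
behind `lungcomp`, and what the synthetic validation does and does not
demonstrate about real data.

## Synthetic cohort model

The generator emulates the statistical structure of an NSCLC single-cell
+ bulk atlas at desk scale, with full ground truth.

**Genome and counts.** A gene catalog of 5 chromosomes x 400 genes
(2000 genes) stands in for the expressed-gene panel that windowed CNV
inference would retain from a full transcriptome. Counts are negative
binomial with per-gene base means drawn log-normal(ln 1.0, 1.0) — about
3.3k counts per cell over the panel, mid-range 10x depth for a panel of
moderately expressed genes — and NB size (inverse dispersion) r = 0.5
(`var = mu + mu²/r`; `r = inf` gives the Poisson limit used in tests).
Per-cell library sizes vary log-normally with sigma 0.2.

**Cell identity.** 12 cell types (8 non-immune: AT1, AT2, Basal, Cilia,
Club, EC, Fib, NE; 4 immune: B, CD4, CD8, Mph) each own a disjoint set of
25 marker genes whose means are multiplied 8x in cells of that type.
Markers are scattered uniformly over the genome rather than laid out as
contiguous blocks: contiguous marker runs would imitate CNV segments in
windowed profiles and confound malignancy calling with cell-type
identity, which no analysis should conflate.

**Malignancy and subclones.** Malignant AT2 (LUAD samples) and basal
(LUSC samples) populations carry subclone-specific dosage events that
multiply expected expression gene-wise (expression proportional to copy
number). Default events are chromosome-scale — a whole-chromosome 2x
amplification shared within a lineage plus an arm-scale private second
event (2x gain or 0.5x loss) per subclone, ~30% of the genome per
subclone — matching the whole-chromosome-arm amplification pattern
typical of NSCLC epithelial malignancies. Non-malignant cells carry no
dosage effect.

**Bulk cohort.** Each bulk sample's true composition is a Dirichlet draw
from its group's archetype concentrations (dominant type 50, others 1;
a deliberately heterogeneous "mixed" archetype uses 3 everywhere);
20 samples per group, 5 groups. The expected profile is the mixture
`profiles @ w` of per-type reference profiles with gene-wise log-normal
noise (sigma 0.2; sigma 0 gives exact mixtures). Survival times are
exponential with group hazards (1.0 for the poor-prognosis Fib-high
archetype vs 0.25 elsewhere — hazard ratio 4, chosen so the end-to-end
chain has ~95% per-replicate log-rank power at this cohort size);
censoring is independent with expected fraction 0.2.

**What the generator does not model:** doublets, ambient RNA, batch
effects, UMI saturation, immune-repertoire structure, gene–gene
correlation beyond cell identity and dosage, allele-specific effects.
Passing tests therefore demonstrate the *inference chain's* correctness
and calibration under a faithful but idealized data-generating process,
not robustness to every real-data artifact.

## CNV inference

Expression scale is log2(counts-per-100k + 1); on this scale a dosage
doubling shifts a fully covered window by ~1 (attenuated slightly by the
pseudocount at low expression). The profile pipeline is:

1. order genes by (chromosome, order_index) and drop all-zero genes
   (erroring if a chromosome loses all genes);
2. center gene-wise on the reference-cell mean;
3. average over sliding windows of 100 genes, step 1, within
   chromosomes; tails keep truncated windows of >= 50 genes, and a
   chromosome shorter than that contributes one whole-chromosome window;
4. subtract each cell's median window value — library-depth differences
   otherwise shift whole profiles per cell (the offset correlates ~0.8
   with log library size) and would dominate the burden statistic;
5. re-center columns on the reference (so reference window means are 0
   by construction) and clamp to +/-3.

A gene-level pre-window clamp was evaluated and rejected: on NB counts
it attenuates the dosage signal more than the noise and worsens
malignant/reference separation.

Malignancy burden is the mean squared window value; the threshold is the
reference burden mean + 3 SD. Three SD keeps the self-flag rate of the
reference around 1% (the burden distribution is slightly right-skewed,
so the flag rate sits above the Gaussian 0.13% but well under 2%).
Subclones are Ward/Euclidean clusters in window space, k by silhouette
over 2..k_max; cells are processed in lexicographic id order so ties
resolve deterministically. In the default cohort the top-level split
separates the AT2- from the basal-derived lineage (they share their
dominant chromosome events), so subclone recovery is run per malignant
cell type, mirroring per-type subclone analysis in practice.

Driver-gene scores average, over a subclone's cells, the mean of all
windows containing the gene; missing drivers are reported with a
warning, never silently dropped.

## Expression programs

DE uses the two-sided Wilcoxon rank-sum test (ties handled by the
asymptotic normal approximation with tie correction) on CP10K — the
rank test is invariant to monotone transforms, so the log is irrelevant
to p-values. The fold change is `ln((mean_a+1)/(mean_b+1))` of group
mean CP10K; the +1 keeps all-zero genes finite and matches the
convention of reporting "average logFC" on the normalized scale with a
natural log (the 0.25 single-cell and 1.0 bulk thresholds are applied on
that scale). Genes constant across both groups get p = 1 and logFC = 0.
BH adjustment runs over all tested genes with no pre-filtering beyond
all-zero removal. Stage modules assign each gene to the stage with the
largest logFC among the stages where it is called up (stages with < 3
cells are excluded with a warning). Gene-set scores are per-cell mean
CP10K over the set's present genes, log2(x+1)-transformed for
stemness-style scores; max-score assignment breaks exact ties by
lexicographic set name and flags them.

## Deconvolution

Marker candidates per type are one-vs-rest up-regulated genes (adjusted
p < 0.05) with tau >= 0.6 computed on per-type mean CP10K, ranked by
logFC; top 50 per type by default (25 in the desk-scale examples to
match the 25 planted markers). The signature holds mean linear CP10K.
Bulk samples are solved by non-negative least squares after scaling each
shared gene to unit variance across signature columns, then the weights
are renormalized to the simplex; the residual norm is recorded. NNLS +
renormalization is scale-invariant per sample. Genes missing from the
bulk matrix are dropped (never zero-filled); an overlap under 50% is an
error. The solver sits behind a single function so weighted or
support-vector variants can be swapped in.

One identifiability caveat: mixtures of raw count profiles differ from
mixtures of CP10K signature columns by per-type library-size factors
(weights estimate transcript fractions, not cell fractions). Recovery
statements are therefore made on mixtures of the signature's own
reference profiles, which is also how consistency across bulk cohorts
is evaluated.

## Composition modules and survival

Sample clustering uses correlation distance (1 − Pearson r) with average
linkage; k is either supplied (the analyses here use the planted
archetype count, as cohort studies fix k from inspection of the
dendrogram) or selected by silhouette. Group naming is rule-based to be
testable: z-score each type's weights over samples; a group whose top
mean z exceeds 1 is "<T>-high", unless the runner-up is within 0.25 z
("<T1>-<T2> hybrid"); otherwise "hybrid". The SVM check uses a linear
kernel, C = 1, stratified k-fold (default 5) repeated with distinct fold
seeds, ROC AUC computed one-vs-one per class pair from the decision
function and macro-averaged; mean and SD over repeats are reported.
Augur-style prioritization subsamples 50 cells per condition per type,
fits an L2 logistic classifier on the 500 most variable genes under
3-fold CV, and ranks types by mean AUC over subsamples; underpowered
types are excluded with a warning. Kaplan–Meier estimation and the
log-rank test are delegated to lifelines; a contrast with zero events
returns p = 1 with a warning instead of a degenerate statistic. The
survival contrast is "named group vs rest", with the contrast group
chosen as the discovered group most enriched for the high-hazard
archetype.

The end-to-end chain in `pipeline.py` simulates its single-cell cohort
at 80-100 cells/type (signature estimation saturates well below the
default 240) and the bulk cohort at the default 100 samples.

## Cell–cell interactions

A pair is evaluated for a (sender, receiver) type pair only when ligand
and receptor are detected in >= 10% of sender/receiver cells (the
convention of permutation-based interaction tools). The score is the
mean of the two group means of CP10K; the null shuffles cell-type labels
over all cells, and the one-sided p-value is (k+1)/(B+1) with B >= 100
enforced (1000 by default). Fewer than 3 cells on either side flags the
result with p = 1. Counts of p < alpha pairs are reported per ordered
type pair and per type with no multiple-testing correction — counts are
descriptive, as is conventional for interaction tallies. Note that
library-size normalization couples genes: a type expressing one gene
very highly slightly depresses its other normalized means, which can
shift null scores for unrelated pairs; with realistic gene panels the
effect is negligible.

## Numerical and testing choices

All randomness flows from integer seeds through numpy Generators; any
output is a pure function of (design, seed). Problem sizes in the test
and acceptance runs — 2000 genes, ~2900 cells, 100 bulk samples, 25
chain replicates, 500 null survival replicates, 200 permutation-test
replicates — were chosen as the smallest scales at which the planted
effects and the calibration bands are comfortably resolved. Tolerances:
exact identities at 1e-10..1e-12; Monte-Carlo comparisons at 3 standard
errors; recovery thresholds (sensitivity/specificity 0.9, ARI 0.8,
Pearson r 0.8) at the levels the validation design targets.
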