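# Methods

This note documents the models implemented in `gliograph`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing results.

## Copy-number scoring and tumor content (`gliograph.cna`)

**Quality control.** Spots with fewer than 200 detected genes or a
mitochondrial count fraction strictly above 5 % are removed first; genes
detected in fewer than 3 of the remaining spots are removed second. The
boundary semantics are deliberate: a spot at exactly 5 % mitochondrial
content is retained.

**Windowed score.** For each spot, genes are taken in chromosome order and
grouped into contiguous 100-gene windows within each chromosome; partial
trailing windows are dropped so no window crosses a chromosome boundary. The
raw per-gene quantity is `log1p(CPM_spot) − log1p(mean CPM_reference)`. These
log-ratios are **mean-centered per spot** before windowing. Centering is
essential: a spot-level count-noise (Jensen) offset — `E[log1p(noisy CPM)]`
sits below `log1p(E[CPM])`, more so for low-expression genes — would
otherwise shift every window of every spot downward relative to a low-noise
reference and masquerade as genome-wide loss. Mean (not median) centering is
used so the window-average of the residual per-gene offsets is zero by
construction; the small amount of true CNA signal the mean absorbs is
negligible when gains and losses are roughly balanced. The window score is
`exp(mean of centered log-ratios)`, a ratio-scale quantity centered at 1.

**Rescaling.** Per window, an affine map sends the reference spots' mean to
1.00 and their half-range `(max − min)/2` to 0.02, so reference scores span
roughly 0.98–1.02. A stated range *and* a stated mean cannot both be enforced
by pure min-max when the reference is asymmetric; the mean-anchored form is
used and reference extremes may land asymmetrically within the band.
Zero-variance windows are shifted to center at 1.00 and flagged. Note the
tumor-content formula below is invariant to the affine scale (the anchor at
1 is a fixed point), so rescaling matters only for event *selection*.

**Signature events and content.** Windows whose mean rescaled score over all
tumor spots is strictly above 1.05 are gain events; strictly below 0.95,
loss events. Fewer than three qualifying events is an explicit error. Per
event, the content of spot *i* is `(A_i − 1)/(max A − 1)` for gains and
`(1 − A_i)/(1 − min A)` for losses, with the extreme taken over the tumor's
spots **in that event's window** (the natural reading of an event-indexed
score; per-chromosome or genome-wide extremes are plausible alternatives).
Events whose extreme equals 1 are degenerate and skipped with a warning. The
spot's content is the mean over events, clipped to [0, 1] (averaging can
push individual spots slightly outside the unit interval). Spots with
content strictly above 0.2 are malignant.

**Known behaviour.** Because the per-event normalizer is the *noisiest
maximum* over spots, estimated content is mildly shrunk toward zero relative
to truth; averaging over many events reduces but does not remove this. With
the default generator settings the estimate correlates with truth at
r ≈ 0.9 and recalls ≥ 90 % of spots with true content ≥ 0.4 at the 0.2
cutoff. Occasional spurious events on neutral chromosomes (residual
window-composition bias amplified by the tight reference band) add noise
but little bias.

## Module scoring and subtype maps (`gliograph.scoring`)

`score_module` follows the control-bin construction: genes are ranked by
mean log-normalized (counts-per-10k, log1p) expression and cut into 24
equal-frequency bins; each module gene contributes 100 control genes sampled
(seeded, with replacement) from its bin; the score is the mean module
expression minus the mean control expression. 24 bins / 100 controls are
the conventional defaults; the control-seed contribution to the score is
below 0.05 SD at these settings. Subtypes are the argmax module per spot
with a lexicographic tie-break (ties counted and logged).

`gw_correlation` computes, at every spot, a weighted Pearson correlation of
two fields with Gaussian kernel weights `w_ij = exp(−d_ij²/(2b²))`. The
default bandwidth is 5 patch units (exposed in every caller); an enormous
bandwidth recovers the global Pearson correlation, and locations with zero
weighted variance are excluded from the sample mean with a count. Cross-
sample correspondence between module sets is summarized by a one-sample
t-test of per-sample mean local r against zero with BH adjustment — a
deliberately simple substitute for a full Wald construction, and labelled as
such in its output.

## Neighborhood-graph statistics (`gliograph.graph`)

"Two-patch distance" is the Chebyshev metric — the only metric that yields
24 neighbors from a 5×5 block, which pins the convention. Each undirected
edge is stored once.

The clustering coefficient of class *m* counts each undirected within-class
edge once: `Cluster(m) = I(M,M)/(I(M,M) + I(M,K))`, where `I(M,K)` sums
edges with exactly one endpoint in *m*. Under random labeling this statistic
has expectation `p/(2 − p)` for a class of frequency *p* (it equals *p* only
if the diagonal is double-counted; the single-count convention is fixed by
the worked 1×5 example `A,A,B,B,B → 0.25`). The interaction matrix
normalizes class-pair edge counts by the total number of edges between
malignant classes; immune-flagged classes may ride on nodes but are excluded
from the denominator. Fractions over unordered pairs sum to 1.

Abstractive networks scan nodes in sorted-position order; a node whose
same-class neighbor fraction strictly exceeds the 0.7 threshold is merged
with its **same-class** neighbors only (super-nodes stay class-pure; merging
opposite-class neighbors is the other defensible reading of "all nodes in
this neighborhood"). For a threshold of 1.0 the rule degenerates under
strict inequality, so the condition becomes "the neighborhood is entirely
same-class". Passes repeat until no merge occurs, making the operation
idempotent.

A fast array path (`lattice_features`) computes the same statistics via
twelve shifted comparisons for use inside simulation loops; tests assert
exact agreement with the graph route, and both against a brute-force
all-pairs oracle.

## Survival modelling and evaluation (`gliograph.survival`)

The loss is the negative log Cox partial likelihood with the **Breslow**
convention for tied event times (the plain risk-set sum form). The linear
fit is Newton-Raphson with step-halving; standard errors come from the
observed information, HRs/CIs/p-values are Wald. Monotone likelihoods
(diverging coefficients) clear the convergence flag with advice to add an
L2 penalty. Synthetic event times are continuous, so Breslow and Efron
coincide in the oracle cross-checks against lifelines.

The risk network is a small feed-forward scorer (tanh hidden layers, linear
output) trained with Adam on the mini-batch Cox loss where **risk sets are
taken within each batch**; batches are fresh seeded permutations per epoch
and zero-event batches are skipped (counted). With no hidden layers and a
full batch it converges to the Newton solution.

C-index uses the admissibility rule "neither member censored, or the
earlier time uncensored"; pairs with exactly tied times are excluded
(no ordering exists), and tied scores count 0.5. Orientation: higher score
= higher risk = earlier failure. The Brier score is the IPCW (Graf) form
with censoring weights from a Kaplan-Meier estimate of the censoring
distribution (computed internally because left limits `G(t−)` are needed);
IBS is the trapezoidal integral over all unique event times, normalized by
the grid span, truncating where the censoring KM reaches zero. The survival
function entering the Brier score is the Breslow baseline-hazard estimator
composed with the risk score — the link between a score and `S(t|x)` is an
interpretive choice and is labelled as one. `CS = (C-index + (1 − IBS))/2`
exactly. Kaplan-Meier (Greenwood bands) and the log-rank test delegate to
lifelines. Median splits send scores strictly above the median to "high",
ties at the median to "low".

## Cohort pipeline (`gliograph.pipeline`)

Tissue-size filtering drops the `floor(0.05·N)` tumors with the fewest
patches, ties broken on patient id. Patient risk is the plain mean over all
patches pooled across a patient's slides (not a mean of slide means).
Association fits are one multivariate Cox model per feature block
(proportions; clustering coefficients; interaction fractions), always with
gender/age/IDH/tissue-size covariates; continuous features are z-scored so
HRs are per SD, compositional blocks drop one reference category, constant
columns are dropped with a warning, rows with missing features are dropped
with a count, and BH adjustment runs across the block only. DE between
high/low aggressiveness groups uses a two-sided rank-sum test per gene on
counts-per-10k with `log2FC = log2((mean_high + ε)/(mean_low + ε))`,
ε = 1e-9, thresholds strict (`log2FC > 0.25`, `P < 0.01`). Enrichment is the
upper-tail hypergeometric with BH, reported at P < 0.05 and Q < 0.20.

`run_pipeline` chains all stages on one synthetic cohort, writes every
artifact (MTX + CSV sidecars, CSV tables, GraphML, a JSON risk model) plus a
manifest with the seed, and is byte-identical across re-runs. Errors surface
with their stage name.

## Synthetic data (`gliograph.synth`)

**Label maps.** i.i.d. multinomial labels refined by a fixed 20 Gibbs sweeps
of an 8-neighbor Potts model at inverse temperature `clustering_strength`
(four-color 2×2 block updates, exact for this neighborhood; strength 0 skips
the sweeps and is exactly i.i.d.). Same-class adjacency rises monotonically
with strength through roughly strength 1, beyond which the conditional
update is a near-deterministic majority vote and the clustering coefficient
saturates — so cohort simulations draw per-patient strengths from U(0, 0.8),
the responsive regime. A batched variant generates whole cohorts of maps at
once (same dynamics, different bitstream than single calls).

**Expression.** Genes occupy contiguous equal-size chromosome blocks in
index order (8 chromosomes, 2000 genes by default); the per-gene baseline is
log-normal (mean 2.5, sigma 0.6 on the log scale, ≈ 30k counts per spot —
deep-Visium-like) and counts are negative binomial with dispersion r = 10.
The gene model (names, chromosomes, baselines, mitochondrial tags) derives
from `config.seed` alone so tumor and reference samples of one study share a
"genome". For a spot of true content *c*, gained-chromosome means scale by
`(1 + 0.2c)` and lost ones by `(1 − 0.2c)` (chromosomes 0–1 gained and 4–5
lost by default). Subtype modules — 30 genes each, two-fold up-regulated in
matching spots — are interleaved across the neutral chromosomes so no CNA
window is dominated by one module (as with real expression programs, which
scatter over the genome). Ten `MT-*`-tagged genes sit at the tail of the
last neutral chromosome for QC tests.

**Reference.** Six pseudo-bulk "normal tissue" profiles, each aggregating 20
spot-equivalents (`NB(k·μ, k·r)`), with no CNA and no module structure. A
tissue-level reference is what the rescaling band presumes: spot-level
reference noise would widen the 0.98–1.02 band's source range so far that
the 1.05/0.95 thresholds become unreachable for moderate CNAs.

**Survival.** Event times are exponential with rate
`exp(x·β)/baseline_scale` (default scale 24 time units, a months-like
post-diagnosis horizon); censoring is an independent exponential whose rate
is found by bisection so the expected censored fraction hits the target
(default 30 %) within 0.02.

**What the generator does not emulate.** No batch effects, no
per-spot cell-count variation, no immune-cell admixture in expression, no
spatial autocorrelation of tumor content, no subclonal CNA structure, and no
histology. Passing tests therefore demonstrate the correctness and
calibration of the statistical machinery under the generative assumptions —
not performance on real Visium or whole-slide-image cohorts, where platform
noise, segmentation error and confounding between subtype expression and
CNA would all be present.

## Simulation sizes and tolerances

End-to-end property checks use: 100 random 10×10 maps for the brute-force
oracle (exact agreement, pair sums within 1e-12); a ~2000-spot sample for
content recovery (r ≥ 0.8); 20 tables of n = 500 for the lifelines
cross-check (within 1e-3; full-batch linear network within 1e-2); 100
seeded 300-patient cohorts for planted-effect recovery (95 % CI coverage
≥ 90 %, positive sign ≥ 95 %); 200 replicates for log-rank null uniformity
(KS p > 0.01); 2000 null genes for the DE type-I rate; and 10 paired seeds
for the trained-versus-untrained comparison (one-sided Wilcoxon p < 0.05).
These sizes keep the whole suite within a few minutes on one CPU while
leaving comfortable statistical margins.
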