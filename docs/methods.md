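# Methods

This note records the models implemented in `clonaltrace`, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions that matter for reproducing the
package's behavior.

## The synthetic cohort generator

The generator produces multi-sample tumor cohorts with complete ground
truth, structured like a rapid-autopsy whole-exome study of a single
patient: one matched normal plus 11 tumor samples (a pretreatment
biopsy, a postprogression biopsy, nine autopsy samples), 292 unique
somatic mutations of which 7 are truncal, four subclones, a truncal
21.9-Mb single-copy gain on chromosome 8q (chr8:124448804–146364022),
and 231× mean target coverage.  These defaults are the cohort structure
every downstream default is calibrated against.

**Clone tree.**  A topology is drawn uniformly over rooted labeled
trees on K clones with a fixed normal root (via random Prüfer
sequences; there are (K+1)^(K−1) such trees).  Mutations are
multinomially distributed over the K edges with every edge guaranteed
at least one.  "Truncal" mutations only exist when the root has a
single child edge; when a drawn topology gives the root several
children the truncal count is inapplicable and simply ignored
(`require_truncal=True` rejection-samples single-basal-edge
topologies instead).  The per-edge mutation-count distribution is
otherwise a free choice; the cohort preset fixes it at
7 / 89 / 111 / 85 (basal, shared branch, rare private clone, early
diverging clone) so that the rare clone carries a realistically large
private burden.

**Clone fractions.**  Each sample's composition over {normal} ∪ clones
is a Dirichlet draw.  The `figure3c` preset centres the Dirichlet on
the emulated prevalence pattern and keeps structural zeros exact: the
early-diverging clone is absent from both biopsies and from one liver
sample, the rare clone exists only in that liver sample (~20%) and at
low level (~7%) in the postprogression biopsy, and the ancestral clone
dominates the pretreatment biopsy (~89%).  The preset's total Dirichlet
mass defaults to 150, giving sample-to-sample prevalence noise of a few
percentage points.

**Read counts.**  A mutation on edge e is carried by all clones in the
subtree below e.  Its expected VAF in a sample is
(multiplicity × Σ carrier fractions) / (average copies per cell); the
multiplicity is fixed at one copy (the downstream model does no
multiplicity inference), the denominator is 2 at diploid sites and the
purity-weighted mixture total 2(1−F) + (M+m)F inside a truncal CNV.
Depth is Poisson (mean 231 by default) — the simplest model matching a
mean-coverage summary — with a negative-binomial option for
overdispersion; alt counts are binomial.  A flat sequencing error rate
(default 10⁻³ when enabled, off elsewhere) can inject alt reads at
wild-type sites.  The normal sample has expected VAF 0.

**What is deliberately not emulated.**  Per-sample caller dropout:
real cohorts report many variants in only a few samples because
calling is depth- and threshold-limited per sample, so a real cohort's
total-call count is much lower relative to its unique count than the
simulator's (which only loses presence when a clone is absent or
coverage is unlucky).  Alignment artifacts, FFPE damage, subclonal
copy-number genotypes, and cross-sample contamination are also out of
scope.  Passing tests therefore demonstrate correctness of the
estimators under the generative model, not robustness to every failure
mode of real pipelines.

## Presence sets, TMB, distances

A variant is present in a sample when alt ≥ 4 reads and VAF ≥ 0.05
(VAF is undefined at depth 0, which counts as absent).  These
thresholds are typical somatic-caller settings and are configurable.
TMB divides the present-mutation count (SNVs + indels by default) by
the capture territory, 38.9 Mb.  Sample distances use SNVs only by
default (indels are kept for TMB); both choices are flags, since set
membership is sensitive to indel representation — indel alleles are
reduced to minimal representation (shared suffix then prefix trimmed)
before deduplication for exactly that reason.

## Neighbor joining

Classic Saitou–Nei in the Studier–Keppler form: join the pair
minimizing Q_ij = (n−2)d_ij − r_i − r_j, limb lengths
l_i = d_ij/2 + (r_i − r_j)/(2(n−2)), distance update
d_uk = (d_ik + d_jk − d_ij)/2, three-point closed form at the end.
Determinism: exact Q ties break toward the lexicographically smallest
sorted label pair.  Distances enter as exact set cardinalities
(integers) and are only averaged inside NJ.  Negative branch lengths
are kept by the core algorithm (the test oracle compares raw output)
and clamped to zero for display, moving the deficit to the sibling
edge created at the same join so path lengths through the pair are
preserved.  The tree is rooted on the edge adjacent to the normal
leaf: the root keeps the full pendant length toward normal and a
zero-length edge toward the rest, so all path lengths are preserved
and re-rooting is idempotent.

## CNV protocol

The segmenter is intentionally simple; what the package preserves
carefully is the curation protocol around it.  Per sample and per
chromosome (≥ 10 het SNPs, otherwise skipped with a warning), two
channels are standardized by their median and MAD: the tumor/normal
depth ratio divided by rdep (the genome-wide tumor/normal aligned-read
ratio), and the mirrored BAF max(BAF, 1−BAF).  Recursive binary
segmentation splits where the reduction in summed squared deviation is
largest, accepting a split when the gain exceeds a BIC-style penalty
(6 × channels × log n; the null distribution of the best-split gain
grows like log n, and the factor 6 keeps diploid false splits rare
while the gains from real copy events are orders of magnitude larger).
Minimum segment length is 10 SNPs.  Per segment, t = 2 × mean depth
ratio and f = mean mirrored BAF give M = t·f, m = t·(1−f); their
standard errors come from the segment-level standard errors of t and f
through the delta method (treated as standard errors, not interval
half-widths).  A segment is reported when max(|M−1|, |m−1|) exceeds
the pass threshold — 0.3 on the first pass, 0.2 on the second — i.e.
"threshold" is the minimum allele-specific deviation from the
one-copy state.

Curation keeps maximal merged regions where any sample shows M > 2 or
m < 0.5.  For each curated region the common breakpoints are the
medians of the overlapping per-sample segment boundaries snapped to
the nearest het SNP; the second pass re-estimates M, m, ε_M, ε_m for
every sample inside those fixed boundaries.  Mirrored BAF is biased
upward near f = 0.5 (folding noise), which inflates M by ~0.05 at
depth 200; this matters only within ~0.1 of the curation boundaries.
Tumor purity is not corrected here: the raw bulk estimates pass
through to the subclone model, which owns normal-fraction estimation —
for the same reason the bulk total W_M + W_m is exactly the
denominator the subclone model needs for expected VAFs.

A note on the M ≈ 2 regime: a clonal single-copy gain in a pure sample
sits exactly on the "M > 2" curation boundary, so its retention is a
coin flip under estimator noise.  The validation suite therefore
exercises the segmentation-recovery example at M = 2 (first-pass
threshold 0.3 retains it comfortably) and the curation/breakpoint
checks at M = 3, which is cleanly above the rule.

## Subclone model

Topologies are parent maps over K clones rooted at normal, enumerated
exhaustively for K ≤ 5 ((K+1)^(K−1) labeled trees; random sampling
beyond).  Inside the K scan the enumeration is deduplicated to the 1,
2, 4, 9, 20 unlabeled shapes for K = 1..5, since clone labels are
exchangeable in the likelihood.

For a fixed topology, the likelihood is binomial per mutation and
sample with expected VAF clamp(inv_cn × Σ carrier fractions) to
[10⁻⁶, 1−10⁻⁶], where inv_cn is 1/2 at diploid sites and
1/(W_M + W_m) inside a curated segment.  Coordinate ascent alternates
(a) exact per-mutation edge re-assignment and (b) projected-gradient
ascent of P on per-sample simplexes with backtracking line search
(steps accepted only when the total log-likelihood does not decrease),
so the objective is provably monotone; the normal row has zero
gradient and absorbs 1 − Σ clones through the simplex projection.

Initialization matters because the objective is multimodal in the
cluster-to-edge labeling: k-means (k = K) clusters the VAF profiles
once, then every cluster→edge permutation is scored by the likelihood
of the tree-consistent P it implies (clone fraction = edge CCF minus
children's CCFs, CCF = 2 × cluster-mean VAF), and restarts (default
10) walk the permutations best-first before falling back to random
starts.  One caution on identifiability: two private mutation groups
on leaf edges under *different* parents can swap, with compensating
intermediate fractions, at exactly equal likelihood whenever the
implied fractions stay non-negative.  With 11 samples and generic
fraction patterns the non-negativity constraints almost surely break
the tie, but structured patterns (a clone absent from most samples)
can leave it unresolved; recovery is therefore assessed up to the
topology's automorphisms, and the residual swap ambiguity is a known
limitation of VAF-only deconvolution, not of the optimizer.

Model score: BIC(K) = log L̂ − ½(K·N)·log(n_obs) with n_obs = modeled
mutations × samples — K·N free fraction parameters, reported so that
larger is better.  Selection scans K upward and stops at the first
step whose BIC increase falls below `elbow_fraction` (default 5%) of
the previous increase, returning the model before that step; with no
elbow the BIC-maximal K wins, and non-increases resolve toward smaller
K.  The elbow form and its fraction are explicit configuration because
"only marginal BIC improvement" is inherently a judgment call.

Mutations with depth < 30 in any sample (configurable) are withheld
from tree building and placed post hoc: each is scored on every real
edge and on hypothetical zero-length ancestor edges above any ≥ 2
sibling subtrees, and assigned to the best edge only if that beats a
flat sequencing-noise binomial (p = 10⁻³); a zero-depth mutation ties
the noise model and stays unassigned.  The margin over the runner-up
edge is reported.  Fitted normal fractions are statistical estimates
and need not match pathologist tumor-content review; no reconciliation
is attempted.

## Bradley–Terry ordering

Within one branch, sample i contributes w_i(v1, v2) = 1, 0, or 0.5 to
the wins matrix according to whether VAF_i(v1) is greater, smaller, or
exactly equal to VAF_i(v2); samples where either VAF is undefined are
skipped for that pair, and each branch is processed independently.
The MAP estimate under a Gamma(shape a = 1.1) prior on abilities is
computed by a minorize–maximize iteration constrained to
Σπ = |V_z| — abilities are identified only up to scale and the
ordering probabilities π_j/(π_j + π_k) are scale-invariant, so the
sum constraint stands in for the prior's rate parameter (only the
shape a matters).  Each sweep maximizes the standard MM surrogate exactly
on the constraint set: the surrogate argmax has the form
π_j = (a − 1 + Σ_k W_jk)/(β_j + λ) with β_j = Σ_k (W_jk + W_kj)/(π_j + π_k),
and λ is the Lagrange multiplier found by a bracketed 1-D root solve.
Because the surrogate minorizes the log-posterior on the constraint
set, the iteration is monotone and its fixed point is the constrained
stationary point — the same point a dense grid search over the
normalized abilities finds.  (The often-quoted unconstrained update
followed by renormalization has a *different* fixed point,
π_j ∝ α_j/β_j, which is not the constrained maximizer; the constrained
sweep is used for exactly that reason.)  Convergence: maximum relative
ability change < 10⁻¹⁰ (default), cap 20 000 sweeps.

Ranks sort abilities descending (rank 1 = earliest); exact ties share
a tie group, with coordinate order used for display only.  Abilities
express confidence in the ordering, not time intervals, and no
cross-branch ordering is attempted.

## Validation scales

The simulation studies in the test suite use: 20 cohorts of 4 clones ×
30 mutations/edge × 11 samples at 250× for subclone recovery and K
selection; 50 branch timelines of 20 mutations × 11 samples with
rank-signal noise σ = 0.02 (baseline VAF declining 0.40 → 0.10) for
ordering recovery; 100 diploid replicates of 2000 SNPs at 200× plus
multi-sample gain simulations of 3000 SNPs for the CNV protocol; 100
random matrices (n ≤ 8) plus additive 5-leaf instances for NJ oracle
equivalence.  These sizes make each study's Monte-Carlo error small
relative to its acceptance margin while keeping the whole suite
runnable on a laptop core in minutes.
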