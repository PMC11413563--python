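# Methods

This note records the models, numerical conventions, and design choices
behind the package, and what the synthetic-data studies do and do not
demonstrate.

## Gradient model

Functional connectivity is the Fisher z-transform of Pearson correlation
between ROI time series; |r| is clipped at 0.999999 so perfect
correlations stay finite, and the diagonal is zeroed. Sparsification is
row-wise: negatives are zeroed, then only the ⌈keep_fraction·(R−1)⌉
largest entries per row survive (default keep_fraction 0.10), with ties
broken toward the lower column index so results are reproducible. The
affinity kernel is the normalized angle, `1 − arccos(cos)/π`, which maps
identical profiles to 1, orthogonal to 0.5 and antipodal to 0; plain
cosine is available by option. "Normalized cosine similarity" is
ambiguous in the literature; the normalized angle is the convention of
the widely used gradient toolboxes and, because downstream steps are
either monotone in affinity or rank-based, the choice is largely
immaterial.

Diffusion-map embedding uses density normalization α = 0.5 (Fokker–Planck
convention), diffusion time 0, coordinates scaled by their eigenvalues,
and 10 retained components. Eigenvector sign is arbitrary, so each
column's largest-magnitude loading is made positive before alignment;
after Procrustes alignment signs are template-determined. Variance
explained is each retained eigenvalue over the sum of positive
non-trivial eigenvalues. A disconnected affinity graph makes the
diffusion operator reducible and is rejected with advice to densify.

Subject-to-template alignment is orthogonal Procrustes (rotation and
reflection only); it preserves within-subject pairwise ROI distances
exactly, so dispersion statistics are compared in a common frame without
distorting any subject's internal geometry. The cohort fit uses the
pooled mean FC as template so both groups share one reference frame.

Between-network dispersion is signed (`mean(A) − mean(B)`, antisymmetric)
with an absolute-value option; group-recovery studies use the absolute
form because the sign of a gradient axis is a convention. Within-network
dispersion is the sum of squared distances to the network centroid on
the named gradient.

## Stepwise functional connectivity

Edges require BH-FDR q < 0.001 on the two-sided p of
`t = r·√((n−2)/(1−r²))` and r > 0; p-values use the raw correlation
(recovered as tanh of the stored z) and the number of frames actually
used. Degrees at step k are walk counts — seed-row sums of the k-th
adjacency power, computed by iterated vector-matrix products. Walks, not
simple paths: adjacency powers count walks that may revisit nodes, which
is what seed-based SFC methods compute; simple-path counting is #P-hard
and not attempted. Maps are min-max scaled per step (a constant step maps
to zero), subject maps are multiplied by the group map (plain group maps;
no leave-one-out recomputation), and convergence is the first step whose
map correlates above 0.999 with the next; a zero-variance step is skipped
with a warning.

## Semantic graphs

Similarity is `(cos+1)/2`. Thresholding is proportional: candidate t
keeps the `round(t·N(N−1)/2)` strongest pairs (round half away from
zero; ties by pair index), and the selected t is the smallest grid value
in {0.05, …, 0.80} whose graph's mean degree exceeds 2·ln N; if none
qualifies, 0.80 is used and flagged. Because ranking is monotone
invariant, the similarity normalization cannot affect the graph — the
suite asserts this directly. No small-worldness gate (e.g. σ > 1.1) is
applied to accept a graph.

Closeness centrality uses the Wasserman–Faust reachable-fraction scaling
so disconnected graphs are handled; global efficiency counts unreachable
ordered pairs as zero; clustering is the mean local coefficient. σ
compares the graph's clustering and largest-component path length with
means over 20 degree-preserving rewired nulls (10·E attempted swaps
each, deterministic given a seed); σ is reported missing when the graph
is disconnected, smaller than four nodes, or the nulls have zero
clustering. Narratives with fewer than four units contribute to unit
counts but not to graph metrics; metric averages over narratives exclude
missing values pairwise.

## Syntactic trees

Leaves are POS preterminals, one per token; a surface token after the
tag is accepted and preserved. Punctuation leaves (PTB tags) are removed
first, then trees are right-binarized with `parent|<…>` intermediates.
Depth (edges from the root to each leaf) and its approximate entropy are
computed on the binarized, punctuation-stripped tree — binarization can
only deepen leaves, and the same convention is applied to every
utterance in any comparison, so group contrasts are unaffected. Phrase,
NP and VP metrics exclude the binarization intermediates entirely and
are therefore identical before and after binarization; category matching
strips functional annotations at the first hyphen (`NP-SBJ` → `NP`);
nesting counts proper domination at any depth. Phrase fraction counts
phrasal (non-preterminal) nodes per leaf. ApEn uses the Pincus
definition with self-matches, m = 2, r = 0.2 × population SD; a constant
series has ApEn 0 and series shorter than m+2 are missing. Ratios over
empty NP/VP sets are missing, not zero. Aggregation is a two-stage
unweighted mean (utterances within narrative, then narratives), with
missing values excluded pairwise at each stage.

## Statistics layer

Cohen's d uses the equal-weight pooled SD √((s₁²+s₂²)/2), and χ² is
Pearson's without continuity correction with effect size
C = √(χ²/(χ²+n)) — these conventions reproduce the reference cohort
table exactly from its printed summaries. Mann–Whitney U is exact for
tie-free samples of at most eight per group, otherwise normal with tie
correction; all-constant input returns p = 1. Partial Spearman
rank-transforms every variable, residualizes on the covariate ranks, and
tests the residual Pearson correlation on n−2−k degrees of freedom.

GLMs delegate to statsmodels; the Tweedie variance power is fixed at 1.5
by default (profile estimation is out of scope). Signed dispersion
responses are shifted by |min|+1e−6 before log-link fitting (flagged in
the output). The goodness-of-fit p is the χ² tail of
deviance/dispersion (Pearson-estimated) on the residual degrees of
freedom. This textbook check is only approximately calibrated: in the
gamma calibration study (n = 500, shape 5) its rejection rate at
α = 0.05 is about 1–4 % — conservative — and the approximation degrades
away from moderate shape. It is a screen against gross misfit, not an
exact test. The mass-univariate parcel model is vectorized OLS with a
group term plus age, sex and education, BH-FDR across parcels; it
matches per-ROI statsmodels OLS to 1e−8 in the suite.

## Synthetic cohort

The generator defines the study conditions: 29 subjects per group, 100
ROIs in seven canonical networks, 240 time points, three narratives per
subject, 24 embedding units and 8 utterances per narrative.

*Time series.* Seven network factors are drawn per time point with a
planted correlation structure: adjacent networks along a
unimodal→transmodal axis correlate at 0.45 fading to 0.10 at the axis
ends, the two unimodal networks (visual, somatomotor) both sit at 0.10
from the default-mode network in controls, and the `compression` dial
moves the visual–DMN correlation toward 0.60 and the somatomotor–DMN
correlation down by 80 % of baseline in the patient group. ROIs mix the
factors through a fixed, deterministic atlas: Gaussian kernel loadings
around evenly spaced axis positions (within-network spread ±0.3, kernel
width 0.2), core→periphery signal amplitudes (1.7 → 0.3), a secondary
network membership per ROI (golden-ratio graded up to 0.6, targets
cycling over the other networks), and a graded opposite-end membership
(up to 0.3) for networks at the axis extremes — the synthetic analogue
of connector hubs. The atlas is shared by both groups, all subjects and
all cohort seeds, exactly as a real parcellation is; without its
heterogeneity, row sparsification retains only within-network entries
and provably erases any end-to-end correlation change. Groups are
matched by common random numbers (subject s of either group uses the
same latent stream), so the only group difference is the planted factor
correlation; at compression 0 the groups are byte-identical. ROI noise
is white with SD 0.5. Hemodynamics, motion and physiological confounds
are deliberately not modelled.

*Embeddings.* Units are cluster centers on the unit sphere plus isotropic
noise of scale `spread`, re-normalized. Small spread (default 0.15)
yields distinct semantic clusters; the patient-like condition multiplies
spread by (1 + 3·compression), homogenizing the space. Under proportional
thresholding the retained edge count is fixed, so what changes is edge
placement: a clustered space concentrates edges within clusters (lower
closeness/efficiency, higher σ), a homogeneous space spreads them
(higher closeness/efficiency, σ near 1) — the patient-direction pattern.

*Trees.* A small probabilistic grammar: S → NP VP; NP → NP PP (embedding)
or (DT) NN; VP → (ADVP) VP chains (one added adverb per level), bare V,
V SBAR, or V NP; utterances coordinate one or more clauses with the
clause count adapted to the expected clause length so total words stay
matched across conditions. The patient-like shift (scaled by
`compression`) lowers NP embedding, determiner use and clausal
complements and raises chaining and intransitivity: the same amount of
speech built from more, shorter, simpler pieces. This jointly reproduces
the expected contrasts — more nodes, deeper trees, lower depth entropy,
fewer/shorter/simpler NPs, more but shorter VPs. Vocabulary realism is a
non-goal; leaves are bare POS tags.

*Covariates* (age ~ N(21.5, 3), sex, education) are generated
independently of group, as in a matched design.

## What the recovery studies show — and what they do not

The acceptance studies run the full pipeline on 100 cohort seeds each and
count directional successes: gradient compression recovered in ≈100 %,
the semantic-space direction in ≈97 %, the grammar direction in ≈99 % of
seeds at the default conditions. They demonstrate that the implementation
transmits factor-level and generator-level effects through every stage in
the expected direction — a non-trivial end-to-end property, since the
effects are planted upstream of FC, thresholding and embedding. They do
not demonstrate sensitivity on real fMRI or real transcripts, where
confound structure, parcellation error, parser noise and vocabulary
effects are all absent here by construction.

## Problem sizes

The test suite and acceptance script use the reference study scale
(29+29 subjects, 100 ROIs, 240 frames; 100 seeds per recovery study;
1000 null ROIs for type-I calibration; 200 replicates for GLM coverage),
which completes in a few minutes on a single CPU.
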