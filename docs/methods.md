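# Methods

## The model

`glandabc` simulates colorectal tumor growth at the resolution of glands
(crypts) and their cancer stem cells (CSCs), and infers three parameters
from single-gland sequencing data by rejection ABC:

* `alpha` — expected new point mutations per daughter cell per division
  *before* the first gland forms (exome scale),
* `beta` — the same rate *after* the first gland forms,
* `r` — the probability that a CSC division is asymmetric.

An elevated `alpha` relative to `beta` is the "mutation burst" hypothesis:
most detectable intratumoral heterogeneity laid down in the first few
divisions of the founding cell.

Growth has three phases. (1) The founding transformed cell divides along a
balanced binary schedule until the gland holds `n_csc` CSCs (default 32);
every daughter created on the way draws Poisson(`alpha`) new mutations, so
the expected pre-gland mutation count is `alpha` times the 62 daughter cells
of the 1 → 32 expansion. (2) Glands double by fission each generation for
`n_fission_gens` generations (default 19, i.e. 2^19 ≈ 524k glands ≈ 4 cm³ at
10,000 cells/gland). In the default *bottleneck* mode each daughter gland is
founded by one CSC drawn without replacement from the parent pool and
regrown to `n_csc` (Poisson(`beta`) mutations per daughter cell); founder
mutations are consequently fixed in the daughter gland, which is what makes
pre-gland mutations sit at allele frequency exactly 0.5 in every sampled
gland. A *split* mode (parent pool divides once and is partitioned at
random) is available for sensitivity analysis but does not reproduce that
fixation behavior. (3) For `t3` generations (default 100) each gland is
maintained by CSC division: asymmetric with probability `r` (one CSC
daughter), otherwise two CSCs or zero CSCs with equal probability — a
critical branching process whose mean pool size is constant. Mutations in
differentiating daughters are discarded: those lineages are short-lived and
never contribute to gland allele frequencies, which are computed over the
CSC pool (`carriers / pool / 2`; the 10,000-cell gland size is reporting
metadata only).

Because the offspring law is critical, a gland's CSC pool can go extinct
during the constant phase. Sampled glands are conditioned on survival: an
extinct gland has its constant phase resimulated from its start with a
fresh random substream, and the restart count is recorded on the sample. An
optional `normalize` flag instead resamples the pool back to `n_csc` each
generation (Wright–Fisher-like) for users who want a strictly constant
pool. Only lineages ancestral to the sampled glands are simulated; glands
evolve independently after fission, so pruning unsampled branches leaves
the sampled glands' joint distribution unchanged (tested against full-tree
simulation on small trees).

Mutations follow the infinite-sites convention (fresh integer id per event,
no recurrence or back-mutation), and each carries its origin phase
(`pre_gland`, `fission`, `constant`).

## Observation model

Perfect mode passes exact frequencies through; a mutation is fixed iff its
frequency is exactly 0.5. Reads mode draws a per-locus depth from a
negative binomial with mean `m` and variance `v` (default `v = 1.1 m`;
`p = 1 − m/v`, `t = mv/(v−m) − m`), then an alternative-allele count
Binomial(k, q). Loci with zero alternative reads are undetected; the
detection threshold `f_min` applies to the observed frequency `n_a/k` in
reads mode (what a caller can see) and to the true frequency in perfect
mode. Fixation is called by an exact two-sided binomial test of H0:
q = 0.5 (minimum-likelihood convention; for this symmetric null it equals
twice the smaller tail) at level 0.05 by default — the level is a parameter
since no canonical value exists. The call is deliberately anti-conservative
(frequencies near 0.5 pass), and exactly the same calling procedure is
applied to reference-table simulations and to observed data, so the
miscalling is part of the generative model rather than a bias. Filtering
precedes testing. Sequencing error, mapping bias and contamination are out
of scope.

## Summary statistics and classification

Nine statistics condense a multi-gland sample: mean and variance of
non-fixed allele-frequency records (s1, s2); counts of distinct
gland-specific/shared × non-fixed/fixed mutations (s3–s6); variances across
glands of per-gland non-fixed and fixed counts (s7, s8); and the variance of
non-fixed allele frequency across the two tumor halves (s9). Design choices
where the definitions were genuinely open:

* A mutation observed in several glands with discordant per-gland fixation
  calls is non-fixed at the sample level ("fixed in every gland where
  present"): any segregating observation contradicts fixation.
* s1/s2 pool every (gland, mutation) record rather than collapsing to one
  value per mutation, preserving per-gland heterogeneity.
* s9 is read as the variance (denominator 1) of the two half-level means of
  pooled non-fixed frequencies; alternative readings exist, and whichever is
  used must be identical between reference table and observed data.
* Empty categories: mean/variance of an empty set is 0; variance of a
  single value is 0; sample variances use `ddof=1`.

## ABC

Rejection ABC with the weighted distance `d(S', S) = ||(S'−S) Wᵀ||₂` on
standardized statistics. Statistics are divided by their reference-table
median absolute deviation (falling back to the standard deviation, then to
1, when degenerate) so count-valued and frequency-valued statistics are
commensurable; R²-based weights are scale-free, so standardization changes
only the equal-weight baseline, and it can be disabled by passing a unit
scale. Priors are uniform: alpha ~ U(0, 5), beta ~ U(0, 1), r ~ U(0.5, 1).
Acceptance is by quantile (default: the closest 1–2% of rows) rather than an
absolute ε.

Three weighting schemes per target parameter: equal (1/M); global — weight
∝ R² of the simple linear regression of the parameter on each statistic over
the whole table; local — the same R² computed in the ceil(η·N) rows whose
value of that statistic is nearest the observed one (1-D neighborhoods,
stable tie-break by row index, η = 0.1 by default). Weights are normalized
to sum to one over the nine statistics for the target parameter — the
printed form of the normalization in the source material runs over
parameters for a fixed statistic, which does not yield the M weights one
distance needs, so the per-parameter reading is used. R² values below 0.01
are indistinguishable from sampling noise at these table sizes and are
zeroed before normalizing; if every statistic is floored the weights fall
back to equal rather than amplifying noise ratios. Posterior summaries are
the mean, sample sd, and a mode taken as the argmax of a Gaussian KDE
(Silverman bandwidth) on a 512-point grid over the prior support.

## Real-data front end

MuTect call-stats files (one per gland, named columns, KEEP judgement) are
merged into the same sample container the simulator produces. Copy number
changes the clonal expectation: a single mutated copy carried by every cell
of a c-copy region sits at frequency 1/c, so the fixed call tests
H0: q = 1/c exactly (0.33 in a copy-number-3 region is "fixed");
multi-copy mutant alleles (q = j/c, j ≥ 2) are not tested by default.
Frequencies are rescaled to the simulator's diploid scale as
min(0.5, q·c/2). Integer copy-number segments are a user input (1-based
closed intervals); uncovered positions fall back to diploid with a warning,
or to a hard error on request. With one gland per half, s9 degenerates to
the variance of two single-gland means; a caveat warning is emitted.

## Problem sizes and study design

The recovery studies (weighting schemes, detection threshold, glands per
half, sequencing depth) default to 40 test tumors and a 2,000-row reference
table with acceptance fraction 0.02 — sizes chosen so that all four studies
run in a few minutes on one core while the qualitative contrasts are clear;
`RecoveryConfig.full_scale()` restores a 300-tumor design. All four
studies share one tumor bank: the same underlying simulated tumors are
observed under every condition (thresholds and gland subsets reuse the
perfect sample; read depths redraw reads). Reference and test banks are
disjoint and separately seeded. Pairing conditions tumor-for-tumor removes
most Monte-Carlo noise from between-condition comparisons while leaving each
condition's ABC analysis valid on its own. Test-tumor generating parameters
are drawn from the priors.

## What the synthetic generator does and does not capture

The generator emulates per-gland variant tables with depth overdispersion,
binomial allele sampling, detection limits and fixation miscalls. It does
not model spatial structure, selection, copy-number evolution, sequencing
error or germline contamination — so passing tests demonstrate correct
inference *under this model*, not robustness to those real-data features.
The MuTect fixtures in the test suite are synthetic stand-ins generated by
`make_fixtures`; no real tumor data ships with the package.

## Known limitations

The pre-gland rate alpha has a low identifiability ceiling under this
model's default priors: its signal lives in the shared-fixed mutation count
(s6), but bottleneck regrowth adds Poisson(beta) mutations on 62 daughter
cells per fission, making s6 ≈ 9.6·alpha + 68·beta empirically. With
beta ~ U(0, 1) the beta term dominates (R² of s6 on alpha ≈ 0.2; multiple
R² of alpha on all nine statistics ≈ 0.48), so no per-statistic weighting
can recover alpha sharply — its posterior mean correlates with the truth at
rank correlation ≈ 0.4–0.6 and its posterior sd is insensitive to the
detection threshold, the number of glands, and depth. In the biologically
reported regime beta ≲ 0.15 the contamination is minor. beta and r are
recovered well (rank correlations ≈ 0.97 and ≈ 0.73–0.83), and behave as
expected across conditions. The local weighting scheme at η = 0.1 on
2,000-row tables is more stable than its reputation: its mean posterior sd
lands between global's and equal's rather than above both.
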