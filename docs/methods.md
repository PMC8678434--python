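# Methods

## Data model

A diary is a set of participant-days. Each entered day carries up to 10
variables ("petals"): 8 fixed — pain, mood, fatigue, sleep quality,
stress, flare, recommended exercise, anti-inflammatory use — plus 2 of 13
optional variables chosen per participant at enrolment. Every variable is
an integer Likert score in 1..5 with 1 the least healthy outcome; scores
are stored exactly as entered and never inverted or imputed. A day with
any entry counts as "data entered" for gap logic even if individual
petals (including the flare petal) are unscored.

One published summary is internally inconsistent with this scale: the
anti-inflammatory petal is tabulated elsewhere on a ~0–1 scale
(group means 0.42–0.58) despite the stated universal 1–5 scoring. The
package keeps the 1–5 data model for all petals; the synthetic generator
accordingly gives that petal a mid-scale baseline (2.6) rather than an
impossible sub-1 mean, while its flare *shift* (+0.13) follows the
published between-state difference.

## Flare state and episode segmentation

The flare petal is binarized: flare-on iff score ≤ T. T is a free
parameter because the operational mapping used in the original analysis
is not recorded; the default T = 3 (scale midpoint) makes scores {1,2,3}
flare-on, and every downstream statistic is reproducible under any T. A
missing flare score yields an *undefined* state and the entry is excluded
from all flare-conditioned computation.

Episodes are maximal runs of flare-on days under a one-missing-day bridge:
two flare-on days exactly two calendar days apart, whose single
intervening day has **no diary entry at all**, belong to one episode (the
bridged day counts toward duration but not toward recorded flare days).
A recorded flare-off day — or an entered day with the flare petal
unscored — always terminates an episode; gaps of ≥ 2 consecutive
entry-free days are never bridged. This is the strict reading of the
published rule, consistent with its worked example (Monday + Wednesday
with Tuesday missing merge; Monday + Thursday with two missing days do
not). Episodes touching the first or last entry day are kept, never
truncated, and flagged.

Duration is calendar days (end − start + 1), so duration =
recorded flare days + bridged days. Per-participant flare frequency is,
by default, observation span (last entry − first entry + 1) divided by
episode count — the only simple definition compatible with very large
published per-participant values (one flare over a long follow-up); the
mean onset-to-onset gap is available as an alternative
(`frequency_method="onset"`). Pooled duration moments use the n−1 S.d.;
frequency moments are taken over participants with ≥ 1 episode.

The segmenter is a single left-to-right scan. It is validated
exhaustively against an independently coded fixed-point merge oracle on
all 3¹⁰ ten-day patterns over {flare-on, flare-off, missing}, plus
property tests (partition of flare-on days, bridge bound, idempotence).

## Features, eligibility, normalisation

Per participant and variable: the mean score over entries where the
variable is scored *and* the flare state is defined, split by state;
the difference d = mean_on − mean_off exists only when both sides have
≥ 1 observation (this produces the varying per-variable n, dominated by
the rarely-chosen optional petals). Clustering eligibility requires
≥ 10 distinct entry days (boundary inclusive) and a complete difference
vector over the 7 fixed symptom petals — the flare petal itself is the
conditioning variable, and optional petals are observed for too few
participants for a complete-case matrix, so they are reported
descriptively only. Each difference column is affinely mapped to [−1, 1]
(x ↦ 2(x − min)/(max − min) − 1); a constant column maps to zeros and is
flagged degenerate. Max-abs scaling (sign-preserving) is available as an
alternative scheme; min-max is the default because the target interval,
not sign preservation, is the stated requirement.

## Inference

Paired layer: one-sample t on the per-participant differences
(t = d̄/(s/√n), df = n − 1, two-sided p, 95% CI = d̄ ± t₀.₉₇₅,ₙ₋₁·s/√n).
Degenerate inputs are defined explicitly: n < 2 → no inference; s = 0
with d̄ = 0 → t = 0, p = 1, point CI; s = 0 with d̄ ≠ 0 → p → 0 limit,
flagged. Cluster contrasts use Welch's statistic with Satterthwaite df;
binary covariates are compared as 0/1 indicators through the same
machinery (equivalent to an unpooled two-proportion z up to df), with a
2×2 chi-square available behind `two_proportion_chi2`. Raw p-values are
reported with a P < 0.01 flagging convention and deliberately no
multiple-testing correction, matching the descriptive character of the
table reports. The between-cluster duration contrast compares
per-participant *mean* episode durations, so long-follow-up participants
do not dominate.

Both tests match scipy's independent implementations to 1e-10 relative
tolerance on 1000 random inputs; simulation shows 5% ± 1.5% type-I error
at p < 0.05 (2000 null variables) and 95% ± 2% CI coverage (2000
replicates at n = 50).

## Affinity propagation

Similarity S(i,k) = −‖xᵢ − xₖ‖^r with r = 2; the shared preference on the
diagonal is the q-quantile (linear interpolation) of the off-diagonal
similarities, q = 0 (the minimum) by default to favour the fewest
clusters. Messages follow the standard responsibility/availability
updates with damping λ = 0.9, a 100-iteration unchanged-exemplar
convergence window within a 1000-iteration cap (mirroring the documented
defaults of the reference R implementation), and the canonical final
refinement: within each cluster the member maximising the intra-cluster
similarity sum becomes the exemplar, then points are reassigned to their
most similar exemplar. Exact duplicate rows make the message fixed point
degenerate, so a one-off seeded jitter of magnitude 1e-12·range(S) is
added; it is skipped when S has zero range (all-identical inputs should
collapse to a single exemplar) and can be disabled for oracle tests.
If no exemplar emerges by the cap, the point with the largest
self-evidence r(k,k)+a(k,k) is returned as a best-effort single exemplar
and the result is flagged unconverged.

A brute-force oracle enumerates all non-empty exemplar subsets (n ≤ 12)
and maximises the net similarity Σ_{i∉E} max_{k∈E} S(i,k) + Σ_{k∈E} p(k),
breaking ties lexicographically. On separable two-blob instances
(inter/intra distance ratio ≥ 4, n ≤ 8) message passing attains the
oracle's optimal net similarity; near-equivalent exemplars inside a tight
blob can tie at equal objective, so optimality is asserted on the
objective and the partition, not on exemplar indices.

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, with two
planted phenotypes. Defaults (all overridable in
`SyntheticCohortConfig`):

- **Mixture**: 129 participants, weights 96:33.
- **Follow-up span**: lognormal, mean 185 d, cv 1.27, truncated to
  [12, 720] d; with 15% missing days this yields ≈ 157 logged days on
  average, matching the reported adherence profile.
- **Episode process**: alternating renewal; flare durations geometric
  with means 7.2 d (cluster 1) and 3.5 d (cluster 2), flare-off runs
  geometric with means 27.8/31.5 d so onset-to-onset ≈ 35 d in both. A
  shifted-negative-binomial tail is available to emulate the heavy
  duration tail (published S.d. 6.8 ≫ mean 4.3).
- **Scores**: latent Gaussian — population baseline (flare-off means
  ≈ 3.4–4.0 by petal) + participant deviation (sd 0.5, matching the
  published between-participant spread of ≈ 0.55–0.7) + cluster flare
  shift on flare days (participant heterogeneity sd 0.15) + daily noise
  (sd 0.8, a typical day-to-day test-retest spread for 5-point scales) —
  rounded and clipped to 1..5. Because rounding/clipping compresses
  differences near the scale ceiling, the latent shift is *calibrated*:
  for each cluster × variable the generator solves for the latent shift
  whose expected realised (rounded, clipped) difference equals the
  configured value, so cluster mean difference features match the
  configured profiles to ≲ 0.04.
- **Flare petal**: encodes the latent state with fidelity 0.995 (scores
  uniform on {1..T} when on, {T+1..5} when off; flipped with probability
  0.005), so threshold binarization recovers the latent state on ≥ 99%
  of entered days.
- **Missingness**: days MCAR at 0.15, petals MCAR at 0.02; an
  informative mode (extra missingness during flare) exists, off by
  default, to probe adherence bias.
- **Baselines**: continuous covariates normal with per-cluster means/sds
  from the published baseline table; smoking as a mutually exclusive
  categorical; per-covariate missingness mirroring the published
  complete-case counts.

Within-day symptom noise is independent across petals by default (only
marginals are published); a shared daily factor is available. Everything
is deterministic given one integer seed.

What the generator does **not** emulate: informative adherence (by
default), within-day timing, serial correlation of symptoms across days
beyond the flare state, measurement drift, and real covariate
correlation structure. Tests passing on synthetic data therefore
demonstrate correctness of the *pipeline mechanics and statistics under
the assumed data-generating process*, not clinical validity on real
diaries.

## Planted-cluster recovery: what to expect

With these defaults the two phenotypes overlap substantially: about 15%
of eligible participants record fewer than ~5 flare-on days, so their
seven difference features are dominated by sampling noise
(se ≈ 0.4–0.8 per feature against a 1.35 between-center separation).
Even a nearest-true-center classifier that *knows* the planted centers
reaches only ≈ 96% accuracy (ARI ≈ 0.84) at n = 500. End-to-end runs at
n = 129 typically find 2 clusters with ARI ≈ 0.6–0.9 against ground truth
and a decisive duration contrast (Welch p ≪ 0.01); occasional replicates
split a third cluster or dip below ARI 0.8. This ceiling is a property
of the planted conditions (short follow-ups plus modest shifts), and the
published between-cluster Welch statistics imply at least as much
within-cluster spread in the original cohort.

## Numerical and reporting choices

- Problem sizes in the validation suite: 3¹⁰ exhaustive segmentation
  patterns; 50 separable clustering instances (n ≤ 8) against 2ⁿ
  enumeration; 1000 random t-test inputs; 2000-replicate type-I/coverage
  simulations; 25 end-to-end replicates at n = 129; calibration checks at
  ≥ 2000 episodes per cluster and 500 participants.
- Missing report cells are NaN in CSV/JSON, never zeros.
- Cluster ids are renumbered by descending size (group 0 largest); the
  adjusted Rand index is label-invariant, so this is cosmetic.
- Reports are byte-reproducible for a fixed config + seed; timestamps
  appear only in logs.
- Known limitations: no imputation of missing difference features (by
  design); per-point preferences and alternative clustering families are
  out of scope; flare localisation cannot be derived from this data
  model.
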