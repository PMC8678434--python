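# flarediary

Analysis pipeline for daily self-reported flare diaries in axial
spondyloarthritis (axSpA). People living with axSpA alternate between
flares and more stable periods; smartphone diary apps let them score
symptoms every day, giving a prospective, recall-bias-free view of what a
flare actually does to pain, fatigue, sleep, mood, stress and behaviour —
and whether distinct *flare phenotypes* exist across patients.

`flarediary` implements that analysis as a reusable, tested package:

1. **Episode segmentation.** Each diary day carries a flare petal scored
   1–5 (1 = least healthy); scores ≤ T (default T = 3) are flare-on. A
   flare episode is a maximal run of flare-on days, where a single calendar
   day with *no diary entry at all* between two flare-on days is bridged
   into the episode; a recorded flare-off day, or a gap of ≥ 2 missing
   days, always ends it. Durations are calendar days; per-participant
   frequency is observation span ÷ episode count.
2. **Flare-conditioned features.** For each participant and variable v,
   the means x̄ᵥ,on and x̄ᵥ,off over flare-on/flare-off entries and their
   difference dᵥ = x̄ᵥ,on − x̄ᵥ,off (negative = worse during flare).
3. **Paired inference.** Per variable, a paired t-test of {dᵥ} against 0
   with mean estimate and 95% CI (t = d̄/(s/√n), df = n−1); raw p-values,
   P < 0.01 convention, no multiplicity correction.
4. **Phenotype clustering.** Participants with ≥ 10 entry days and
   complete difference features over the 7 fixed symptom petals are
   min-max rescaled per column to [−1, 1] and clustered by affinity
   propagation (implemented from scratch): similarity S(i,k) = −‖xᵢ−xₖ‖²
   (negDistMat, r = 2), shared preference = the q = 0 quantile (minimum)
   of off-diagonal similarities to favour few clusters, damped
   responsibility/availability message passing, and the standard final
   exemplar refinement. A 2ⁿ exemplar-subset oracle certifies optimality
   on small instances.
5. **Cluster contrasts.** Welch's unequal-variance t-test (Satterthwaite
   df) compares clusters on difference features, raw flare-on/off means,
   episode durations, and baseline covariates (BASDAI/BASMI/BASFI-like
   scores, HLA-B27, smoking, …), 0/1 indicators included.
6. **Synthetic cohorts.** Because diary cohorts of this kind are not
   public, a generator plants two latent phenotypes (mixture 96:33) with
   cluster-specific episode dynamics (geometric flare durations with means
   7.2 vs 3.5 days, ~35-day onset-to-onset cadence), latent-Gaussian
   Likert scores with calibrated per-cluster flare shifts, irregular
   follow-up and missingness — so every stage is testable against known
   ground truth.

## Worked example

```python
import flarediary as fd

model = fd.FlareDiaryModel.from_synthetic(seed=1)   # default planted cohort
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Flare diary analysis
====================
participants registered           129
participants with >=1 flare       121 (93.8%)
eligible (>= 10 entry days)        129
clustered (complete features)     121

flare episodes                    785
episode duration, days            mean 4.65 (S.d. 4.79, range 1-34)
flare frequency, days/flare       mean 29.05 (S.d. 13.91, range 6-106)

paired flare-on vs flare-off differences (P < 0.01 flagged):
  pain                           -0.746 [-0.818, -0.674]  n=121 *
  fatigue                        -0.534 [-0.610, -0.458]  n=121 *
  ...
affinity propagation: 2 cluster(s), sizes [92, 29], converged=True after 131 iterations
episode duration by cluster: 5.45 vs 2.97 days (Welch p = 7.645e-08)
adjusted Rand vs ground truth: 0.896
```

Reading: the planted pain shift is recovered as a −0.75-point worsening
during flare with a tight CI; affinity propagation at q = 0 finds the two
planted phenotypes (92 and 29 of the 121 clusterable participants,
adjusted Rand 0.90 against ground truth), and the longer-flare phenotype
is confirmed by the between-cluster Welch test on episode durations.
Observed durations (5.5 vs 3.0 days) sit below the latent 7.2/3.5-day
means because missing diary days truncate and split observed episodes.

Real data enter through `FlareDiaryModel.from_csv(diary, baseline)`
(long or wide diary CSV; see `flarediary.io`). The same pipeline is
scriptable from the shell:

```sh
flarediary simulate --seed 1 --out cohort/
flarediary run --config cfg.json --seed 1 --out out/
```

writing `episodes.csv`, `features.csv`, `table1.csv`–`table4.csv`,
`labels.csv` and `report.json`.

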