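# Methods

## Model and procedure

The probe reads counts per 1 s exposure. Counting is Poisson by the physics
of radioactive decay, but the discrimination algorithm deliberately avoids a
parametric noise model: the background of each surgical district is
summarized by the extremes of a short (≥ 5 s) background acquisition, treated
as a flat distribution on [R_min, R_max], giving mean (R_max + R_min)/2 and
standard deviation (R_max − R_min)/√12. The cutoff is this mean plus N_σ flat
sigmas. The flat model is conservative and estimable from the very short
streams available in theatre, where a sample variance over 5–10 bins would be
noisy and a fitted Poisson mean would discard the surgeon-facing simplicity
of "max and min seen on the display".

A sample (lymph node) may be measured more than once. Each measurement is
evaluated independently against the district cutoff; the sample is
probe-positive if **any** measurement satisfies the fraction condition
(share of bins strictly above cutoff ≥ ε_Frac) **or** the run condition
(longest contiguous series of bins strictly above cutoff ≥ ε_Num). Runs never
bridge acquisitions: acquisitions are temporally disjoint probe placements,
so a run spanning two placements has no physical meaning. "Above" is strict
(>), the ε comparisons are inclusive (≥).

The two conditions target different lesion presentations: a briefly-held hot
node (high fraction in a short stream) and a sustained dwell over a lesion
embedded in a longer sweep (long run, possibly low overall fraction).

### Decay correction

All counts are corrected for physical decay before any comparison:
c → c · 2^((t − t_ref)/T½). T½ defaults to the standard ⁶⁸Ga value,
67.71 min = 4062.6 s, and is configurable. The reference time t_ref defaults
to the start of the district's first background acquisition, which puts the
cutoff and every sample of that district on a single rate scale; referencing
to injection time (t_ref = 0) is supported and changes nothing downstream
because classification only ever compares rates within one district, and both
choices differ by a district-constant factor.

### Optimization

The parameter grid is fixed:
N_σ ∈ {0.5, 1, 1.5, 2, 2.25, 2.5, 2.75, 3, 3.25, 3.5, 3.75, 4, 4.5, 5, 6, 8,
10, 30} (18 values), ε_Frac ∈ {5%, 10%, 20%, 50%} (4), ε_Num ∈ {2, 3, 4, 6,
8, 10, 20} (7) — 504 configurations. For each of the 28 (ε_Frac, ε_Num)
pairs, varying N_σ traces a ROC curve of 18 (sensitivity, specificity)
points. Both detection conditions are monotone in the cutoff, so sensitivity
is non-increasing and specificity non-decreasing in N_σ; the `RocCurve`
constructor enforces this invariant.

AUC is the trapezoidal integral of sensitivity against false-positive rate
(both as fractions) after anchoring at (0,0) and (1,1); the anchors are
needed because the 18 sampled N_σ values need not span the full ROC range.

The operating point is the one nearest (Euclidean distance in the percent
plane) to the ideal (100, 100) corner. Ties prefer higher specificity — in
this surgical context a false positive is an unnecessary resection. Residual
ties are common on small or well-separated training sets: a whole plateau of
N_σ values can share an identical empirical score. The plateau is resolved
toward the N_σ nearest the median of the tied values. The centre of the
plateau maximizes the margin in both directions: a cutoff at the low edge is
one noise fluctuation away from false positives on new data, one at the high
edge one weak lesion away from false negatives. (Resolving toward either
edge measurably degrades held-out performance on noisy synthetic cohorts.)
Any remaining tie falls back to the deterministic grid order (lower ε_Frac,
then lower ε_Num).

### Train/test split

Splitting is by district, never by sample, since all samples of a district
share one background estimate. The split draws `n_candidates` (default 1000)
random partitions and keeps the one minimizing
|train_pos − test_pos| + |train_neg − test_neg|, tie-broken by total-sample
balance; it is deterministic given the seed. Undefined metrics (a split
stratum without positives or negatives) raise an error rather than yielding
NaN, so degenerate splits fail loudly during ROC construction.

### Fixed-SBR comparator

The conventional rule declares a sample positive when
(mean measurement rate)/(flat background mean) ≥ a fixed cutoff (1.5 or 2.0;
boundary inclusive). The arithmetic mean rate is used as the numerator, being
the conventional probe readout; no smoothing is applied anywhere.

## Synthetic data

`generate_cohort` draws a cohort whose *structure* matches a first-in-human
prostate-cancer series: 7 patients, 3–4 districts each (≈ 25 total),
1 + Poisson(1.64) samples per district (≈ 66 total), 47% pathology-positive,
background acquisitions of 5–10 s, measurements of 5–20 s (20% of samples
measured twice), all within 20–152 min after injection. Per 1 s bin, counts
are Poisson with mean = district background rate × multiplier × 2^(−t/T½).
Background rates are log-normal with median 100 CPS (log-sd 0.4); tumor
multipliers are uniform on 1.2–5.0; healthy multipliers are log-normal around
1.0 (log-sd 0.05). The clinical distributions of background rate and lesion
uplift are unpublished, so these are order-of-magnitude placeholders, not
calibrated values. An optional additive `gamma_floor_cps` (default 0) mimics
shine-through-like floor signal for robustness experiments. Districts are
independent; there is no spatial correlation, no detector-efficiency model,
and no dead-time behaviour — passing tests on this generator demonstrate the
statistical machinery, not clinical performance.

`make_separable_cohort` reuses the structural draw but replaces all streams
with noise-free levels: background ramps over 95–105 CPS (flat mean 100,
σ_flat = 10/√12 ≈ 2.89), tumors constant at 200 CPS (≥ 10 σ_flat above the
cutoff at every grid N_σ), healthy nodes constant at 95 CPS (below the flat
mean). It is the ground truth for end-to-end recovery checks: the pipeline
must classify it perfectly out of sample for essentially every seed. The
recovery experiment in the tests and acceptance script runs 50 seeded
replicates of this cohort and requires held-out sensitivity and specificity
≥ 95% in at least 95% of them. On Poisson-noisy cohorts no selection rule can
meet such a bound: a test stratum of ~15 nodes makes a single misclassified
node cost ~7 percentage points, and choosing the empirically cleanest cutoff
on ~35 training samples is a winner's-curse construction whose held-out error
is of exactly that order. The complementary no-information experiment
(multipliers ≡ 1 for tumor *and* healthy, so both are identical in law, at
~200 samples) checks that measured "sensitivity" is statistically
indistinguishable from the false-positive rate.

## Numerical choices and edge cases

* Background estimates need ≥ 2 counts; a degenerate background
  (max = min) gives σ_flat = 0, so the cutoff equals the mean for every N_σ —
  allowed, but flagged with a validation warning.
* Backgrounds shorter than 5 s warn (protocol deviation) without rejecting.
* Multiple background acquisitions of one district are concatenated before
  the max/min scan — one estimate per district, by the district's definition.
* Corrected counts are real-valued; all comparisons operate on real rates.
* Sub-second exposures, dead-time correction, and detector physics are out of
  scope.
* Empty label strata raise `UndefinedMetricError`; the pipeline never emits
  silent NaNs.
* Problem sizes in the test suite (cohorts of ~60–70 samples, 50-replicate
  recovery runs, 10 000 s decay streams) match the scale of the emulated
  study while keeping the whole suite in the tens of seconds.

## Known limitations

The flat-distribution background is a heuristic, not an efficiency-optimal
estimator; its σ grows with acquisition length for Poisson data (range of n
draws), so cutoffs from very long backgrounds are systematically more
conservative. The train/test split is a single partition, not
cross-validation. The generator's uplift and jitter distributions are
placeholders; absolute sensitivity/specificity numbers obtained on synthetic
cohorts say nothing about clinical performance.
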