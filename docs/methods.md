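# Methods

This note documents the models, conventions and free parameters behind
`blinkcr`, and what the synthetic closed loop does and does not establish.

## Conditioning protocol

Week 1 consists of 3 US-alone exposures (UR calibration only; excluded from
all CR statistics) followed by 60 acquisition trials (30 CS+, 30 CS−);
Week 2 is 30 acquisition trials (15/15) with no US-alone exposures. Trial
order is drawn by rejection sampling: the multiset of trial kinds is
shuffled and re-drawn until no same-kind run exceeds 3, which makes the
distribution exactly uniform over admissible orders (verified against a
brute-force enumeration on a small instance). The run-length constraint is
applied to acquisition trials only; the leading US-alone block is fixed.
Stimulus timing places CS onset 1,000 ms into the 3,000-ms trace (leaving a
full 250-ms baseline and a post-stimulus tail); the US onset for paired
trials is CS onset + 450 ms (co-termination of the 500-ms tone and 50-ms
puff). The inter-trial interval is uniform on 15–30 s and is recorded per
trial but feeds no downstream computation.

## EMG model and simulator

Traces are 3,000 samples at 1 kHz. Baseline activity is Gaussian noise
spectrally confined to 1–30 Hz (synthesised in the frequency domain, so the
band limit is exact), with SD `sigma_baseline = 0.05` envelope units.
Blinks are smooth unimodal bursts: Gaussian envelopes whose full width at
half maximum is uniform on 30–60 ms and whose peak amplitude is log-normal
with median 0.65 (≥ 3× the 0.2 detection threshold; log-scale SD 0.25).
CR latency is uniform on 120–400 ms post-CS (inside the scoring window), UR
latency uniform on 25–60 ms post-US with median amplitude 1.0, and
spontaneous blinks arrive at Poisson rate 0.05/trial, placed outside the CR
window unless configured otherwise. Two trace modes exist:

* **envelope** (default): the trace is the post-preprocessing envelope plus
  band-limited noise, flagged pre-filtered; the detector skips its
  band-pass.
* **raw**: the envelope modulates a 15-Hz carrier (scaled by π/2 so the
  rectified mean matches the envelope amplitude) and the detector must
  band-pass, rectify and smooth. Carrier ripple fragments burst peaks, so
  raw-mode sensitivity is a few points lower — a deliberate stress test of
  the preprocessing, not the calibrated operating point.

What the simulator does **not** model: motor-unit physiology, electrode
artifacts, alpha/startle responses, session-level drift. Passing closed-loop
tests therefore show that the pipeline recovers what this generative model
plants — not that the detector is robust to every real-world artifact.

## CR/UR detection

Preprocessing is a zero-phase Butterworth band-pass (1–30 Hz, order 6,
applied forward-backward with generous padding to suppress the slow 1-Hz
edge transient), full-wave rectification, and a moving-average smooth of
half-width 12 ms. Candidate CR events are local maxima of the smoothed
envelope in the half-open window [CS onset + 80 ms, US onset); on CS−
trials the window ends at the *virtual* US onset (CS + 450 ms) so both trial
types are scored over identical windows. A candidate is accepted iff

1. amplitude > 0.2 (unitless threshold),
2. amplitude > baseline mean + 2 × baseline SD (250 ms immediately
   pre-stimulus; sample SD), and
3. min(rising slope, |falling slope|) ≥ `min_slope`, slopes measured ±25 ms
   about the peak.

The earliest passing candidate is the CR event. The conjunctive reading of
(1) and (2) — failing either criterion rejects the peak — matches the
scoring convention's intent of discarding sub-threshold peaks. URs use the
same criteria in [US + 20 ms, US + 500 ms]; UR magnitude is peak amplitude
minus baseline mean.

`min_slope` is the one criterion the convention leaves quantitatively open
("steep enough to resemble a blink"). The default 0.004 /ms — a
0.2-amplitude rise over 50 ms — passes the simulated burst population
(FWHM ≤ 60 ms) while rejecting drifts on the order of 0.3 amplitude over
800 ms. It is a free parameter and is surfaced as such in
`DetectionConfig`. Whether both slopes or their minimum must pass is also
unstated in the convention; the minimum is used here so a burst riding a
slow shoulder is not rescued by one steep side.

At the default operating point the closed loop measures hit rate ≈ 0.985
and false-positive rate < 0.01 on blink-free CS− trials (the acceptance
suite enforces ≥ 0.95 / ≤ 0.05).

## Scoring

CR% is computed per block of 10 acquisition trials — forced by 60 Week-1
and 30 Week-2 trials over 6 and 3 blocks — pooling CS+ and CS− trials,
which are scored over identical windows; a `cs_plus_only` switch supports
sensitivity analyses. The learning series is the 9-vector
[w1b1…w1b6, w2b1…w2b3]; subjects missing a session are excluded and
reported.

## Latent learning profiles

Per-block CR probability follows saturating growth
p(b) = p_start + (p_asymptote − p_start)(1 − e^(−rate·b)); Week 2 restarts
from retention × the Week-1 final value and grows toward the asymptote.
Defaults:

| profile | p_start | p_asymptote | rate | retention |
|---|---|---|---|---|
| HIGH | 0.40 | 0.70 | 0.9 | 1.00 |
| MID | 0.05 | 0.50 | 0.35 | 0.90 |
| LOW | 0.05 | 0.14 | 0.5 | 0.85 |

These are stand-ins calibrated to the qualitative shape of the published
learning curves (fast/high early responder, gradual intermediate, flat low
learner); the source reports those curves only graphically, so no numeric
value here is a published claim, and all are configurable. Profile
membership is enriched in PTSD+ subjects (P(HIGH|PTSD+) = 10/25 vs 4/29 in
PTSD−), matching the published profile-by-PTSD cross-tabulation.
Questionnaire totals are truncated-normal draws around the published group
means/SDs, with the PCL-5 additionally truncated on the group-defining side
of the 33 cut-off so drawn group labels survive rescoring; totals are
decomposed into item responses by random unit increments (only totals and
cluster sums are analysed downstream). Seeding is hierarchical — one master
seed, fixed per-subject child streams — so cohorts extend without
reshuffling existing subjects.

## Mixed RM-ANCOVA

The 2×2×k model is estimated via the orthonormal-contrast decomposition:
subject means (scaled by √k) regressed on the sum-to-zero-coded between
design [1, PTSD, mTBI, PTSD×mTBI, centred age] give the between stratum;
the k−1 orthonormal Helmert contrast scores regressed on the same design
give the within stratum, pooling SS across contrasts. Type III sums of
squares come from full-vs-reduced residual comparisons; with n = 54 this
yields the design's df: between 1,49 and within 5,245 (Week 1) / 2,98
(Week 2), i.e. the age covariate consumes a df in both strata. Partial η²
is SS_effect/(SS_effect + SS_error) within stratum.

Mauchly's W is computed on the contrast covariance of the between-model
residuals, with Box's chi-square approximation including the second-order
ω₂ term (matching SPSS/ezANOVA; cross-checked against pingouin).
Greenhouse–Geisser ε̂ = (tr S_c)²/((k−1)·tr S_c²), clipped to
[1/(k−1), 1]. By default GG-corrected p-values replace uncorrected ones
only when Mauchly rejects at α = 0.05 (`gg_policy="mauchly"`); "always"
and "never" are available. Note the familiar claim "the GG p-value is
always ≥ the uncorrected p" holds in the rejection-relevant region but can
reverse for F below ≈ 1, where shrinking both df can raise the tail mass;
the test suite asserts the property where it is true.

Post-hoc simple effects use pooled-variance (Student) t-tests — reproducing
integer dfs like t(32) for a 21 + 13 comparison — with Bonferroni
correction. Helmert contrasts on three ordered groups test Low vs
mean(Mid, High) and Mid vs High on the one-way ANOVA error term.

Degenerate designs abort: any empty or singleton between-cell raises, as
does a collinear covariate. `covariate=None` fits the same model without
the age term (used by the exactly-solvable oracle tests).

## Subtyping

Learning series are clustered on raw CR% (no standardisation — all inputs
share units) with squared Euclidean dissimilarity and complete linkage.
The cluster count is chosen by majority rule over a 15-index internal
validity panel; ties break toward smaller k (parsimony). The panel mixes
extremum-rule indices (Calinski–Harabasz, silhouette, Dunn,
Davies–Bouldin, Ratkowsky–Lance, C-index, McClain–Rao, point-biserial)
with difference/elbow-rule indices (Hartigan, Ball–Hall, TraceW, Scott,
Marriot, Friedman, Rubin), whose votes are computed from successive or
second differences *within the candidate range* — so, as in the reference
majority-vote implementation, an elbow index cannot select the boundary k.
This rule-type mix matters: on three ordered learning-curve clusters,
extremum indices lean toward k = 2 (the low/rest split), and it is the
elbow bloc that recovers the three-group structure, mirroring how a
minority-but-plurality of a large index panel settled on three groups in
the original analysis. The panel and every index score are emitted with
the result for audit. Two known index idiosyncrasies are documented in the
tests: McClain–Rao drifts toward many clusters even under perfect
separation, and elbow indices never vote for the smallest candidate k.

Week-2-only mode clusters the three Week-2 blocks with a three-group
solution specified (the follow-up analysis design); full-data mode selects
k by vote over k = 2…8. Clusters are labelled HIGH/MID/LOW by descending
grand-mean CR% (ties broken by cluster id). Profile comparisons run
one-way ANOVAs with partial η² on PCL-5 total and clusters B–E, PHQ-8 and
AMBI, Helmert contrasts, and positive-flag proportions per profile.

## Questionnaires

PCL-5: 20 items (0–4), total 0–80, provisional PTSD at ≥ 33; DSM-5
cluster blocks B = items 1–5, C = 6–7, D = 8–14, E = 15–20 (the standard
mapping; the instrument description names clusters but not indices).
PHQ-8: bands None 0–4 / Mild 5–9 / Moderate 10–14 / Moderately Severe
15–20 / Severe > 20; aggregate positive at ≥ 10; symptom rule = an anchor
item (depressed mood or anhedonia) ≥ 2 plus ≥ 5 of 8 items ≥ 2.
AMBI: 16 items (0–2), total 0–32, behaviourally inhibited at > 15.5.
mTBI: injury event + altered consciousness + (no LOC or LOC ≤ 30 min);
this predicate approximates the clinical screening tool's decision tree,
which is not fully public, and is swappable via its `loc_limit_min`
argument.

## Numerical and testing choices

Problem sizes were chosen so each suite completes comfortably on one CPU:
type-I calibration of Mauchly and the ANCOVA uses 2,000 null replicates at
n = 40, k = 6; the full simulate→detect→score→ANCOVA calibration uses
1,000 replicates at n = 16 (4 per cell) with a flat learning profile so
every effect, including Block, is null; linkage is verified against a
naive O(n³) agglomerative oracle on all instances n ≤ 7; the paper-analog
closed loop runs 10 full 54-subject studies. Hypothesis-based property
tests are seeded/derandomised.

Known limitations: the simulator's envelope mode bypasses the band-pass
(by design); raw mode loses a few points of sensitivity to carrier ripple;
the item-level questionnaire decomposition is not psychometrically
realistic (only totals are analysed); the majority-vote outcome depends on
the index panel's rule-type composition, which is why the panel is emitted
verbatim with every run.
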