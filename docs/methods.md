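# Methods

This note documents the models, parameter choices and numerical decisions
behind `movesync`, and what the synthetic experiments do and do not show.

## Problem setting

Two people in conversation tend to coordinate their body movement. Given a
split-screen video, *motion-energy analysis* (MEA) reduces each person to a
univariate time series: the percentage of their region of interest (ROI)
whose pixels changed appreciably between consecutive frames. The scientific
question the package serves is methodological: the literature offers many
numerically different "synchrony" statistics for such bivariate series, and
their mutual agreement (convergent validity) and clinical sensitivity
(predictive validity) cannot be taken for granted. `movesync` implements a
battery of 21 measures from seven algorithm families plus the cohort-level
statistics needed to compare them.

## Motion-energy stage

- Frame differencing counts ROI pixels with `|I(t+1) − I(t)| ≥ 12` of 256
  gray levels. The comparison is inclusive (`≥`); the strictness is
  exposed as a flag because the conventional description ("cut-off 12")
  does not fix it.
- Counts are standardized to percent of ROI (`100·count/size`) so 0 means
  no motion and 100 a fully activated ROI, then smoothed with a centered
  moving median of 5 frames. At the series ends the median window shrinks
  symmetrically (the edge value is the raw value, the next uses 3 frames),
  which preserves length without inventing data.
- A single ROI mask per person is assumed; multiple body-part masks can be
  combined by OR-ing before the count.

## The synthetic cohort

Real interview recordings are not distributable, so the package ships a
generator whose output is statistically similar to preprocessed
motion-energy series and whose coupling structure is known exactly.

**One member** is a burst process: the number of movement bursts is Poisson
(default 2 per minute), bursts are placed uniformly in the remaining free
space so they never overlap (a hard-core thinning that only bites at high
occupancy), each burst is a raised-cosine hump (default 250 frames = 10 s,
peak 20 % of ROI), on a baseline of 0.5 % with Gaussian noise (SD 1) and
final clipping to [0, 100]. Default length is 15 000 frames (10 min at
25 fps), inside the 10 000–45 000 range typical of recorded interviews.

**A dyad** adds episodic coupling: during each scheduled synchronization
interval (default 0.8 per minute, 500 frames long, lag uniform in ±25
frames) the second member's segment is replaced by `sign · β · A` shifted
by the lag, plus fresh noise; anti-phase coupling maps through the burst
peak level so values stay non-negative. Outside intervals the members are
independent. The schedule is returned as ground truth, which is what makes
interval-detection tests possible.

**A cohort** (default 30 dyads, 15/15 control/patient) draws a latent
coupling coefficient β per dyad from a group-specific normal (control mean
0.9, SD 0.25; patient mean lower by 0.45) truncated at zero. Symptom sums
are linear in β with a patient offset, rounded and truncated to the
instrument ranges (PHQ9 0–27, GAD7 0–21): depressed-group dyads are both
less coupled and more symptomatic, which is the direction of the clinical
hypothesis the validity statistics probe. One global seed expands into
per-dyad sub-seeds via `SeedSequence.spawn`, so whole cohorts are
bit-reproducible.

What the generator does *not* model: realistic kinematics, turn-taking
structure, nonstationary baselines, camera artifacts, or any facial/vocal
channel. Passing tests therefore demonstrate algorithmic correctness and
calibration under a known coupling model — not field validity on clinical
recordings.

## Measure battery

All measures run on the same standardized, smoothed series; positive lag
always means the second member follows the first.

**CC family.** Global Pearson correlation at lag 0 (CC-raw) plus |r|,
Fisher-Z and r². |r| is clamped at 1 − 10⁻⁷ before `atanh` so noiseless
fixtures cannot produce infinities; the clamp is flagged. Because `atanh`
and squaring are strictly monotone, raw/Z and abs/R² columns are perfectly
rank-correlated across any cohort — a built-in sanity check on the
correlation matrix.

**rMEA-style WCC/WCLC.** Windows of 60 s stepped by 30 s, lags to ±5 s in
frame steps; each cell is `atanh(|r|)` of the window pair, so cells are
non-negative. WCC averages the lag-0 column, WCLC the whole grid. Lagged
windows that leave the series make the cell missing; missing cells are
excluded from all means. The pseudo-synchrony test recombines each dyad's
A with the B of another dyad (uniform with replacement, 100 shuffles,
pairs truncated to the shorter length) and standardizes the real measure
against the shuffled distribution.

**SUSY.** Non-overlapping 30 s segments; per segment the cross-correlation
at every integer-frame lag in ±5 s, Fisher-Z, averaged over lags either
sign-free (Z_abs) or signed (Z_noabs); the dyad value is the mean of
segment scores. Lagged windows may read into the partner's neighboring
frames when available; otherwise the lag is skipped for that segment. The
surrogate ensemble is the exhaustive set of n(n−1) ordered non-identical
segment pairings — deterministic, no seed — and the effect size is
`ES = (Z − mean_surr)/SD(surr)` (sample SD). By construction, applying the
standardization to the ensemble itself gives mean 0, SD 1 exactly.

**SUCO.** Local least-squares slopes in 3 s windows stepped by 1 s,
windows aligned to segment starts (the last window of a segment may read
past the segment edge but must fit in the series). Per segment the two
slope sequences are Pearson-correlated (r_i, degenerate segments dropped
with a relative variance guard so rounding noise on a pure ramp does not
masquerade as variation); `Z'_abs` is the mean of `atanh|r_i|` and the
concordance index `CO = ln(Σ r_i>0 / |Σ r_i<0|)`. CO is reported missing
(not ±∞) when all r_i share one sign. ES_abs uses the same pairwise
ensemble as SUSY. ES–CO cannot: a single segment pair has one r_i and no
finite CO. Each CO surrogate is therefore a full cyclic-shift dyad (A
segment i paired with B segment i+k mod n, k = 1…n−1), which partitions
the same n(n−1) pairings into n−1 complete surrogate dyads and keeps the
ensemble exhaustive.

**WCLC-PP / WCLR-PP.** Windows of 125 frames at unit increment, lags to
±125 frames. WCLC cells are squared window correlations; WCLR cells are
`ΔR² = R²(follower ~ own-past + partner) − R²(follower ~ own-past)`,
computed from the pairwise window correlations
(`R²_M2 = (r_y1² + r_y2² − 2 r_y1 r_y2 r_12)/(1 − r_12²)`), floored at 0.
At lag 0 the follower window equals its own predictor, so the WCLR lag-0
column is structurally zero — zero-lag coupling is invisible to WCLR by
design of the autocorrelation adjustment. Cells failing the (incremental)
F test at α = 0.001 are set to zero; both modes share the filter behind
the same flag, defaulting to on. For negative lags the member roles are
mirrored, preserving leader–follower symmetry.

Peak picking selects per-row local maxima along the lag axis (strictly
greater than the nearest distinct neighbors; a plateau contributes its
smallest-|lag| cell; row edges count as −∞), chains same-lag maxima over
consecutive rows, resolves row-sharing conflicts by keeping the interval
with the larger mean (the loser is discarded entirely; ties break toward
earlier start, then smaller |lag|) and retains intervals with mean
strength > 0.25. F counts the fraction of window-start rows covered
(a frame-coverage alternative is exposed separately); R² pools the member
cells of all retained intervals.

**Mutual information.** Plug-in MI in nats from Gaussian product-kernel
densities (Silverman bandwidths per series), evaluated at the sample
points; all normalization constants cancel in the log ratio except a
`ln m` term. Bias correction is a delete-block jackknife over 50
contiguous blocks (`MI_cor = B·MI − (B−1)·mean(MI₋b)`), which keeps the
cost at one O(n²) kernel pass (symmetric blocks are evaluated once) and
keeps serially dependent neighbors inside the same deleted block;
bandwidths stay at their full-sample values across replicates. MI-Z is
MI_cor over the jackknife SE. The raw value is floored at 0; the
corrected value may be slightly negative. No numerical equivalence with
any particular MI library is claimed — the tests pin down symmetry,
affine invariance, null calibration and dependence ordering instead.

**WinCRQA.** Series are min–max rescaled to [0, 1] and delay-embedded with
dimension 3 and delay 1 frame (the delay is a package choice; it is
exposed in `CrqaParams`). Windows of 1500 frames with 750 overlap; within
a window, states of the two trajectories recur when their Euclidean
distance is below ε = 0.05, restricted to the diagonal band |i−j| ≤ 125 —
the same ±5 s lag range as the correlation methods (a full-matrix mode
exists behind the same parameter). RR is the percent of recurrent band
cells; DET the percent of recurrent points on diagonal runs of ≥ 2
(undefined when RR = 0); ENTR the Shannon entropy of the run-length
distribution normalized by the log of the number of distinct lengths (0
with fewer than 2 distinct lengths; the raw entropy is also reported).
Window values are averaged with NaN-aware means.

## Validity statistics

The cohort table (one row per dyad, 21 measure columns, group and symptom
columns) feeds four analyses, all with pairwise deletion of missing
values and no multiplicity adjustment by default (Benjamini–Hochberg is
available but off, so significance stars mean unadjusted p < 0.05):

- **Correlation matrix**: Pearson below the diagonal, Spearman above,
  two-sided p per cell.
- **Parallel test**: observed eigenvalues of the correlation matrix
  against the 95th percentile of eigenvalues from 100 reference data sets.
  The reference sets are per-column independent bootstrap resamples of the
  observed data (preserving marginals, destroying dependence); Gaussian
  simulation is available as an alternative. Resampling whole rows would
  preserve the observed correlations and make the test vacuous, which is
  why the column-wise scheme is the default.
- **ML-EFA**: maximum-likelihood extraction (statsmodels) on the Pearson
  matrix, quartimin (oblimin family, γ = 0) oblique rotation, RMSEA/TLI
  from the Bartlett-corrected χ², RMSR over off-diagonal residuals.
  With 30 rows and 21 measures the matrix is heavily ill-conditioned; the
  fit is attempted anyway with a logged warning and Heywood cases are
  flagged but returned — deliberately reproducing, and surfacing, the
  statistically strained situation of a small clinical cohort. Minimum
  rank factor analysis is out of scope; reports are ML-only.
- **Group comparison and symptom correlations**: two-group Kruskal–Wallis
  p per measure, Hedges g (pooled SD, correction `1 − 3/(4N−9)`, patient
  minus control), and Pearson/Spearman correlations with PHQ9/GAD7.
  Cohen's verbal labels (r: 0.1/0.3/0.5; g: 0.2/0.5/0.8) are available
  as annotations.

## Problem sizes in the test suite and acceptance script

Oracle-equivalence tests run on instances of ≤ 1000 frames against
literal double-loop implementations at 10⁻¹⁰ relative tolerance. Null
calibrations use 200 independent dyads of 3750 frames (5 segments); the
peak-picking null uses 100 white-noise replicates of 1000 frames; factor
recovery uses n = 200 with planted 0.8/0.0 loadings. The end-to-end
determinism check runs the full 30-dyad, 15 000-frame cohort through the
battery twice and requires bit identity. The acceptance script repeats
the cohort pipeline once and the calibration experiments at 100 null
dyads / 50 null replicates / 20 parallel-test replicates. These sizes are
the package's chosen compromise between Monte-Carlo resolution and a
suite that runs in minutes.

## Known limitations

- Detection power for group contrasts is moderate under the default
  episodic-coupling conditions (~27 % of the recording coupled): on
  full-length cohorts roughly a quarter of the measures separate the
  groups at p < 0.05, led by the rMEA means and the PP frequency
  measures, and directional properties (negative Hedges g, negative
  symptom correlations) are recovered reliably — but no guarantee of the
  form "some measure is significant in ≥ 80 % of cohorts" holds at these
  settings, and the suite does not assert one.
- WCLR's autocorrelation adjustment makes smooth, self-predictable
  signals largely invisible to it (including all zero-lag coupling);
  recovery tests therefore use low-autocorrelation drivers.
- The CRQA embedding delay, minimum diagonal line (2) and band semantics
  are package choices where the field's conventions vary; all are
  configurable and sensitivity to them is not explored here.
- MI values depend on the bandwidth rule; only bandwidth-robust properties
  are asserted.
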