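# Methods

## The index and the processing chain

The short-term memory load index (STMLI) is the ratio of relative theta
(3–7 Hz) to relative gamma (30–40 Hz) power spectral density at the frontal
midline electrode Fz, evaluated for every 1-second epoch of each timed task
and aggregated per participant × task with a 5% trimmed mean.

The chain reproduced here, stage by stage:

1. **Referencing.** Scalp channels (Fz, F3, F4, Cz, C3, C4, POz, P3, P4) are
   re-referenced to the mean of the two mastoid electrodes; the mastoids are
   then dropped. Re-referencing a second time is an error, not a no-op.
2. **Filtering.** Zero-phase 4th-order Butterworth band-pass 0.5–65 Hz.
   Because forward–backward filtering squares the magnitude response, the
   design cutoffs are pre-warped by (√2−1)^(1/8) ≈ 0.896 so the *combined*
   response is 3 dB down at the nominal cutoffs. Notch filters at 50, 60,
   100 and 120 Hz are second-order IIR sections with a fixed 3.2 Hz −3 dB
   bandwidth per pass; after the double pass this gives ≥ 20 dB attenuation
   within ±0.5 Hz of each notch while changing the response by < 1 dB at
   ±5 Hz. A fixed bandwidth (rather than fixed Q) is needed to meet both
   constraints at every notch frequency simultaneously.
3. **Artifact detection and decontamination.** One auditable detector per
   artifact class, all thresholds configurable (`PreprocessConfig`):
   - *saturation*: |x| ≥ 350 µV sustained ≥ 4 samples. The rail itself
     cannot be used after filtering: a 0.5-s clipped plateau at 1000 µV
     droops to ≈ 38% of the rail once the 0.5 Hz high-pass removes its DC
     content, so the trigger is placed below that droop but above the
     largest physiological deflections the generator produces.
   - *spike*: sample-to-sample step > 45 µV. A 200 µV single-sample spike
     emerges from the zero-phase band-pass as a ≈ 72 µV step, against a
     background step s.d. of ≈ 8 µV; 45 µV is ≈ 5.5 σ.
   - *excursion*: departure > 200 µV from a 1-second block-median baseline
     (piecewise-constant median rather than a running median; O(n) and
     equally effective for baseline estimation at these time scales).
   - *EMG*: RMS of the 30–100 Hz component > 20 µV in 0.25-s windows with
     50% overlap (clean-signal windows stay below ≈ 9 µV).
   - *blink*: on frontal channels, a 0.5–8 Hz component whose moving-max
     envelope (150 ms) exceeds 60 µV triggers an event that extends to the
     surrounding 20 µV contour. The envelope bridges the zero-crossings
     inside a single slow deflection; without it one blink fragments into
     disjoint lobes and sample-level coverage drops.
   Every event is padded by 25 ms on both sides. Flagged samples are
   replaced by exact zeros ("zero insertion"), which the spectral stage
   counts to apply the rejection rules. Detection operates on the filtered
   recording; thresholds were derived from the filter chain's analytically
   known response to each artifact shape, not fitted to data.
4. **Spectra.** Each task interval is tiled with consecutive 1-s epochs
   (trailing partial seconds discarded). For the epoch starting at t the
   three overlays are [t−0.5, t+0.5), [t, t+1) and [t+0.5, t+1.5), clamped
   to the task interval, so interior epochs have three overlays and boundary
   epochs two. Each 256-sample overlay is Kaiser-tapered and Fourier
   transformed; with 1-second windows at 256 Hz every FFT bin falls on an
   integer frequency, and bin k (1–40) represents [k−0.5, k+0.5) Hz. Power
   uses Parseval (energy) normalization, which makes a sinusoid's summed
   power exactly taper-invariant. An overlay with more than 128 zeros is
   rejected; an epoch with fewer than two usable overlays is invalid.
   Valid overlays are averaged and normalized by the summed 1–40 Hz power;
   in the default linear domain the 40 relative bins sum to exactly 1.
   Band values are means of the constituent bins: theta 3–7, alpha 8–12,
   low beta 13–19, high beta 20–29, gamma 30–40 Hz.
5. **Index and aggregation.** STMLI = theta/gamma at Fz per valid epoch;
   epochs with exactly zero relative gamma (degenerate synthetic input) are
   dropped with a logged count. Per participant × task the epochs are
   aggregated with a per-tail 5% trimmed mean — floor(0.05 n) values
   removed from each end — so no trimming occurs below n = 20.
6. **Statistics.** (i) Behavioral-style measures: independent t-tests whose
   variant (pooled vs Welch) is gated by Levene's test (mean-centered,
   α = 0.05), with per-tail 5% trimming available as a robust descriptive
   convention, and Dunn–Bonferroni control via the t quantile at α/2m.
   (ii) STMLI cohort: listwise completion, Mahalanobis screening against
   χ²(9) at p < 0.001, then a 2 (group) × 9 (task) mixed ANOVA with
   classical partitioned sums of squares. Mauchly's W and the
   Greenhouse–Geisser ε come from the within-group pooled covariance of the
   repeated measures (ε clipped to [1/(k−1), 1]); when Mauchly rejects at
   α = 0.05 the within and interaction dfs are multiplied by ε. Partial η²
   is SS_effect/(SS_effect + SS_error) with each effect's own error term.
   (iii) PCA of the 9-task correlation matrix with KMO and Bartlett
   (χ² = −(n−1−(2p+5)/6)·ln det R, df = p(p−1)/2) diagnostics; components
   with eigenvalue > 0.80 are retained, varimax-rotated (Kaiser-normalized,
   tol 1e-6, ≤ 100 iterations); Anderson–Rubin scores
   W = R⁻¹L(LᵀR⁻¹L)^(−1/2) have exactly zero mean and identity sample
   covariance; with two components retained the scores enter a 2 × 2 mixed
   ANOVA (no sphericity correction is possible or needed at k = 2).

The mixed-ANOVA partition was verified to agree with pingouin's
implementation to full precision on balanced and unbalanced designs, and the
varimax rotation attains the same criterion value as statsmodels'; both
libraries serve as independent oracles in the test suite, not as the
implementation.

## The synthetic-data generator

Each scalp channel is Gaussian 1/f^α background (α = 1, RMS 15 µV over
0.5–128 Hz, shaped in the frequency domain so the one-sided PSD is exactly
c/f^α) plus sinusoidal oscillators at the band centers — theta 5 Hz, alpha
10 Hz, gamma 35 Hz — active only inside task intervals, with one random
phase per task interval. Because the model is a power law plus pure tones,
the relative band powers implied by the generating amplitudes are available
in closed form and are stored as each session's ground truth. A phase that
is constant within a task (rather than redrawn every second) is required for
that closed form to hold: a phase discontinuity inside an analysis window
scatters sidelobe power across all bins, measurably corrupting both the
theta-band estimate and the gamma band.

Default generating amplitudes are theta 6, alpha 6, gamma 5 µV RMS. These
place the oscillator band powers at or above the in-band background power
(theta: 36 vs ≈ 45 µV²; gamma: 25 vs ≈ 13 µV²), so band estimates are
signal-dominated, and they put the baseline STMLI near 5 on the linear
relative-PSD convention. The concussion-history group carries 1.25 × the
gamma amplitude on the four visuo-motor-control tasks (PS, HRT, EHC, GNG);
with a per-participant, per-band log-normal amplitude multiplier of σ = 0.05
(≈ 5% inter-individual spread, constant across tasks) the injected contrast
corresponds to a standardized between-group effect large enough to be
detected reliably at the default 56 vs 17 group sizes, mirroring a clearly
significant group effect rather than a borderline one. Mastoid channels are
0.5 µV white noise, so linked-mastoid referencing is exercised without
distorting the truth.

Artifacts per class, at cohort-default rates per minute: blinks (12) as
0.4-s raised-cosine deflections of 100–300 µV applied jointly to the three
frontal channels; EMG bursts (1) as 1–3 s of 20–100 Hz noise at 60 µV RMS on
one channel; spikes (0.5) as single-sample ±200 µV excursions; saturations
(0.2) as 0.5-s segments pinned at ±1000 µV. Injected events are logged as
per-channel truth intervals, against which the detectors achieve ≥ 90%
sample-level recall per class at default thresholds with < 1% false
positives on clean sessions.

What the generator does *not* emulate: volume conduction or any head model
(channels are independent), cross-frequency phase–amplitude coupling,
non-stationary band power within a task, realistic blink morphology beyond a
raised cosine, or behavioral outputs of the tasks beyond marker intervals.
Passing tests therefore demonstrate that the pipeline recovers known
spectral structure under realistic noise and artifact contamination — not
that the index behaves identically on real recordings.

## Numerical and design choices

- **Kaiser β = 2 (configurable).** The taper's mainlobe must stay inside a
  single 1-Hz bin for band attribution to be crisp: at β = 2 a bin-centered
  sinusoid keeps > 95% of its power in its own bin, whereas at β = 8 the
  mainlobe spreads across ±2–3 bins and that figure drops to ≈ 60%.
- **Relative-PSD domain.** Default is linear (bin / Σ bins, bins sum to 1).
  A `log10` mode (normalization applied to log10-PSD values) is selectable
  in `SpectralConfig`; vendor pipelines differ on the order of the log
  transform and the normalization, and STMLI's group ordering is invariant
  to the choice (verified in the tests), though its absolute scale is not.
- **Overlay geometry.** The symmetric reading of "50% overlapping windows
  across three one-second overlays": overlays centered on the epoch,
  clamped at task boundaries; boundary epochs proceed with two overlays.
- **Trimmed mean.** Per-tail floor(0.05 n) (the EXAMINE convention of the
  major statistics packages), so short tasks are aggregated by a plain
  mean. An alternative total-10% reading would trim twice as much;
  the per-tail convention is the one the reported analyses imply.
- **Bonferroni critical t.** Computed from the t quantile at α/(2m) with
  the between-subject error df. For m = 9, df = 71 this gives 2.86; the
  published family-wise critical value of 2.82 for the same design differs
  slightly (consistent with a different df or table), so the quantile is
  computed from stated inputs rather than hard-coded.
- **Mahalanobis screening** uses χ² with df = number of variables at
  p < 0.001 — the usual multivariate-outlier convention when the screening
  rule itself is not further specified. A singular covariance is reported
  as an error, never silently pseudo-inverted.
- **Listwise deletion** for missing task cells within each analysis, with
  the dropped count logged.
- **EDF interchange** at physical range ±3276.8 µV gives exactly 0.1 µV
  per digital unit; round trips are verified to half a quantization step.
- **Sphericity at k = 2** is exact (ε = W = 1); the implementation skips
  the test rather than computing a 0-df statistic.

## Problem sizes in the tests and acceptance script

Unit tests use cohorts of 12–16 participants with 6–10 s tasks; the
acceptance script analyses one full cohort at the default 56 + 17 × nine
60-s tasks, runs the type-I calibrations at 10,000 (t-test) and 5,000
(mixed ANOVA) null replicates, and evaluates full-chain recovery over 50
cohorts with 10-s tasks — sizes chosen so the whole acceptance run
completes in minutes on a single CPU while keeping Monte-Carlo error well
inside the asserted bounds.

## Known limitations

- The generator's closed-form truth ignores the band-pass attenuation at
  the 0.5–1.5 Hz edge; the filter-aware oracle used in the spectral
  fidelity test accounts for it, and the discrepancy is ≤ a few percent of
  relative band power.
- Per-epoch STMLI is a ratio of noisy estimates and is biased upward
  relative to the truth ratio (Jensen); group comparisons are unaffected
  because the bias is shared, but absolute STMLI values should not be read
  as unbiased estimates of the generating ratio.
- The 2 × 9 ANOVA uses the classical weighted-means partition; with the
  strongly unbalanced default groups a Type-III (unweighted-means) analysis
  would differ slightly in the within and interaction terms.
- KMO is undefined (NaN) for an exactly diagonal correlation matrix.
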