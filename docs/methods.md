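# Methods

`obnorm` re-implements, as tested library code, the quantitative pipeline of
a study of olfactory-bulb output normalization in "monoclonal nose" (M71
transgenic) mice: calcium-imaging response calling and population
statistics, whole-cell membrane-potential metrics, and sniff/operant
behavioral measures — together with a synthetic-data generator that encodes
each genotype/condition's printed population statistics, so every stage of
the pipeline can be exercised and validated without any raw data.

## Imaging analysis

**ΔF/F and response criterion.** For each trial, F0 is the per-cell median
fluorescence over seconds [2, 6) of the pre-odor period and
ΔF/F = (F − F0)/F0. The baseline fluctuation is the SD of ΔF/F over the
whole pre-odor period, per cell and trial. A cell is called responsive on a
trial when its ΔF/F exceeds a threshold multiplier times its baseline SD on
at least 3 frames (not necessarily consecutive; a `consecutive=True` switch
is provided) within the 10 s after odor onset. Mitral cells use 3.2×SD,
periglomerular (PG) cells 3.4×SD, with 3.8×SD available as the stringent
variant. All windows are half-open `[start, end)`; frames are indexed from
trial start; cells are 0-indexed.

**Population statistics.** The responsive fraction of a site is the mean
over trials of (responsive cells / cells). Odor maps and tuning use only
cells responsive on ≥2 of 4 trials. The reliability histogram is the
distribution of k = number of responsive trials among cell-odor pairs
responsive at least once, pooled (count-weighted) over sites — per-site
histograms are dominated by small-sample noise at realistic site sizes.
Trial-to-trial pattern similarity combines all cells (responsive or not,
pooled across sites) into a single cells × (odor, trial) matrix of mean
ΔF/F over the 4 s after onset and averages the within-odor off-diagonal
Pearson correlations, odor by odor, with plain arithmetic means (no Fisher
z). Both a per-site variant (`within_odor_mean_correlation`) and the pooled
variant (`pooled_within_odor_correlation`) are exposed; the pooled variant
is the headline statistic, because the per-site estimator at ~35 cells is
strongly shrunk by sampling noise (we measure ≈0.65 per site where the
pooled readout gives 0.75).

**Concentration series.** LC is the ordinary-least-squares slope of
responsive fraction on log10(dilution), pooled over sites (a per-site
option averages per-site slopes; a `log_x=False` switch uses linear
concentration). ΔLC is the difference of slopes between a test and a
reference stimulus. The series' Pearson r is computed between per-site
fractions and log10(dilution) over all (site, concentration) points.

**Motion correction** is frequency-domain phase correlation with subpixel
refinement (scikit-image's implementation behind the module surface).

**False-positive calibration.** `calibrate_fpr` measures the empirical
false-positive rate of the criterion on response-free trials. With the
baseline SD known, the rate follows the binomial tail
P(X ≥ 3), X ~ Bin(n_window_frames, Φ̄(multiplier)); with the SD *estimated*
from ~50 baseline frames and F0 estimated from 10, the rate is far higher
(≈0.1% per cell-trial at 3.2×SD) because threshold underestimates and F0
offsets interact multiplicatively with the 3-frame rule. This estimated-SD
inflation plausibly explains why published FPRs for such criteria are in
the ~1% range; we expose the calibration rather than target any specific
value.

## Synthetic imaging data

Each site draws a latent responsive fraction from a normal law centered on
the profile mean, clipped to [0, 1]. The profile SD is interpreted as the
*total* empirical across-site SD; the expected within-site sampling
variance (binomial cell sampling plus trial participation) is subtracted
when drawing latent site means so the pipeline-recovered across-site SD
matches the printed one. The cell-level responder-pool rate is the latent
fraction × n_trials / E[k] (k ~ the profile's reliability vector), so that
the *trial-averaged* measured fraction — the paper-style readout — equals
the profile value. Per-cell rates follow a Beta law (concentration
`tuning_shape`, mean = pool rate) sampled through shared per-cell
quantiles, which makes responder sets nested across a concentration series
and reproduces the odor-tuning distribution (≈46% of cells silent across a
13-odor panel at control statistics).

Responders get a response identity per odor: peak amplitude (truncated
normal, floored at 0.14 ΔF/F ≈ 1.5× the nominal threshold so that trial
gain jitter cannot push true responses under the criterion, and saturated
at 1.3), duration, and onset latency within the first second of the odor
window. The kernel is an instantaneous rise with exponential decay whose
time constant is derived per event as τ = duration / ln(peak/threshold), so
the trace re-crosses the nominal threshold at the drawn duration.
Amplitude and duration scale with trial reliability
(`amp_reliability_coupling`, `dur_reliability_coupling`; duration only
upward): reliable responses are stronger and longer, a threshold effect
present in real data and the mechanism by which the generator reproduces
the printed within-odor pattern correlations (0.75 control vs 0.25
transgenic) while holding the reliability histogram at its printed masses.
The coupling values (0.4/0.2 control, 0.15/0.05 transgenic) were fixed by a
design-time moment calculation plus simulation sweep against those printed
values and then frozen.

On non-crossing trials a responder still emits a plateau-shaped transient
at `subthreshold_frac` of its amplitude, capped at 0.7 noise-SD below which
the ≥3-frame rule keeps noise-riding detections rare (~0.5% per trial); half
of the non-responders likewise carry consistent weak plateaus. This graded
sub-criterion activity exists in real recordings and carries part of the
trial-to-trial correlation. Noise is iid Gaussian per frame at 0.03 ΔF/F
(no shot-noise model); raw fluorescence is F0 × (1 + ΔF/F + noise) with
per-cell F0 around 100 a.u.

Residual estimator interactions are small but real: sub-threshold plateaus
plus F0-estimation error occasionally cross the criterion, shifting ~2
points of reliability-histogram mass upward from k=1; false positives add
~1–2% of cell-odor pairs at k=1. Both effects are visible in the migration
matrices of the test suite and are covered by the stated test tolerances.

## Electrophysiology

**Generator.** 20-kHz Vm = rest + sniff-locked theta (per-cell lognormal
amplitude matching the printed mean ± SD; per-cell uniform phase
preference) + Ornstein-Uhlenbeck noise (τ = 50 ms, 0.3 mV) + stereotyped
spikes + an odor-evoked two-level deflection aligned to the first
inhalation after valve opening (level over the 1-s odor window and tail to
5 s drawn from the profile's 1-s/5-s distributions). Spiking is Poisson at
a lognormal per-cell baseline rate; the odor-second rate is
(baseline + mean ΔFR) × a unit-mean lognormal gain, which respects the
rate ≥ 0 floor while keeping the measured ΔFR mean exact — an additive
normal ΔFR with the printed 13.3-Hz SD would be floored so often that the
measured mean would roughly double. Sniff events are Gamma renewal
processes; the respiration channel is a cosine of the interpolated cycle
phase (peak = inhalation).

**Analysis.** Spikes are upward crossings of median(Vm)+20 mV with a 1-ms
refractory; each is replaced by linear interpolation over a 6-ms window
(the window covers the full spike shape; with 4 ms a residual tail
survives). Awake evoked Vm: per trial, baseline = mean Vm over the 2 s
before valve opening; 1/2/5-s windows start at the first inhalation after
valve opening; the per-trial differences are averaged. The ±2 SD
significance rule uses the SD across trials of the baseline means (awake)
or across baseline-cycle residual means (anesthetized). Anesthetized evoked
Vm aligns to respiration peaks, subtracts the mean resampled baseline-cycle
waveform from the first complete post-valve cycle, and averages the
residual. Binned firing-rate responses use 0.25-s bins aligned to the first
inhalation post onset, baseline bins over the 2 s pre-valve (all windows
half-open), and a paired t-test across trials. Theta coupling uses sniff
cycles of 0.2–0.32 s within inter-trial intervals, resamples each cycle's
mean-removed Vm to 64 phase bins (phase 0 at the inhalation peak), averages
them, and reports strength = (max − min)/2 of the mean waveform and the
phase of its maximum; fewer than 5 qualifying cycles flags the result
low-confidence.

## Behavior

Sniff frequencies are inverses of mean inter-sniff intervals, using
intervals fully inside the 2-s pre-odor window (baseline) and intervals
beginning and ending within the odor window (response); straddling
intervals are excluded. Novelty adaptation pairs each (session, odor)'s
first-presentation response with the mean of its 2nd and 3rd, tested with a
paired t-test. The sniff generator is an inhomogeneous Gamma-renewal
process (shape 8, which avoids pathological short intervals) built by
time-rescaling, so rate steps at odor onset/offset are exact; the response
rate increment is drawn from the 1st-presentation distribution on the first
presentation of an odor and from the 2nd/3rd distribution afterwards, with
the total rate floored at 0.8 Hz. Go/no-go sessions are Bernoulli outcomes
per trial with S+/S− balanced 10/10 within each 20-trial block; accuracy is
percent correct (lick on S+, no-lick on S−) per block, and a session passes
when any block strictly exceeds the 75% criterion.

## Statistics

The two-sample KS statistic D, Bartlett's chi-square, Pearson r and the
paired t-test are implemented from their defining formulas (p-values from
the standard asymptotic reference distributions) and cross-checked against
independent implementations in the test suite. KS ties are handled by
evaluating right-continuous ECDFs at the union of observed points. The
variance-homogeneity screen reports Max(s²)/Min(s²) with the strict <4
rule.

## Default profiles and study sizes

Named profiles carry the printed statistics of each condition: control
mitral panels (14 sites × 35 cells, 13 odors × 4 trials, responsive
fraction 14.5 ± 11.2%, reliability 56/20/10/14%), the transgenic
low-concentration panel (7 sites × 28 cells, 4-of-4 mass 2.9%; the k=1..3
masses are the control proportions rescaled, since only the 4-of-4 value is
printed), acetophenone concentration series (10.0/28.7/50.1% at
0.01/0.1/1%, SDs 11.2/17.1/25.8%), PG profiles (48/85.1/94% transgenic vs
~11% control; 3.4×SD criterion), awake whole-cell profiles (baseline firing
5.8 ± 6.2 vs 3.0 ± 1.0 Hz, theta 0.4 ± 0.4 vs 0.2 ± 0.1 mV, 1-s ΔVm
−1.8 ± 2.1 mV, ΔFR +2.2 ± 13.3 Hz, 5-s ΔVm −0.7 ± 0.5 vs −2.2 ± 1.9 mV)
and sniff profiles (novelty response 2.1 ± 1.6 Hz, re-exposure 0.3 ± 1.2
Hz). Reliability vectors at higher concentrations shift toward 4-of-4
(trial-to-trial variability decreases with concentration), which also keeps
the implied responder-pool rates ≤ 1 at the high printed fractions. The
transgenic 1-s evoked-Vm mean is not printed; the profile uses −1.0 ± 1.0
mV and only the 5-s statistic is asserted anywhere.

Because single study-sized simulations carry large sampling error (10
imaging sites with an across-site SD of 26 points have a 8-point SE), the
reproduction script averages each statistic over replicate simulated
studies at the original study size (14, 7, 10 or 9 sites; 27 or 20
cell-odor pairs; 27 mouse-odor pairs), reporting the total problem size
used. Replicate counts were chosen so each estimate's SE is well inside the
spread of the statistic itself; the full run takes a few minutes on one
CPU.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analyses assume —
sparse reliability-structured transients, graded sub-criterion activity,
theta-locked Vm, renewal sniffing — not raw-data realism: there is no
photon shot noise, neuropil contamination, motion artifact (beyond the
registration test's constructed shifts), bursting, or respiration-coupled
response latency structure. Recovery of the printed statistics therefore
validates the pipeline's correctness and calibration on data satisfying its
assumptions; it is not evidence about any particular real recording. Known
limitations: the reliability histogram carries the ~2-point k=1 interaction
bias described above; clipping latent site fractions to [0, 1] biases
means near the boundaries by up to ~1 point (visible for the 94% PG
condition); the peak-ΔF/F distribution is right-shifted relative to the
printed medians because amplitude-reliability coupling inflates reliable
responses; and Bartlett's test on the positive-valued firing-rate
populations detects the printed variance contrast in ~65% of draws at
n = 7 vs 6, not the higher rate normal theory would suggest.
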