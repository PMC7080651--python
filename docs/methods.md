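# Methods

`alphacoupling` studies the within-subject relationship between prestimulus
occipital alpha oscillations and response time (RT) in a flanker task, and
how that relationship differs between healthy older controls (HC) and older
adults with mild cognitive impairment (MCI). Because no public dataset
accompanies this design, the package is simulation-backed: a generator with
analytically controlled coupling stands in for the recording, and every
analysis stage is validated against it.

## The synthetic cohort

**What it emulates.** Epoched EEG around a flanker stimulus: trials ×
channels × samples at 500 Hz, −2000…+1000 ms, 60 trials per congruency
condition, 8 channels including Oz/O1/O2. Each subject carries an alpha
oscillation at a peak frequency drawn uniformly from 9–11 Hz, riding on
independent 1/f background noise per channel, with per-trial metadata
(condition, RT, correctness) and a neuropsychological score table whose
group means and SDs reproduce a community MCI cohort versus matched
controls (MMSE 26.6 vs 28.4, timed tests slower in MCI, etc.).

**The coupling construction.** The scientific quantity of interest is the
Spearman correlation ρ between single-trial prestimulus alpha power and RT.
The generator makes this an input: a latent bivariate normal pair with
Pearson correlation r = 2·sin(πρ/6) — the Gaussian-copula inverse of the
Spearman target — maps through a lognormal quantile to the trial's alpha
amplitude and through a normal quantile to its RT. Spearman correlation is
invariant under increasing maps, and squaring a positive amplitude is
increasing, so Spearman(power, RT) = ρ exactly in population. RTs below
150 ms are rejected and the whole pair redrawn (clipping would pile ties at
the floor and bias ranks). Copula fidelity is tested to ±0.02 at 10,000
trials.

**Defaults as study conditions.** RT means/SDs 498/55 ms (congruent) and
538/58 ms (incongruent); error rates 6/7 % (HC) and 5/10 % (MCI,
congruent/incongruent); coupling +0.10 in HC and −0.03 in MCI. Parameters
without a stated counterpart were fixed once at values a practitioner would
call realistic: per-trial amplitude lognormal(μ=−0.15, σ=0.40) in µV, a
per-subject lognormal scale factor (σ=0.30) for between-subject power
spread, 1/f exponent 1.0, and background-noise RMS 2.0 µV per channel.
At these defaults the measurement chain attenuates the generative HC
coupling of +0.10 to a measured Fisher z near +0.04, with the MCI group
near −0.02 — the regime the package is meant to emulate. Channel count is
8 rather than a full montage: the region-of-interest statistic uses only
the occipital three, and non-occipital channels exist to make average
re-referencing non-degenerate (they carry the alpha at 0.3 gain).

**What the generator does not model:** volume conduction or any spatial
head model (noise is independent across channels), evoked-potential
morphology after stimulus onset, eye/muscle artifacts (an external boolean
artifact mask is honored during exclusion instead), and non-stationary
alpha bursts — the oscillation amplitude is constant within a trial.
Passing tests therefore certify the analysis chain and its statistics, not
robustness to artifacts or to within-trial alpha dynamics.

## Preprocessing

Average re-reference, then a zero-phase FIR band-pass of 1–30 Hz, then
baseline correction by subtracting the −2000…0 ms time-domain mean per
trial and channel. The band-pass is a windowed-sinc (Hamming) design built
from a cascaded high-pass and low-pass kernel with transition widths
min(max(0.25·lo, 2 Hz), lo) at the low edge and 0.25·hi at the high edge
(−6 dB at the band edges; ≈1651 + 221 taps at 500 Hz). Epochs are
reflect-padded by half the kernel before convolution, so the output is the
same length with no phase shift. Measured response: |H| within 5 % at
10 Hz, ≥50 dB down at DC and at 45 Hz.

Trial exclusion: trials with no response within 2000 ms of stimulus onset
(the post-stimulus fixation duration) are invalid; per condition, the RT
mean and SD over valid trials are computed in a single pass and trials
strictly outside the closed interval mean ± 2·SD are outliers; incorrect
and artifact-masked trials are additionally excluded from EEG analyses.
Error rate is computed over all responded trials; RT summaries over
included trials only. The outlier interval is closed (a trial exactly at
the bound survives; with SD = 0 the bounds degenerate to the mean and
nothing is excluded), the statistics are per participant and per condition,
and the rule is applied once, not iterated.

## Time–frequency analysis

Single-trial spectrograms use a windowed Fourier transform: a fixed 300-ms
(150-sample) Hanning taper centered on each output time (2-ms steps),
zero-padded to 500 samples, so frequency bins sit on an exact 1-Hz grid
(fs / pad_to); the spectrogram is P(t, f) = |F(t, f)|² in µV².
Conventions, chosen once and tested: symmetric Hanning; the 150-sample
window is centered at 0-based index 75, with symmetric zero-padding at
epoch edges (the ROI never reaches an edge, so this cannot affect
results); zeros are appended after the taper — padding placement changes
only DFT phase, never |F|²; no taper-gain compensation is applied, so
absolute power is convention-dependent and every downstream statistic is
scale-invariant within subject. Prestimulus alpha power is the mean of P
over −1000…−300 ms × 7–14 Hz (inclusive bounds: 351 × 8 grid points),
computed per channel and averaged over Oz/O1/O2 (equivalent to pooling,
since the grids are identical). The implementation is verified against a
brute-force O(N²) DFT to 1e−10 relative error and conserves energy under
padding (Parseval).

## Coupling statistics

Per condition, included trials are median-split on RT: strictly below the
median is fast, at or above it is slow ("faster than the median" read
strictly, so ties go to slow). The median is per condition by default
because the downstream ANOVA crosses speed with congruency; a global-median
variant is available as a config switch. The per-condition Spearman
correlation between alpha power and RT (average ranks for ties, both speed
bins pooled) is mapped through Fisher's z = 0.5·ln((1+r)/(1−r)). The
transform's variance theory is Pearson-specific; it is applied to Spearman
coefficients deliberately, for fidelity to the analysis being emulated.
|r| ≥ 1 raises rather than clamping silently; an explicit clamp at
±(1−1e−7) is available for degenerate simulated subjects.

**Range restriction and recovery.** The ±2 SD RT trim is a two-sided
truncation of the RT distribution, and truncation attenuates rank
correlations: trial-level Monte-Carlo (6000 reps, 60 trials) puts the
asymptotic bias of the mean recovered z at −0.019 for ρ = 0.2 and −0.041
for ρ = 0.4. Parameter-recovery experiments therefore run with the trim
disabled (`outlier_sd=None`) so they estimate the generative coupling
itself; the attenuation under the full protocol is asserted separately as
a directional property (recovered z strictly between 0 and the target).

## Group inference

The mixed-design ANOVA is a classical balanced split-plot: one
between-subjects factor, any number of fully crossed within-subject
factors, subjects random. Sums of squares come from orthogonal projections
of the (group × subject × within-cells) tensor — centering operators on
the factors in an effect, averaging on the rest — with the standard error
strata (between effects over subjects-within-groups; each within effect
and its group interaction over its own effect × subject stratum). The
implementation requires equal group sizes; the balanced decomposition is
exact there, every simulated cohort is balanced, and unequal-n mixed
ANOVA raises questions (weighted vs unweighted means) this package has no
need to answer. Greenhouse–Geisser ε is the Box epsilon of the pooled
within-group covariance of orthonormal effect contrasts, clipped to
[1/df, 1]; any 2-level factor has df = 1 and hence ε = 1, making the
corrected p equal the uncorrected one — implemented generally and verified
on 3-level designs against pingouin. Effect size is partial η² =
SS_effect/(SS_effect + SS_error).

Post-hoc simple effects within an interaction form one Bonferroni family
per interaction (p·m capped at 1). Between-group tests use the pooled-
variance two-sample t with Cohen's d on the pooled SD (d = t·√(2/n) at
equal n, the convention consistent with the emulated effect sizes).
Feature–neuropsychology associations are Pearson correlations computed per
group, never pooled across groups — pooling would confound group mean
differences with within-group association.

Calibration: under a null with coupling 0 in both groups, the group main
effect on z rejects at α = 0.05 in 5 % ± 2 % of 500 runs (verified with
scaled-down cohorts of 14 subjects per group and 30 trials per condition,
via the trial-level shortcut `simulate_z_table`, which reuses the copula
and RT distributions but skips EEG synthesis — measurement noise can
attenuate coupling but cannot create a group difference under the null).

## The SVM protocol

Fifteen per-subject features in a fixed canonical order: six behavioral
(ER and mean RT per condition, flanker effects on ER and RT) and nine
electrophysiological (alpha power per speed × congruency cell, their grand
mean — the mean of the four cell means —, the slow − fast differences per
condition, and z per condition). Regression uses only the nine
electrophysiological features.

The protocol around scikit-learn's RBF SVM: min–max rescaling to [0, 1]
fitted on outer-training rows only (out-of-range test values extrapolate,
unclipped); exhaustive enumeration of feature subsets capped by
`max_subset_size` (full enumeration of 2¹⁵−1 subsets is available but not
a default); grid search over C ∈ {2⁻⁵…2¹⁵}, g ∈ {2⁻¹⁵…2³} in octave
steps; all selection inside an inner stratified k-fold within each outer
training fold of a stratified outer k-fold (plain k-fold for regression);
the inner winner — ties broken toward smaller subsets, then enumeration
order, then smaller C, then smaller g — refit on the outer training set
and scored on the held-out fold; 100 repetitions (fewer in tests) with
2.5/97.5-percentile confidence intervals over repetition means. For tiny
cohorts the inner fold count is capped by the smallest class in the outer
training set. Classification reports pooled-fold accuracy, AUC,
sensitivity, specificity, PPV and NPV (undefined ratios are NaN, never 0);
regression reports MSE on the rescaled target and two R² conventions —
squared Pearson correlation of pooled out-of-fold predictions versus
observed (primary; always in [0, 1]) and 1 − SSE/SST (can be negative
under cross-validation). A deliberate leakage variant (rescaling fitted on
all rows before splitting) sits behind `leak_rescale=True`; its measured
effect on null accuracy is below Monte-Carlo resolution at desk scale
(+0.014 ± 0.015 over 12 paired seeds), so the tests demonstrate the
mechanism (the leaky scaler provably uses held-out rows) and the chance
level of both variants rather than asserting an inflation ordering.

## Problem sizes in the test suite

The acceptance-style studies are sized to run on a laptop: parameter
recovery uses three 20-subject cohorts per coupling level (120 trials per
subject, background noise 0.05 µV); the directional group contrast uses
20 seeded cohorts of 28 + 28 subjects at the full study defaults; ANOVA
calibration uses 500 trial-level cohorts; the nested-CV checks use 56
subjects, 10 repetitions, singleton subsets and a 3 × 3 grid. These sizes
keep Monte-Carlo error well inside each asserted band.

## Known limitations

Unequal group sizes are rejected by the ANOVA (by design, above). The
generator's artifact-free data means the artifact mask path is exercised
only synthetically. The WFT absolute power scale is convention-dependent;
comparisons across packages require matching taper-gain conventions.
Exhaustive subset enumeration over all 15 features with the full grid and
100 repetitions is computationally expensive (~10⁹ SVM fits) and is not
exercised end-to-end; the protocol is validated at reduced enumeration
sizes where its behavior (selection consistency, chance-level nulls,
separable-case ceiling) is checkable.
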