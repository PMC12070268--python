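# Methods

This note documents the models, statistics and numerical choices behind
`eegbind`, what the synthetic-data generators emulate, and what the
passing test-suite does and does not establish about real data.

## Study design being modelled

A Go/Nogo task with two feature-overlap conditions. Each overlap
condition contains 196 Go and 84 Nogo trials (70:30), distributed over
seven equally sized blocks in pseudorandom order with the Go:Nogo
proportion preserved per block; stimuli last 450 ms, trials end at a
response or 1700 ms, inter-trial intervals are uniform in 700–1100 ms.
Two groups (GTS patients, NT controls; 30 per group in the modelled
study) are compared on Go hit rates, Go reaction times and Nogo false
alarm rates, and on oscillatory power differences between the two Nogo
conditions ("overlap effect" = overlapping − non-overlapping).

## Synthetic data

**Behaviour.** Each group × overlap cell is specified by a mean and SD
for the three outcomes. Rates are drawn from a Beta distribution
matched to the cell's moments (ν = μ(1−μ)/σ² − 1), which respects the
[0, 1] support even at the near-floor false-alarm cells (0.01–0.02);
when moment matching is infeasible (σ² ≥ μ(1−μ)) a clipped normal is
used. Reaction times are Gaussian with a per-subject speed offset
(SD 25 ms) shared across conditions, so the paired overlap contrast has
realistic power. The default cells are the modelled study's reported
means/SDs, giving a built-in group × overlap false-alarm interaction.

**EEG.** Epochs are 1/f background noise (power ∝ 1/f, RMS 10 µV per
channel) plus band-limited bursts: Gaussian-windowed sinusoids with an
independent uniform phase per trial, i.e. non-phase-locked activity
that appears in total power but not in the evoked average. Burst
amplitude is (group, condition)-specific and multiplied by a
per-subject gain (1 + N(0, 0.15), shared across conditions). The
default effect spec mirrors the reported direction of effects: a
midfrontal theta increase (channels Cz, FCz, FC1, FC2, CP1, CP2, F2,
FC4) and broad alpha/beta decreases in the overlapping Nogo condition,
with a stronger theta and weaker alpha modulation in the GTS group and
no beta modulation in GTS. The default theta amplitudes (3.0 µV
non-overlapping vs 5.0/5.6 µV overlapping) were calibrated once, with a
100-subject run, to put the per-channel paired effect size near
d ≈ 1.4–1.5 — the planted-effect regime the power checks assume — and
then frozen. Setting every amplitude to zero (`EffectSpec.null()`)
makes the condition labels exchangeable by construction; this is the
null generator used for error-calibration studies.

**Sensor array.** A deterministic montage on the unit head sphere: the
eight named 10-10 electrodes at canonical positions plus a Fibonacci
lattice filling the cap to a polar angle of 115°. The named electrodes
are mutually adjacent under the default neighbour graph so that seeded
midfrontal clusters are connected.

**Source space.** A regular grid (default 5 mm; tests use 10 mm)
inside a sphere of 72 mm radius, with free-orientation leadfields from
the current-dipole potential in an unbounded homogeneous conductor
(φ = q·(r−r₀)/4πσ|r−r₀|³), average-referenced. This toy forward model
preserves the geometry-dependent mixing that beamforming must undo but
is not a boundary-element head model; with sensors only on the upper
cap it produces the far-field "ghost" artefacts typical of simplified
forward models, which the localisation tests account for. The atlas is
a geometric parcellation (octants × two depth shells) with two reserved
labels — "non-labelled" (deep core) and "cerebellar" (inferior
posterior) — exercising the masking logic; it carries no anatomical
meaning.

**What the generators do not model:** eye blinks, muscle and cardiac
artifacts, electrode drift, volume-conducted correlated noise,
phase-locked evoked components, realistic anatomy or channel-specific
noise profiles. Passing tests therefore establish the correctness and
calibration of the *statistics* under the stated generative
assumptions, not robustness to real-world artifact structure.

## Preprocessing

Fixed order: resample → bandpass+notch → average reference → artifact
rejection → interpolation → baseline. Filters are Butterworth designs
applied forward–backward (zero phase): the 0.5–40 Hz bandpass has 8
poles (4-section design; the zero-phase pass squares the magnitude
response) and the notch is a 2nd-order 48–52 Hz band-stop. The
amplitude criterion (±200 µV) and the flatline criterion (peak-to-peak
< 0.5 µV over any full 100 ms window, evaluated per channel with
sliding min/max filters) each reject the whole epoch when any channel
violates them; "activity" is read as peak-to-peak amplitude.
Interpolation uses Perrin-style spherical splines (m = 4, 20 Legendre
terms, ridge 1e-5) with the constant-term constraint. ICA and manual
inspection are deliberately absent; the rejection log says so.

## Time–frequency analysis

Complex Morlet wavelets with 7 cycles at every frequency (σ_t =
n_cycles/2πf, truncated at ±3σ_t), normalised to unit discrete energy
so that white noise of variance s² has expected power s² at every
frequency — the property the flat-spectrum test checks. Trials are
zero-padded to the ceiling of the trial length in seconds before the
FFT convolution. Power is averaged across trials (total power), then
across band frequencies (θ 4–7, α 8–12, β 15–30 Hz) and the 0–1 s
post-stimulus analysis window. Raw power enters statistics: no
baseline normalisation, no log transform. Computation runs in the
input's precision (float32 supported) with float64 accumulation of the
power average; agreement with an independent wavelet implementation
(MNE) is asserted in the tests up to the global normalisation
convention.

## Cluster-based permutation tests

Per-node classical t statistics (paired or pooled-variance two-sample;
zero-variance contrasts are capped at ±1e6 so degenerate synthetic
input stays deterministic). The cluster-forming threshold defaults to
the two-sided critical t at α = 0.05 with the design's df.
Suprathreshold nodes of equal sign are grouped into connected
components of the adjacency graph; sensor graphs use a distance
threshold auto-selected so the median neighbour count reaches ~7
(logged), voxel grids use 26-connectivity. The "minimum two
neighbouring channels" rule is implemented as a single-pass pruning:
a node enters clustering only if at least two of its neighbours are
suprathreshold with the same sign.

The Monte Carlo null records, per randomisation (condition sign flips
within subject, or group relabelling preserving sizes), the maximal
|T_sum| over clusters formed by the identical procedure. Each observed
cluster gets p = (#{null ≥ |T_sum|} + 1)/(R + 1), bounded below by
1/(R+1); significance at α against the maximal-|T_sum| null is a
two-tailed, family-wise-corrected decision across clusters of both
signs.

**Calibration.** Without the neighbour-pruning rule the test is
calibrated: on effect-free synthetic EEG (12 subjects, 32 channels,
R = 500) the family-wise rejection rate sits at the nominal 5 % (11/200
replicate studies in the shipped suite; 0.043–0.055 across larger
Gaussian-map runs). With the pruning rule the test becomes
conservative at this scale (~1 %): most randomisations then produce no
cluster at all, so the attainable rejection probability drops below α.
This is an inherent property of the rule — which exists to suppress
singleton sensor clusters, not to calibrate error — and the acceptance
suite therefore checks exact calibration for the unpruned test and
validity (never anti-conservative) for the pruned variant. A cluster-sum
statistic also favours spatially broad effects; for deliberately focal
planted sources the integration tests raise the cluster-forming
threshold (cluster_alpha = 0.01), which is the standard lever.

## DICS beamforming

Cross-spectral densities use a single Hanning taper per trial on the
demeaned 0–1 s window, averaged over trials and the band's Fourier
bins. The common filter is built from the trial-weighted average CSD
of both conditions: W_v = (LᵥᵀC⁻¹Lᵥ)⁺ LᵥᵀC⁻¹ with C = Re(CSD) +
λ·mean(diag)·I and λ = 0.05 ("5 % lambda"). The rank parameter keeps
the strongest leadfield orientation components (3 = full free
orientation, the standard EEG setting; the "3 %" of the modelled
study's settings is read as rank 3 with the percent sign a
typographical artifact). Source power is the dominant eigenvalue of
the 3×3 source CSD W C Wᴴ (scalar beamformer via the dominant
orientation). Two bias-free readouts exist: the neural activity index
(`normalize="noise"`, power divided by projected white-noise power),
which removes the depth bias of raw unit-gain power and is used for
single-condition localisation; and the relative condition contrast
(P_over − P_non)/(P_over + P_non) ∈ [−1, 1], the pipeline's statistic,
in which the bias cancels. In the λ→∞ limit the filter tends to the
leadfield pseudoinverse (LᵀL)⁻¹Lᵀ — the spatial matched filter up to
the column-normalisation (LᵀL)⁻¹; the tests assert this exact limit.

## Source-peak localisation

Fixed order: reserved atlas labels are masked out first, then the map
is thresholded to the top q % (default 1 %; exactly ⌈qN/100⌉ voxels,
ties broken by voxel index, ranking toward the sign of the cluster
under study), then DBSCAN clusters the retained coordinates with
eps = 1.5 grid steps and min 5 points (the voxel itself counts),
discarding noise; clusters are labelled with per-parcel histograms and
a dominant label. The order matters — an extreme value inside a
reserved region must never survive — and a test asserts it.

## Leave-one-out cluster robustness

The dependent-design cluster test is rerun once per left-out subject
(iteration seed = base seed + index). Each iteration records the
largest significant cluster of the expected sign (T_sum, number of
significant voxels, relative T_sum = T_sum/n; a sum-over-clusters
aggregate is available). Group comparisons use Mann–Whitney U with
tie-corrected normal-approximation Z and no continuity correction,
either dropping iterations without clusters ("missing") or scoring all
three statistics as zero ("zero-penalty" — never fewer usable
observations than missing handling). The effect size convention is
r = Z/√n with n the per-group iteration count (n = 30 in the modelled
study), which is the convention the reported values follow; a
total-sample alternative is exposed. Leave-one-out samples overlap
almost entirely, so treating iterations as independent observations
overstates evidence; the procedure is reproduced as published and this
caveat is deliberate, not corrected.

## Behavioural statistics

The 2×2 "mixed-effects ANOVA" is the classical split-plot ANOVA
(between: group; within: overlap), computed via pingouin and verified
against a from-first-principles sums-of-squares oracle; with one
numerator df, η²p = F/(F + df2). Post hoc tests are gated by
Shapiro–Wilk at α = 0.05 per sample (per group × condition for
condition comparisons, per group's overlap effect for effect
comparisons; constant samples are flagged degenerate and routed
nonparametric): parametric ⇒ paired/Welch t (Welch–Satterthwaite df,
pooled-SD Cohen's d — equal to t√(1/n₁+1/n₂) at equal n);
nonparametric ⇒ Wilcoxon signed-rank (zeros dropped) or Mann–Whitney U,
both with tie-corrected normal approximation and no continuity
correction. The normal approximation at n ≤ 7 deviates from exhaustive
enumeration by up to ~0.16 in mid-range p (the exact null has atoms of
1/32–1/64) but stays within ~0.06 where p < 0.2; the tests state these
bounds explicitly. Pearson χ² (df = 1, no continuity correction)
handles the 2×2 sex table.

The sensitivity power analysis solves, by bisection on the noncentral-F
survival function, for the smallest Cohen's f whose interaction power
reaches the target, with df1 = (g−1)(m−1), df2 = (N−g)(m−1)ε and
noncentrality λ = f²Nm/(1−ρ); for N = 60, m = g = 2, α = 0.05, power
0.95, ρ = 0.5, ε = 1 this gives f = 0.237. A direct split-plot
simulation (one cell offset by 4f, so the interaction deviations are
±f) reproduces the target power within binomial error, which pins down
the λ convention.

Leave-one-out correlation series are built with `loo_means` (mean with
subject i excluded); because such series are strongly non-normal,
association is measured with Spearman's ρ and flagged at the
Bonferroni-corrected α = 0.001 (48 planned comparisons in the modelled
study; the correlation set is reproduced structurally since the exact
list lives in unpublished supplementary material).

## Problem sizes and precision

Simulation-heavy suites run at desk scale, chosen as a realistic
minimal study the statistics remain meaningful at: 12 subjects/group,
40 trials/condition, 32 channels at 128 Hz with −0.75..1.25 s epochs
(all bands sit far below Nyquist), float32 signal arrays with float64
statistics, 200 replicate studies for error calibration (exact binomial
95 % CI at the nominal α), 50 for planted-effect power, 20 seeds for
dipole recovery, R = 500–2000 randomisations. The defaults of the
generators themselves (256 Hz, −2..2 s epochs, 61 channels available)
match the modelled recording setup.

## Known limitations

No ICA or manual artifact pass; toy forward model and atlas (import
hooks exist for real BrainVision recordings via the optional `mne`
extra); LOO dependence not corrected (as published); no TFCE or
cluster-mass alternatives; no baseline-normalised (dB) power; the
exact supplementary correlation list and the clinical instruments are
carried only as metadata concepts, not implemented scales.
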