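# Methods

## Montage and coordinates

The 59-channel montage is an anterior-to-posterior ordered 10-10 subset with
four fixed anchors: code 1 = Fpz, 43 = Pz, 50 = POz, 57 = Oz, 59 = O2.
Codes 43–59 (Pz, P1–P6, POz, PO3–PO8, Oz, O1, O2) form the posterior "V1"
region used for all region comparisons; the remaining 42 channels are
"other".  Positions are computed, not digitized: head coordinates are
meters with origin at the head center (+x right, +y anterior, +z superior);
midline electrodes lie on the sagittal nasion–vertex–inion great circle at
10% arc steps, the outermost lateral electrodes on the horizontal circle
through the ears, and intermediate electrodes on great-circle arcs between
the two at even fractions, all on a sphere of radius 0.092 m.  This is a
deliberately idealized spherical scalp — no MRI coregistration and no
per-subject digitization; anatomical (MNI) realism is out of scope.

## Synthetic study

The generator reproduces the study design: 20 subjects (configurable),
three color-pair teams (RG, RB, GB), 3 trials per team, 70 one-second
epochs per trial (exactly 35 + 35 per color, randomly interleaved per
trial), 59 channels at 1000 Hz.  Derived bookkeeping: 210 epochs and
210,000 ms of stimulation per team, 630,000 ms per subject.

**Source.** All stimulus responses are driven by one fixed ground-truth
dipole at r0 = (0, −57.5, 37.5) mm, oriented in the sagittal plane at 160°
from +z (i.e. mostly −z with a −y tilt).  The geometry was chosen by a
forward-model search over sagittal candidates subject to two constraints
the synthetic study must embody: (a) the noise-free scalp pattern ranks the
midline posterior channels Pz/POz/Oz strictly highest (amplitudes
1.00/0.95/0.93 of the maximum, with the fourth-ranked channel at 0.67), and
(b) the dipole's orientation line passes 5.8 mm from the center of the
calcarine target ball (center (0, −65, 0) mm, radius 15 mm), so the line
test has a real margin.  Deeper or differently tilted single dipoles either
promote the lateral neighbors P1/P2/PO3/PO4 into the top three or miss the
calcarine ball.

**ERP templates.** Each color contributes a Gaussian-windowed biphasic
bump: positive main lobe (width 25 ms) at the color's first-peak latency —
red 180 ms, green 185 ms, blue 205 ms — preceded 60 ms earlier by a
negative lobe at 30% amplitude.  Peak dipole moments are 60 nA·m (red),
72 nA·m (green), 48 nA·m (blue): a 20% amplitude contrast between pair
members in addition to the latency offset, which is what makes the pairs
linearly decodable from single-channel raw samples.  The overall moment
scale was calibrated once so the best posterior channels decode at roughly
70–85% — the regime the analysis targets — and is not otherwise tuned.

**Noise.** Per channel: 1/f ("pink") background at 4 µV SD (spectral
shaping of seeded white noise), white sensor noise at 1.5 µV SD, a common
50 Hz sinusoid at 5 µV (exercises the notch), and eye blinks — 400 ms
half-sine bursts of 120 µV on the six most anterior channels at 2/min
(exercises artifact rejection).  Noise is spatially independent across
channels; real EEG background has strong spatial correlation, so passing
tests here says nothing about spatially correlated interference, volume-
conducted artifacts, or per-subject anatomical variability.  Rest periods
between trials are plain inter-event gaps; they are not materialized as
epochs.

## Preprocessing

50 Hz IIR notch (quality 30), windowed-sinc Hamming FIR low-pass with the
stopband starting at 40 Hz (passband edge 30 Hz), both applied
forward-backward for zero phase; polyphase 5:1 decimation to 200 Hz with
event onsets remapped by `round(onset/5)`; epochs `[−200, +1000)` ms
(half-open in samples: 240 samples at 200 Hz, onset at index 40) with the
baseline mean removed per epoch and channel; amplitude rejection at
±100 µV.  The split plan is repeated stratified holdout: test size
`round(0.2 n)` with per-class largest-remainder allocation, 30 repeats —
with 210 epochs this reproduces the 168/42 per-repeat and 5040/1260
cumulative totals exactly, which k-fold cross-validation cannot.

## Decoding

Features are the raw 0–500 ms post-onset samples of one channel
(100 columns at 200 Hz).  Classifiers: a linear SVM (C = 1, per-column
z-scoring fit on the training fold only) and a small conv1d feedforward
net (8 filters, kernel 7, hidden width 32, 50 full-batch Adam passes at
learning rate 0.01, seeded initialization) implemented in numpy with
manual gradients.  A channel's accuracy is the mean over the split plan's
repeats.  Region comparison uses the two-sided Wilcoxon rank-sum on
posterior vs other accuracy values.  The ROC treats every subject × channel
accuracy as one point, positives = codes 50–59 (POz–O2): AUC by the
midrank statistic, standard error by Hanley–McNeil, p by the normal
approximation against 0.5, Wald 95% CI clipped to [0, 1].

## ERP / VEP analysis

First-peak latency operates on the squared amplitude of a color-averaged
waveform: the first local maximum inside the 0–500 ms search window that
reaches (a) 3× the baseline-window SD of the squared amplitude and (b) 20%
of the in-window maximum.  Criterion (b) exists because after averaging
105 epochs the baseline SD becomes so small that criterion (a) alone
accepts the template's own 9%-power pre-lobe (and even residual noise
ripples) as the "first peak"; the relative floor restricts detection to
actual components.  Both thresholds are parameters.  Quartiles use linear
interpolation between order statistics; outputs name the 75th/25th
percentiles upper/lower quartile (box plots elsewhere sometimes label
these Q1/Q3).  Time-frequency is a short-time FFT (250 ms Hann, 80%
overlap, 4× zero padding) truncated at 30 Hz.  The VEP power map is the
mean 0–30 Hz periodogram power of the color-averaged ERP in 0–400 ms,
averaged over the pair's colors; the accuracy–power spatial correlation is
Pearson across the 59 channels (Spearman available).

## Source localization

Two constant conventions coexist deliberately.  The field/moment algebra
(`dipole_field`, `moment_from_field`) uses the electrostatic form with ε0,
exactly as the transfer-matrix equations are written; scalp potentials use
the volume-conductor form with conductivity σ = 0.33 S/m.  The choice only
rescales recovered moments, never positions.  The printed moment-inversion
equation omits the scalar distance factor; it is restored here as
`P0 = 4π ε0 |r−r0|³ M(ê)⁻¹ E`, the exact inverse of the forward field, with
`M⁻¹ = ½êê^T − (I − êê^T)` in closed form.

The head model is an infinite homogeneous medium evaluated on the spherical
montage with average reference — the major simplification relative to a
BEM/FEM "real head model"; the forward interface is a single function so a
multi-shell model could be substituted.

**Single-dipole fit (DLM).**  Weighted least squares over position: coarse
search on the 1 cm interior grid (|r| ≤ 0.85 R), Nelder-Mead refinement to
0.1 mm, with the moment solved in closed form at every candidate position.
Channel weights come from decoding accuracy, `w_c = max(acc_c − 0.5, 0)`
normalized; an all-chance map falls back to uniform weights with a flag.
The observation vector is a configurable choice (never pinned down by the
analysis this mirrors): by default the grand-average ERP value per channel
at the group median first-peak latency.

**eLORETA.**  Standard fixed-point iteration on 3×3 per-source weight
blocks, `W_i = [A_i^T (A W⁻¹ A^T + α H)⁺ A_i]^{1/2}` with H the
average-reference centering matrix and α scaled by the mean sensor variance
of the weighted gain; iteration stops at relative weight change < 1e-6
(ConvergenceError after 500 steps).  The defining property — zero
localization error for a noiseless point source at a grid node — is what
the tests verify; α = 0 uses the pseudo-inverse and is exact for that case.

**Line test.**  The fitted dipole's orientation line `r0 + t·p̂` (t ∈ ℝ,
both directions) hits the calcarine ball iff its minimum distance to the
center is ≤ 15 mm.

## Numerical choices and degenerate inputs

Filters raise on cutoffs at/above Nyquist; resampling accepts only the
1000 → 200 Hz path the design uses.  Rejection of every epoch raises
DataQualityError rather than returning an empty set.  Zero observation
vectors raise DegenerateInputError (fit) or return exact zero (eLORETA).
Rank computations use midranks; AUC ties count ½.  The EDF writer is a
minimal 16-bit implementation (1 s records, true sample count kept in the
reserved header field, values exact to one quantization step of the
per-channel range); tests cross-check written files against an independent
EDF reader.

## Desk-scale problem sizes

The default study (20 subjects × 3 teams × 59 channels × 30 repeats) is
what `PipelineConfig` encodes.  The test suite and the acceptance script
run the same code at sizes chosen for a single-CPU desk run: the
20-subject decoding topography uses 3 split repeats per channel; the
group top-3 check uses 10 replications of 3-subject maps at 15 repeats;
the calcarine line test uses 10 single-subject replications at 3 repeats;
inverse recovery uses 50 random noise-free dipoles and 20 eLORETA node
sources.  These sizes are recorded next to the numbers they produce.

## Known limitations

Single fixed dipole (no multi-dipole fitting), spherical homogeneous head,
spatially independent noise, no ICA or bad-channel handling, no SSVEP
flicker modeling, and no claim that synthetic decoding accuracies transfer
to recorded EEG — the synthetic study validates the machinery and its
internal consistency, not human data.
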