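# Methods

This note records the models implemented in neurofuse, the conventions and
defaults they use, what the synthetic-data generators do and do not
emulate, and the design choices made where more than one reasonable
definition exists.

## Coordinate and unit conventions

Voxel and time indices are 0-based; event times are seconds from recording
start; all intervals (bad blocks, sliding windows) are half-open
[start, end).  EEG signals are microvolts; motion translations are mm and
rotations radians, in the column order [X, Y, Z, pitch, yaw, roll] of
realignment "rp" text files (strictly six numeric columns, no header).
The TR comes from the NIfTI header (pixdim[4]) unless the caller overrides
it; the override always wins because converted headers are unreliable, and
Analyze images — which have no trustworthy TR field — require it.

## Denoising

Nuisance removal is voxelwise ordinary least squares against a confound
matrix assembled from: a motion block (6 = [R]; 12 = [R, ΔR] with ΔR the
backward difference, first row 0; 24 = [R, R², R_{t−1}, R²_{t−1}];
36 adds the lag-2 pair), tissue-mask mean series, an optional global
signal (off by default — its use is contested), a centered linear trend,
and DCT drift columns.  Lagged motion blocks are zero-padded at the start;
the alternative of replicating the first row was rejected because
zero-padding makes the shift oracle exact.  Residuals keep the voxel's
temporal mean so later grand-mean scaling stays meaningful.  Rank-deficient
designs are fit by pseudoinverse with a warning naming dependent columns.

The ideal bandpass zeroes DFT coefficients outside the band.  Band
membership is half-open (low, high]: an edge frequency belongs to the band
below it, so disjoint bands covering (0, Nyquist] reconstruct the demeaned
signal exactly, and the filter is idempotent.  DC is kept only when the low
edge is exactly 0 (a pure low-pass).  The volume-level wrapper re-adds the
voxel means by default.  The default resting-state order is nuisance
regression, then bandpass; both orders are supported since the reverse is
also common practice.

The DCT drift basis contains K = floor(2·T·TR/cutoff) − 1 unit-normalized
cosine columns (constant excluded), cutoff 128 s by default; short runs get
an empty basis.  Grand-mean scaling multiplies the volume by 100/(in-mask
grand mean), so fitted effects are percent of the global mean.

## FCD family

Correlations are Pearson, over the whole time axis (or a window).  gFCD
counts strict suprathreshold correlations (r > θ) to all other in-mask
voxels; self-connections never count.  lFCD grows a cluster from the seed:
a candidate joins if it is spatially adjacent (6/18/26-neighborhood;
default 26, the full 27-voxel cube) to any current member *and* its
correlation **with the seed** exceeds θ.  Correlating candidates against
the seed, not against the evolving cluster, is the classical growing rule
and makes lFCD equal to the seed's connected component within the
thresholded correlation field — which is exactly how the independent test
oracle computes it (full correlation matrix + scipy flood fill).  lrFCD is
gFCD − lFCD by construction.  Zero-variance voxels score 0, are flagged,
and are excluded from the normalization denominator; normalized maps
divide by the in-mask mean (undefined for an identically zero map).
Sliding-window FCD re-runs the static computation on windows starting at
0, step, 2·step, … (count = floor((T − window)/step) + 1); defaults are a
40-TR window and 1-TR step, with a 10-TR minimum window so windowed
correlations keep a usable sample size.

## FOCA

For each voxel, the 27-voxel cube intersected with the mask (at least 9
members required) yields two numbers: temporal consistency t_i = the mean
pairwise Pearson correlation among the member time series, and spatial
consistency s_i = the mean correlation between the member-value patterns
at consecutive time points.  The default combiner is the rectified product
max(0, t_i)·max(0, s_i), which is 1 exactly for a neighborhood of the form
x_v(t) = a_v·f(t) (common waveform, graded amplitudes) and stays in
[0, 1].  The combiner is pluggable; the rectified product is this
package's own choice of a combination that preserves the documented unit
range.  Neighborhoods that are too small or contain a zero-variance
pattern score 0 and are flagged; flagged voxels are excluded from the
normalization mean.

## Dynamic-series indices

For a series v_t (scalars or maps, elementwise): mean; sample SD (ddof 1);
CoV = SD/mean; mean point-by-point change = mean over t ≥ 1 of
|1 − v_t/v_{t−1}|; mean relative ratio = mean of v_t/v_{t−1}.  Ratio
indices are NaN-flagged when any predecessor is 0; the other indices are
still returned.

## EEG conditioning and features

Re-referencing subtracts the per-sample mean of all channels (average) or
of a named channel set; it is idempotent and invariant to common offsets.
Filtering is zero-phase: windowed-sinc FIR applied forward and backward
(order ≈ 3·srate/edge, forced odd), or an FFT brick-wall mask.  ERP
extraction accepts a channel label or an externally computed component
series (e.g. from ICA, which is out of scope here) as a virtual channel;
epochs are baseline-corrected by the mean over [−200, 0] ms by default and
summarized by the mean or the signed extremum of the measurement window.

Band power uses the one-sided DFT convention p_k = 2|Y_k|²/L for interior
bins, with the DC and (even-L) Nyquist bins undoubled so the bins sum to
the segment's total power; a sinusoid of amplitude A at a bin frequency
therefore contributes A²L/2.  Band membership is inclusive of both edges
here (a display/reporting convention); windows overlapping a bad block are
returned as NaN — a flag, never a zero, since zero power is meaningful.
Bad blocks clip features without shifting time, so downstream regressors
keep absolute alignment with the fMRI clock.

## HRF kernels and regressors

Kernels are sampled on [0, 32] s and scaled to peak magnitude 1 (making
regressor scale independent of the sampling step): single-gamma = a gamma
density with unit scale and shape peak+1, so the mode sits exactly at the
requested peak latency — the one free parameter of the multi-peak
analysis; canonical = double-gamma with response delay 6 s, undershoot
delay 16 s, unit dispersions, undershoot ratio 1/6; Glover = the two-gamma
t^a·exp(−(t−ab)/b) form with a = 6 and 12, b = 0.9 s, undershoot fraction
0.35.  Features are painted on a microtime grid of TR/16 (onsets as unit
impulses scaled by value; TR-locked series as per-TR boxcars with missing
values linearly interpolated — never zero-filled), convolved, and sampled
at each volume's first bin (volume start; configurable, since acquisition
reference timing is a site convention).  Designs are ordered
[interest | nuisance | drift | intercept] with one t-contrast per interest
column and an F-contrast over all of them.

## GLM and the multi-HRF variant

Fitting is voxelwise OLS; t = cᵀβ̂ / √(σ̂²·cᵀ(XᵀX)⁻¹c) with
σ̂² = RSS/(T − rank), and F comes from the extra sum of squares between the
full model and the model with the contrast's columns removed.  Drift is
handled as DCT confound columns rather than pre-filtering so the degrees
of freedom stay exact; grand-mean scaling runs first (toggleable).
Out-of-mask voxels carry NaN, never 0 — 0 is a valid statistic.  The
multi-HRF analysis builds one single-gamma regressor per peak latency
(default 3/5/7/9 s), fits each with shared confounds, and reports per-peak
T maps, the voxelwise maximal T with the winning latency, and a joint
F-test of all peak regressors against the confound-only model.  The max-T
map is reported uncorrected for the implicit maximum over fits; the
per-peak maps and joint F are emitted precisely so users can apply their
own correction.

## LMSA

The EEG feature series is locked to the TR grid (onsets become per-TR
counts) and delay-embedded into T×(L+1) columns, lag 0..L TRs; the default
L = 6 (12 s at TR 2 s) covers canonical hemodynamic delays.  Per voxel,
the first canonical pair between this lagged matrix and the neighborhood's
time series (27-voxel cube ∩ mask, ≥ 9 members — the same rule as FOCA) is
computed by QR-whitening and SVD; rank-deficient sides are reduced by
dropping dependent columns (their weights report as 0).  Significance is
Bartlett's chi-square likelihood-ratio test that all canonical roots
vanish (df = p·q), gating at α = 0.05.  Where significant, the EEG-side
variate v = X·a (sign fixed so Σa ≥ 0, keeping HRF estimates comparable
across voxels) is the regressor of interest in an OLS fit of the voxel's
own series with confounds and intercept; the T of its coefficient is
mapped, and the lag weights a — indexed by lag·TR seconds and
peak-normalized — are the voxel's data-driven HRF estimate.  The EEG-side
variate is the default because the second LMSA step estimates the voxel's
activity *from* the EEG feature space; the fMRI-side variate is available
behind a flag.  With lag 0 and a single-voxel neighborhood the procedure
reduces exactly to the voxelwise GLM t, which the tests verify to 1e−8.

## Synthetic data

`simulate_bold` draws AR(1) temporal noise (coefficient 0.3, roughly the
lag-1 autocorrelation of resting BOLD at TR 2 s; unit marginal SD),
optionally embeds hub clusters sharing a latent series (mixing weight =
target correlation, since corr(√w·z + √(1−w)·e_i, √w·z + √(1−w)·e_j) = w),
adds event-locked activations as onset impulses convolved with a
single-gamma kernel of known peak, and offsets everything by a grand mean
of 1000 so auto-masking and grand-mean scaling behave as on real data.
`simulate_motion` makes smoothed random walks scaled to a peak amplitude;
`simulate_eeg` layers 1/f-shaped background, random-phase band-limited
oscillations and biphasic 250 ms spike templates whose true onsets ride in
the event table as type "GSWD".  All generators run on
numpy.random.default_rng (PCG64), so one seed fixes every output bitwise.

What the generators do **not** emulate: neural-mass or balloon-model
dynamics, draining veins or any spatial hemodynamic structure, MR gradient
or ballistocardiogram artifacts in the EEG, physiological (cardiac or
respiratory) noise, or between-subject variability.  Tests passing on
these simulations therefore validate the *computations* — counting,
filtering, estimation, calibration — under the models' own assumptions,
not robustness to every artifact of real recordings.

## Calibration and validation settings

Statistical calibration (GLM t, joint F, CCA/Bartlett) is checked with
white temporal noise because that is the independence assumption the OLS
and Bartlett references make; the default AR(1) simulations exercise the
same code paths with realistic smoothness.  For the LMSA false-positive
rate, the significant fraction is evaluated on a stride-3 voxel lattice
whose 27-voxel neighborhoods are disjoint, making the per-voxel tests
independent so a binomial reference applies; overlapping neighborhoods
would correlate the decisions and inflate the variance of the observed
fraction without changing its mean.  Recovery studies use: multi-HRF peak
selection — true peak 7 s, SNR 1 (regressor SD equal to noise SD), 50
seeded runs, 4×4×4 grids, T = 140; LMSA HRF recovery — true peak 5 s,
SNR 1, 100 seeded runs, 5×5×5 grids, T = 150, success = estimated-HRF
argmax within one TR of truth.  Problem sizes (6³–8³ grids, 48–150
volumes, 12–21 seeded replicates per property) were chosen as the smallest
scales at which the measured properties are stable; the brute-force FCD
oracle (full correlation matrix + flood fill) is exact at any scale.

## Execution model

All computations are deterministic and single-threaded; the CLI accepts a
worker-count knob for forward compatibility, and results are contractually
independent of it.  Every CLI run writes a provenance JSON (resolved
configuration, package version, SHA-256 of inputs) sufficient to re-run
the analysis bit-identically.

## Known limitations

No slice-timing/realignment/normalization/smoothing (use a standard
preprocessing tool first); no AR(1) prewhitening in the GLM (OLS only, so
t-statistics on strongly autocorrelated data are approximate); no
multiple-comparison correction beyond the emitted per-peak/joint maps; EEG
support covers EDF and BrainVision only, and ICA/artifact removal are out
of scope (component series can be passed in as virtual channels); the
Bartlett gate is asymptotic and runs slightly liberal at short runs; FCD
at very low thresholds on large grids is quadratic in voxel count.
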