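# Methods

## Problem and approach

Serum proton NMR spectra carry three composite inflammation-related
resonances — GlycA and GlycB (N-acetyl methyl protons of circulating
glycoproteins) and SPC (the supramolecular phospholipid composite of
lipoprotein choline headgroups) — that are broad, mutually overlapped, and
ride on lipid/lipoprotein background humps and sharp metabolite multiplets
(notably the β-glucose doublet-of-doublets at 3.21 ppm next to SPC).
Conventional quantitation requires apodization, Fourier transformation,
phasing, baseline correction and peak integration, each a source of operator
variance precisely where the signals overlap.

This package instead works entirely in the time domain. A raw
water-suppressed FID is modelled as a sum of exponentially damped sinusoids

    s(t) = Σ_k a_k e^{iφ_k} e^{(i2πf_k − λ_k) t},

whose frequency-domain counterparts are Lorentzian lines (FWHM = λ/π Hz).
The amplitude a_k at the excitation origin t = 0 is proportional to proton
concentration regardless of phase or baseline, so no spectral processing is
ever applied. Selected ppm windows are isolated by demodulation + low-pass
filtering + decimation; the first stretch of the filtered signal is
discarded and amplitudes are *back-calculated* to t = 0 by fitting on the
absolute time axis. Cohort separation is then assessed on amplitude *ratios*
with O-PLS-DA, cross-validated Q², and label-permutation null distributions.

## Segment extraction

1. **Demodulation.** Multiply by exp(−i2πf_c t) with f_c the window centre,
   using absolute times so the operation commutes with back-calculation.
2. **Low-pass filtering.** Linear-phase windowed-sinc FIR (Kaiser window,
   ≥60 dB stopband). The passband is the window half-width widened by
   `guard_fraction` (default 0.25) so lines at the window edge are not
   attenuated; the transition band is 0.5× the passband (floor 10 Hz).
   Group delay is removed exactly by centred convolution with an odd-length
   kernel, so filtered sample n sits at time n·Δt — an undistorted time
   origin is essential for back-calculation.
3. **Decimation.** "auto" picks the largest power of two keeping passband
   plus transition band below 80% of the decimated Nyquist, so nothing
   above the stopband edge (suppressed ≥60 dB) can alias into the band.
4. **Skipping initial points.** The default skip is the decimated FIR
   half-length (the edge-transient region, where the filter saw zeros)
   **plus** `broad_settle` = 0.05 s. The settling term is the package's
   reading of "ignore the first few points": background humps are ≥60 s⁻¹
   by design, so 0.05 s is ≥3 decay constants and their remnant falls well
   below the fit's noise floor. Without it the remnants are too weak to be
   detected by rank selection yet strong enough to bias GlycB by several
   percent; with it, noiseless biases are <0.1% and SNR-100 median errors
   ≈1%. The skipped duration is recorded in `t_start`.

Broad components wider than the window are deliberately *not* removed here;
whatever survives the skip enters the fit and is classified downstream.

## Damped-sinusoid fitting

* **Initialization — Hankel SVD / matrix pencil.** A Hankel matrix of the
  first `n_hankel` samples (default 1024; `hankel_rows` = 256 rows) is
  rank-truncated by SVD. Model order = number of singular values ≥
  `sv_threshold` (default 0.01) × the largest, capped at `max_order`; on a
  plateau the smaller order wins (parsimony protects quantitation). Signal
  poles follow from the shift invariance of the left singular subspace.
  Growing poles (λ ≤ 0, an overfitting symptom) are clamped to 0.01 s⁻¹ and
  logged.
* **Amplitudes at the origin.** Linear least squares of the samples on the
  damped-exponential basis evaluated at *absolute* times (t_start included),
  so coefficients are t = 0 amplitudes directly. This avoids multiplying
  noisy stored points by e^{λ·t_start}; when λ·t_start > 3 a warning marks
  the amplitude as poorly constrained. A basis condition number above 1e12
  raises an error advising a lower order.
* **Refinement — variable projection.** Nonlinear least squares over
  (f_k, log λ_k) with amplitudes re-solved by projection at each step, using
  the analytic Golub–Pereyra Jacobian. The analytic Jacobian matters twice:
  it is cheaper than finite differences and it lets the optimizer converge
  to the true optimum rather than the ~1e-8 parameter resolution that
  finite-difference noise allows. The refined residual is never accepted if
  worse than the initial one.
* **Scale equivariance.** Input data are normalized to unit RMS before
  fitting and amplitudes rescaled afterwards, making fit(c·x) = c·fit(x) to
  machine precision; amplitude ratios are therefore exactly invariant to
  overall intensity.
* **Pruning.** Components are dropped (and reported in diagnostics, never
  silently) when their amplitude is below `min_amplitude_fraction` (0.005)
  of the in-segment maximum, or when their modelled RMS contribution to the
  observed samples is below `prune_snr` (1.0) × the residual RMS. The second
  rule removes noise-born components — a pure-noise segment fits to zero
  surviving components — while a noiseless fit (residual ≈ 0) prunes
  nothing.

## Target assignment

Each fitted component belongs to at most one named target: its ppm position
must fall in the target's half-open window [lo, hi) *and* its decay in
[min_decay, max_decay]. Components broader than max_decay are background
(lipid/lipoprotein humps); components narrower than min_decay are sharp
metabolite lines. The SPC target uses min_decay = 8 s⁻¹ because a sharp
β-glucose singlet sits near 3.25 ppm inside the SPC window; linewidth is the
only physical property that separates it from the composite SPC resonance.
A target's amplitude sums the *moduli* of its assigned components (robust to
phase scatter between sub-components of a composite resonance); every
requested target gets a row per sample, amplitude 0 with component count 0
when nothing matched. Default windows (ppm): SPC [3.23, 3.30), GlycB
[2.05, 2.10), GlycA [1.99, 2.05), acetate [1.90, 1.94); default segments
[3.15, 3.35) and [1.85, 2.15). Acetate is always extracted as an internal
control. Before any of this, the ppm axis can be recalibrated against the
α-glucose doublet at 5.233 ppm (`reference_axis`).

## Spectrum reconstruction (QC)

For visual inspection and the area oracle, model spectra are evaluated
analytically per component as 2c_k/(λ_k + i2π(f − f_k)); with this
convention the absorptive (real-part) area of a line equals its amplitude,
and the area within ±k FWHM is amplitude × (2/π)·arctan(2k). The data trace
uses the matching discrete transform (first point halved, doubled), and the
residual trace transforms (data − model time signal) so an exact fit leaves
a residual at the numerical noise floor.

## Synthetic serum generator

The generator emulates the targeted-serum scenario with known ground truth:
32,768 complex points over a 10 kHz (20 ppm) window at 500 MHz, carrier at
4.7 ppm (water). Line set: α-glucose doublet at 5.233 ppm; β-glucose
doublet-of-doublets at 3.21 ppm plus sharp peaks at 3.42 and ~3.25 ppm;
acetate singlet at 1.92 ppm; composite SPC (3.26 ppm, 15 s⁻¹), GlycB
(2.07 ppm, 18 s⁻¹), GlycA (2.03 ppm, 20 s⁻¹); broad background humps
(80–120 s⁻¹) under both the SPC and Glyc regions; and a small
dispersive-phase water remnant at the carrier. Sharp lines decay at 3 s⁻¹
(FWHM ≈ 1 Hz). SPC/GlycA/GlycB positions are configurable — the literature
places them variously, and the defaults are chosen to reproduce the
characteristic overlap challenges (SPC against the β-glucose dd; GlycA/GlycB
on broad background). Default noise gives the acetate singlet a time-domain
SNR of ≈100.

Cohorts: two groups (default 20 + 20, pair-matched, mirroring a matched-pair
study design). Between-subject variation is a per-subject (per-pair when
paired) *global* lognormal intensity factor with CV 15% — dilution and
overall-concentration differences, which is exactly the variation amplitude
ratios are designed to cancel — plus independent per-resonance lognormal
variation with CV 5% (`line_cv`) for residual biology. The default case
effect is an inflammation-like pattern {GlycB ×1.5, GlycA ×1.12, SPC ×0.92}:
glycoprotein acetyls rise and the phospholipid composite falls slightly, so
the GlycB/SPC ratio carries the largest effect of the four built-in ratios.
With a single-marker effect GlycB ×1.5 alone, GlycB/SPC and GlycA/GlycB
would have exactly symmetric effect sizes and no ratio ordering would be
identifiable. Ground truth records every line amplitude and ratio exactly.

What the generator does **not** emulate: J-coupling evolution and strong
coupling, non-Lorentzian lineshapes (shimming imperfections), chemical-shift
drift between samples, baseline distortions from imperfect water
suppression beyond the single dispersive line, and pH/ionic-strength shift
variation. Passing tests therefore demonstrate correctness of the
*algorithms* under the stated signal model, not performance on real serum.

## Chemometrics

Features are amplitude ratios (built-ins: GlycB/SPC, GlycA/GlycB, SPC/GlycA,
SPC/(GlycA+GlycB)); samples with a zero denominator are dropped with a
warning. Columns are mean-centered and scaled to unit variance (univariate
scaling). O-PLS-DA removes `n_ortho` y-orthogonal score/loading pairs before
a single predictive PLS component; because each orthogonal weight is
orthogonal to X'y, orthogonal scores have exactly zero covariance with y and
with the predictive score, and n_ortho = 0 reproduces single-component
PLS-DA exactly (verified against scikit-learn's PLSRegression). Class coding
is y ∈ {0, 1}, centered; with a single feature orthogonal components are
impossible and n_ortho is forced to 0 with a warning. Q² = 1 − PRESS/SS_tot
from stratified 7-fold cross-validation (scaler refit per training fold);
R²Y is the training fit. Permutation validation refits after random label
permutation (identity permutations excluded) and reports the null R²Y/Q²
distributions. Outlier exclusion, when requested, is an explicit MAD rule on
predictive scores (threshold × 1.4826·MAD, at most 10% of samples, ids
always reported) so every exclusion is reproducible.

Single-ratio models are reported per ratio and the feature set used is named
in the model report, since a "ratio model" could equally mean the lone ratio
or its constituent amplitudes; both are constructible from the same
amplitude table.

## Numerical choices and degenerate inputs

* Windows are half-open [lo, hi): adjacent segments partition the axis.
* All-zero FIDs, empty target lists, duplicate sample ids, single-class
  label sets, and overlapping target windows raise errors at entry.
* A failing segment marks its targets missing (amplitude 0, flagged) rather
  than aborting a batch.
* Stochastic steps (noise, folds, permutations) take explicit seeds; two
  runs with the same configuration are byte-identical.
* Problem sizes in the test/acceptance runs — 20 noise replicates for
  overlap recovery, 20 study replicates for cohort separation, 50 null
  cohorts with 50 permutations each, 10 replicates in the acceptance
  script's cohort block — were chosen as the package's own compromise
  between statistical resolution of the pass criteria and a test suite that
  runs in minutes.

## Known limitations

* Lorentzian-only lineshapes; no Gaussian/Voigt component.
* The Hankel stage uses a bounded data window (`n_hankel`) for cost; lines
  closer than ~1/T over that window at low SNR may merge (the refinement
  stage can separate them only if the order was selected correctly).
* Back-calculated amplitudes of very broad components (λ·t_start > 3) are
  intrinsically ill-determined and only flagged, not repaired.
* JCAMP-DX support is limited to the time-domain NTUPLES/AFFN dialect;
  spectrometer raw directories must be converted upstream.
* No multi-class discriminant analysis; two cohorts only.
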