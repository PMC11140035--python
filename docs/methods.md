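# Methods

`organoidlab` implements the quantitative analysis chain used to characterise
drug-exposed brain organoids with three modalities — reverberant optical
coherence elastography (Rev-OCE), Brillouin microscopy guided by OCT
structural imaging, and bulk RNA-seq summarisation — together with the
synthetic-data generators that define the ground truth every estimator is
tested against.  This note records the models, the parameters that matter,
the numerical choices, and what the synthetic data do and do not capture.

## Reverberant elastography

### Physical model

A ring of piezo-driven rods vibrating at F = 3 kHz sets up a diffuse field of
shear waves inside the sample.  The model field is a superposition of Q plane
shear waves with propagation directions drawn uniformly on the sphere and a
random transverse polarization per wave; phase-sensitive OCT measures the
axial (z) component of particle velocity on a lateral grid.  The phase
difference between sequential A-lines encodes velocity as

    v_z = λ0 Δφ / (4 π n Δt),

with λ0 = 840 nm the source wavelength, n = 1.34 the tissue refractive
index, and Δt = 40 µs the A-line period (25 kHz rate).  Velocities above
λ0/(4nΔt) = 3.92 mm/s wrap; the simulator default field RMS is 1 mm/s
(≈50 nm displacement amplitude at 3 kHz), comfortably below the limit, and a
per-pixel temporal unwrap is available for larger amplitudes.

### Local wavenumber estimation

For an ideal isotropic reverberant shear field the normalised spatial
autocorrelation of the axial velocity over a transverse lag Δr depends only
on a = kΔr:

    B(a) = (3/2) [ j0(a) − j1(a)/a ]  =  j0(a) − j2(a)/2,

obtained by averaging (p̂·ẑ)² exp(i k n̂·Δr) over directions n̂ and transverse
polarizations p̂ (the sin²θ polarization weight distinguishes this from the
scalar sinc kernel).  The closed form is verified two ways in the tests: a
direct quadrature of the sphere average, and an empirical kernel pooled from
the autocorrelation of large simulated homogeneous fields (agreement
required within 2% RMS over kΔr ∈ [0, 2π]).

The estimator slides a 0.5 × 0.5 mm window (50% stride) over the complex
amplitude of the 3 kHz temporal-harmonic field, computes the unbiased 2D
autocorrelation per window, radially bins its real part (bin coordinate =
exact mean lag radius per annulus), and least-squares fits c·B(kΔr) over a
log-spaced k grid with local refinement, ties broken toward smaller k.  The
shear speed map is v_s = 2πF/k.  Numerical choices that matter, each adopted
after calibration runs on the simulator:

* **Pooling before normalising.** Raw (unnormalised) correlation profiles are
  averaged over a block of neighbouring windows before the fit.  A single
  window is one coherent speckle patch; normalising each window's profile by
  its own zero-lag power and then averaging ratios is biased, whereas
  averaging the raw correlations first is not.
* **Amplitude fitted jointly, zero lag included.** For windows smaller than a
  wavelength B(a) ≈ 1 − a²/5, and a free amplitude is nearly collinear with
  k on lags alone; anchoring the fit with the zero-lag point resolves the
  degeneracy without the ratio bias of pinning the normalisation.
* **Adaptive pooling scale.** When the first-pass median wavelength exceeds
  the window, each window sees a quasi-plane wave whose in-plane wavenumber
  is k·sinθ; the median of such local estimates converges to ≈1.05k, a −5%
  speed bias.  The pooling block is then widened (up to 7×7 windows) until
  the correlation support spans about one wavelength, and the fits repeated.
  On the default 101×101, 2 mm grid this removes the bias at v_s = 5 m/s
  (λ = 1.67 mm) while leaving two-compartment maps at shorter wavelengths
  untouched.
* **Fit quality.** R² is computed over positive lags only; including the
  zero-lag point would let structureless (white-noise) profiles score ≈1.
  Windows need R² ≥ 0.6 and an interior k to count as valid.
* **Spatial bandpass.** An annular FFT-domain mask with raised-cosine edges,
  default cutoffs [0.25, 4]·k_nominal, applied when the velocity data are
  noisy.  A low-side cutoff below ~2 k-space bins of the aperture is skipped:
  at long wavelengths the DC bin carries genuine leaked signal power and
  removing it biases speeds several percent low.  On noiseless data the
  filter is unnecessary (temporal demodulation already averages broadband
  noise down by ~25 dB) and is off by default in the pipeline.

**Precision.** A single 2 mm aperture holds roughly (L/λ)² independent
speckle cells — barely one at v_s = 5 m/s — so the per-acquisition median
speed has an irreducible realization scatter of ~7% there (~1% at 1 m/s).
Calibration studies therefore pool 24 replicate acquisitions per condition
(the wet-lab protocol itself scans three organoids per group) and average
the per-acquisition medians.  With the adaptive pooling the estimator is
unbiased to well under 1% at 1–5 m/s; single-acquisition maps should be read
with the scatter above in mind.

### Heterogeneous phantoms and region summaries

Exact elastodynamic scattering at the shell/core boundary is out of scope.
Two-compartment fields are synthesised with locally varying wavenumber: one
isotropic plane-wave set per compartment sharing directions, polarizations
and phases but using the compartment's k, blended across a ~2-pixel logistic
transition band.  Because the estimator is local and windowed, this local-k
construction is the appropriate test harness for it; what it does not test
is mode conversion, refraction or reflection at internal boundaries.

Region summaries take the organoid mask on the window-centre grid, measure
radius from the mask centroid, and call the outer 20% of the radial extent
"surface" and the rest "core" (configurable `shell_fraction`).  Volumetry
follows the sphericity convention: horizontal and vertical diameters through
the segmentation centroid, d̄ their mean, V = (4/3)π(d̄/2)³ in mm³.

## Brillouin microscopy

Spectra are modelled as a Stokes/anti-Stokes pair of Lorentzians at ±ν_B
about the elastic line, seen through an affine pixel→GHz spectrometer
dispersion, with Gaussian read noise.  Calibration fits both peak pixels for
each reference liquid and regresses known shifts (±ν per liquid) on fitted
pixels; two liquids with distinct shifts are the minimum, three (water,
acetone, methanol) the default.  The shipped reference shifts at 660 nm —
water 6.00, acetone 4.83, methanol 4.42 GHz — are computed from standard
acoustic-velocity/refractive-index tables via ν = 2nV/λ and are explicit
configuration inputs, not constants of the method.  Sample fits use a
symmetric pair model with shared linewidth in frequency space; spectra whose
maximum is within 5 robust SDs of the baseline are reported invalid rather
than fitted.  Closed-loop recovery (simulate → calibrate → fit) is accurate
to <0.1% noiseless and unbiased to ≪ linewidth/10 at peak SNR 10.

OCT volumes are segmented by Otsu threshold, largest connected component and
hole filling.  Two guards keep pure background from segmenting: a minimum
component size, and an Otsu between-class separability ≥ 0.8 — thresholded
speckle percolates into large components, but its separability plateaus
near 0.63 versus ≥0.94 with a real object at 10:1 contrast.  Speckle is
modelled as gamma-distributed multiplicative noise with shape snr²; surface
summaries average valid shifts over the morphological boundary shell
(default 3 voxels).

## Transcriptomics

Counts-per-million normalisation (CPM[g,s] = 10⁶·c[g,s]/libsize[s]) and
log2(CPM + 1); the pseudocount (default 1) is carried in the output
metadata.  Fold changes are ratios of arm-mean CPM (plus pseudocount)
against the control arm — arm means rather than per-replicate values because
each library is a pool of ~20 organoids; a per-replicate mode exists.
Gene lists are threshold-based (default FC > 15 up, < 1/15 down, reported
separately); the four exposure-vs-control up-lists feed an exact Venn
partition whose 15 region counts are checked against brute-force enumeration.
No p-value-based differential testing or multiple-testing correction is
applied — selection in this workflow is deliberately a fold-change screen.
PCA runs on gene-centred (not scaled) log2CPM with samples as observations,
via SVD with a deterministic sign convention (largest-magnitude loading
positive); all genes are used by default, with an option to restrict to the
top-N most variable.

The count simulator draws negative-binomial counts with variance
μ + φμ² (default dispersion φ = 0.1), log-uniform library-size factors over
a 2-fold range, and a 5-arm × 2-timepoint × 3-replicate design.  FOLR1
(folate receptor alpha) carries a planted log2FC of 8 in all four exposure
arms — 256-fold, an induction spanning several orders of magnitude on the
CPM scale while remaining finite — and a nine-gene neurodevelopment set
(DVL3, GATA2, KIF22, LHX2, NEUROG1, NKX2-2, NTF3, SEMA6B, WNT8B) carries
mixed ±1–2 log2FC effects, attenuated in the folate-rescue arms.  The
simulator does not attempt realistic co-expression structure, batch effects
or transcript-length bias; passing tests demonstrate the estimators'
correctness on the stated generative model, not robustness to those
real-data features.

## Statistics

One-way ANOVA is computed from the explicit between/within sums-of-squares
decomposition (F = MS_between/MS_within, p from the F distribution); tables
with zero within-group variance and equal means are flagged degenerate
rather than given a number.  Pairwise comparisons default to pooled-variance
t tests with df = N − k and Bonferroni adjustment min(1, m·p) — the
classical post-hoc behind "ANOVA with Bonferroni's comparisons" — with a
Welch option and a versus-control-only mode (all-pairs is the default).
Family-wise error control is verified by simulation (1000 null tables).
Prevalence uses the exact Clopper–Pearson binomial interval, chosen for
validity at small case counts; the worked examples reproduce the published
NTD surveillance rates 4/426 = 0.94%, 5/1683 = 0.30%, 10/9460 = 0.11%.

## Demo pipeline

The `all` pipeline simulates the full study design (5 arms × 2 timepoints ×
3 replicates).  Arm physics for the demo scenario: dolutegravir arms get
softer cores (×0.75–0.85), slightly softer shells, smaller radii
(×0.88–0.92) and higher surface Brillouin shifts (+0.08–0.18 GHz with the
folate-combination arms highest); day-24 organoids are 10% larger; each
replicate adds ~4% lognormal jitter in size and stiffness so group tests
see biological variance.  The demo acquisition grid is 41 × 41 with 250
timepoints and 400 plane waves — a deliberate reduction of the full
101 × 101 × 500 acquisition that keeps a complete 30-organoid run around
half a minute while leaving every wavelength comfortably resolved (≥7
samples per wavelength at the softest demo core).  Full-resolution settings
are one config line away.

## Known limitations

* Local-k field synthesis ignores scattering at compartment boundaries; the
  shell/core contrast it tests is geometric, not elastodynamic.
* The reverberant-field idealisation (fully diffuse, isotropic) is assumed,
  not demonstrated, for organoid interiors at 3 kHz; eight discrete rods
  approximate it imperfectly in reality.
* Brillouin shifts are reported as GHz, not converted to longitudinal
  moduli — that conversion needs density and refractive-index assumptions
  the measurement itself does not constrain.
* Volumetry assumes sphericity; aspherical organoids bias V cubically in
  the diameter error.
* The wavenumber estimator reports maps on window centres; depth-resolved
  (3D) wavenumber estimation and viscoelastic dispersion are out of scope.
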