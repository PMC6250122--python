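# Methods

This note documents the models implemented in `cryphot`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical decisions a user should know about.

## 1. Signal model and global fitting

A transient-absorption measurement is a matrix ΔA(λ, t) of pump-induced
absorbance changes (decadic OD).  Streak-camera acquisitions are converted
from the image triplet (flash-lamp+laser D_FL, dark D_0, flash-lamp-only
D_F) as ΔA = −log₁₀[(D_FL − D_0)/(D_F − D_0)]; cells where either
difference is non-positive cannot be evaluated and are masked, never
imputed.  Masked cells are excluded from every least-squares problem
downstream (verified by poisoning tests).

The kinetic content is modelled as a sum of exponentials convolved with a
Gaussian instrument response (IRF, centre μ, width σ):

    f_k(t) = ½ exp(−k(t−μ) + k²σ²/2) · erfc((μ + kσ² − t)/(σ√2)),

with the k = 0 limit ½·erfc((μ−t)/(σ√2)) representing *persistent*
components (lifetime far beyond the window).  The persistent component is
carried exactly as k = 0 rather than as a tiny rate: a tiny-but-finite
rate introduces spurious curvature that biases the finite lifetimes.  The
expression is evaluated through `erfcx` wherever the erfc argument is
positive, which keeps it stable to kσ ≫ 10³.

Fitting uses variable projection: for any trial of the nonlinear
parameters, the spectra B solving χ² = ‖ΔA − F B‖² = min are obtained
exactly by linear least squares; only log₁₀(k) (and optionally μ) are
iterated with a Levenberg–Marquardt optimizer.  Optimizing log-rates
enforces positivity and flattens the fs→s dynamic range.  χ² is unweighted
over grid points: on the quasi-logarithmic delay axis (linear to the
switch time, logarithmic beyond it, equal point counts per decade) every
decade of dynamics contributes equally, which is the intended weighting.
Exponential fitting is multimodal, so the fit launches several starts
(default 5) with log-uniform rate jitter in ×[0.2, 5]; ties resolve to the
lowest χ², then the lowest iteration count.  All randomness flows through
one integer seed.

IRF width is held fixed during optimization (it is better determined from
the coherent artefact); the centre μ floats by default.

### Rank analysis

The component count is decided before fitting: a singular component is
significant when (i) its singular value exceeds a noise floor (3× the
median of the trailing half of the spectrum) and (ii) the first-lag
autocorrelations of *both* its singular vectors exceed 0.8 (noise
decorrelates lag-to-lag; kinetic/spectral structure does not).  Counting
stops at the first failure — parsimony protects the nonlinear fit.  Both
thresholds are configurable; the defaults are conventional, since the
underlying criterion is not standardized.  On chirp-corrected data the
analysis typically reports one weak extra component — the interpolation
residual of the correction — some 40-fold below the leading singular
value; it is real structure, and the user decides whether to model it.

### Preprocessing

Pump scatter is time-independent, so the mean of the pre-time-zero columns
is subtracted per wavelength (idempotent).  The probe-continuum chirp
t₀(λ) — about 1.5 ps across the visible for a CaF₂ continuum — is modelled
as a low-order polynomial and removed by shifting each wavelength row via
shape-preserving piecewise-cubic (PCHIP) interpolation; points shifted
outside the measured axis are masked.  PCHIP avoids the ringing of global
splines at the coherent artefact.  The alternative of fitting per-
wavelength t₀ inside the model is not implemented; shifting is the
default and only mode.

## 2. Target analysis

A compartmental scheme is a first-order rate matrix K over named transient
species with initial populations p₀ (the photo-excited fraction).  With
eigen-decomposition K = V Λ V⁻¹ the concentrations under an IRF-convolved
δ-excitation are C(t) = V diag(f_{−λᵢ}(t)) V⁻¹ p₀ — each eigenmode is an
IRF-convolved exponential.  When the scheme's eigenrates match the fitted
rates, C(t) = F(t)·A with an invertible modal amplitude map A, so

    SAS = A⁻¹ · DADS,   F·B = C·SAS,   χ² unchanged (asserted exactly).

Rate matching uses an absolute tolerance scaled to the largest rate,
because eigenvalue round-off is absolute at the scale of ‖K‖, not relative
to each eigenvalue.

Two spectral-arithmetic steps quantify the branching:

* **Ground-state addition.**  The DADS sum equals (initially excited
  species − ground state) × excited amount.  The smallest amount of
  ground-state spectrum that leaves no negative lobe inside the
  ground-state band (default 430–490 nm) is the photo-excited amount; it
  anchors all quantum-yield estimates.  The estimator reads low by the
  ratio of excited-state to ground-state absorption at the most bleached
  wavelength (≈1–2 % under the synthetic conditions).
* **Flavin stripping.**  The persistent DADS contains the stable radical
  pair minus ground state.  The coefficient α that removes the
  (excitation-scaled) FAD˙⁻ − FAD difference spectrum, in the
  least-squares sense over a flavin-dominated window (default 430–500 nm),
  measures the surviving radical-pair fraction; RPR = 1 − α.  The window
  is a package decision — the original criterion ("all flavin features
  disappear") is visual.  When the counter-radical absorbs inside the
  window the projection inherits a bias of order +1 percentage point on
  RPR under the synthetic conditions; detrended and curvature-matched
  variants were evaluated and rejected (degenerate with the flavin
  difference, or noise-amplifying).  A residual-correlation diagnostic
  (|corr| with the flavin difference inside the window) is reported.

Equilibrated tryptophan radicals that the data cannot distinguish are one
effective compartment with a composite spectrum; the model layer does not
pretend to resolve them.  Model rates are fixed to the fitted rates by
default (two-stage workflow) rather than refitted.

## 3. Basis decomposition and pocket pH

Spectra sequences are decomposed per time point over a species basis by
plain least squares (default) or NNLS.  Fractions are normalized by the
fitted species total of the first point (the dark-state amount); the
per-point deviation of the species sum from 1 and the residual norm are
*reported*, never silently normalized away — conservation is the
diagnostic by which the basis is judged.  An ill-conditioned basis
(condition number above 10⁶) warns; above 10¹⁰ it is an error.

The binding-pocket pH follows Henderson–Hasselbalch,
pH = pKₐ + log₁₀([FAD˙⁻]/[FADH˙]) with pKₐ = 8; the package takes the
concentration ratio (from decomposition) as input, because the
extinction-ratio conversion behind any absorbance-only shortcut is not
standardized.

## 4. Anisotropy

r(λ, t) = (ΔA∥ − ΔA⊥)/(ΔA∥ + 2ΔA⊥), masked where the isotropic signal is
below 1 mOD (the anisotropy diverges at isosbestic and bleach-cancellation
points).  Magic-angle data are (∥ + 2⊥)/3.  Theoretical values use
photoselection, r = 0.4·P₂(cos θ), taking pairwise pump–probe dipole
angles as input — extracting dipoles from structures or QM output is out
of scope.  Population-weighted averages assume equal band shapes.  The
"magic angle" printed as 54.71° is a rounded instrument setting; the exact
zero of P₂ is at 54.7356°, so r(54.71°) ≈ 2.5×10⁻⁴, not 0.

## 5. Photocycle model

One photon drives: FAD* →(848 fs) RP1 →(46 ps) either ground (fraction
φ_rec = 0.20) or the equilibrated RP2/3; →(τ ≈ 30 ns) RP4; →(1 μs)
deprotonated RP4d; the neutral tryptophan radical then decays (187 ms)
into the absorbing product Trp-X while FAD˙⁻ re-oxidises with
τ_reox/[O₂] (τ_reox = 60 s at the reference oxygen level; the anaerobic
limit is no decay).  The RP4 formation time is only bracketed between 3
and 100 ns by experiment; 30 ns is the geometric midpoint and
configurable.  Populations are propagated with an exact triangular-cascade
eigen-solver (eigenvalues are the diagonal of the flow-ordered rate
matrix; eigenvectors by forward substitution).  Generic `expm`/`eig`
propagation is kept as a cross-check but loses accuracy catastrophically
across 14 decades of rate stiffness (absolute eigenvalue errors of order
eps·‖K‖ corrupt the slow components); the analytic path conserves total
population to machine precision.

Repeated illumination sacrifices the tetrad positions terminal-first: each
productive photocycle (probability 1 − φ_rec per absorbed photon)
decomposes the current terminal tryptophan; after the three sacrificial
positions (4, 3, 2) are consumed, the remaining photochemistry recombines
at tryptophan 1 and the destabilised pocket releases FAD with probability
φ_release per absorbed photon.  Φ(FAD˙⁻) = 1 − φ_rec exactly;
Φ(FAD release) is defined operationally as released FAD per absorbed
photon over the protocol.

The per-protein absorbed-photon rate and φ_release are calibrated so that
the standard 30 s protocol (10×1 s, 2×5 s, 1×10 s pulses with full
re-oxidation between) releases half the FAD at an overall 6 % per-photon
yield — the two stationary observables of the protocol; this folds
saturation and inner-filter losses into one effective rate (the naive
Beer–Lambert dose from the stated OD and pulse energy is several-fold
larger).  The calibration is solved at run time (Brent root-finding on the
sacrifice-chain endpoint), not hard-coded.

DTT chemistry is reduced to an optional modifier of the re-oxidation rate;
the model is deterministic (ensemble populations) throughout.

## 6. Synthetic data

Species spectra are Gaussian-band sums anchored at reported band
positions (oxidised FAD 365/450 nm with vibronic shoulders; FAD˙⁻
367/403/472 nm; FADH˙ red-shifted 39 nm into 550–700 nm; the tryptophanyl
radical cation with its broad ~565 nm band plus the 410 nm protein band;
the neutral radical near 510 nm; Trp-X below 400 nm).  Matrices are built
as C(t)·S(λ)ᵀ from the same compartment schemes the analysis assumes, plus
Gaussian IRF, probe chirp (ps regime, evaluated exactly on shifted time
grids — no interpolation in the forward model), constant pump-scatter
spectrum, and i.i.d. Gaussian noise with σ = peak|ΔA|/SNR.  Polarized
matrices weight each species by (1 + 2r₀) and (1 − r₀) so the magic-angle
identity holds by construction; r₀ is time-independent (no rotational
diffusion).  Default SNR is 30 — recovery tolerances (10 % on lifetimes,
±3 points on fractions) are then achievable but not trivial.

What the generator does *not* emulate: vibronic structure beyond Gaussian
sums, shot/detector noise statistics, pump-intensity fluctuations,
rotational depolarization, sample degradation within one scan.  Passing
closed-loop tests therefore demonstrates correctness of the estimators
under the stated noise model, not robustness to every instrument
pathology.

Problem sizes follow the instruments: 121 wavelengths × 500 quasi-log
delays (ps regime), 121 × 300 (μs), 31 single-wavelength traces × 801
points at 12.5 ms (ms regime), 14 spectra for the 13-pulse sequence.  The
replicate batteries in the test suite run reduced replicate counts
(8–20) of these sizes; the acceptance workflow averages the sub-ps
analysis over 3 independent replicate measurements, matching the
experimental protocol of several independently analysed scans.

## 7. Known limitations

* The RPR estimator inherits a ~+1 point systematic when the
  counter-radical absorbs inside the stripping window (§2); the reported
  uncertainty band (±3 points) covers it.
* `GlobalFit` handles one matrix at a time; simultaneous multi-dataset
  fitting and non-Gaussian or wavelength-dependent-width IRFs are out of
  scope.
* The kinetic layer assumes branching cascades (no feedback loops);
  genuinely reversible schemes are rejected by the analytic propagator.
* Rotational-ambiguity resolution beyond rank counting (multivariate curve
  resolution) is not attempted.
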