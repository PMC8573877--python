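# Methods

## Signal model and assumptions

Every simulated and fitted frame is a saturation-prepared single-shot
magnitude image. The forward model per pixel and frame is

    S = A (1 − exp(−τ/T1)) exp(−TE/T2)

with A the proton-density amplitude, τ the saturation-to-readout delay and
TE the T2-preparation echo time (0 when no preparation is played). Three
idealisations are made deliberately:

* **Perfect saturation and inversion efficiency.** No residual longitudinal
  magnetisation after the saturation pulse, no B1-dependent efficiency map.
* **Instantaneous readout.** The single-shot bSSFP readout neither perturbs
  the recovery nor contributes its own weighting; in practice a variable
  flip-angle readout is what makes this a reasonable approximation, and the
  fitted model contains no readout-recovery correction term.
* **T2 preparation immediately before readout.** The T2-prep decay
  multiplies the saturation-recovered magnetisation; its sub-beat timing is
  not otherwise modelled. The recovery heartbeat attached to T2-prepared
  frames is schedule bookkeeping only — their effective recovery delay is TS,
  while anchors recover for `recovery_beats·RR + TS`.

Because every frame follows a saturation, signals are non-negative and the
data are fitted as real values: no phase restoration or polarity recovery is
needed (an intrinsic advantage of saturation recovery over inversion
recovery at the acquisition stage). The inversion-recovery and IR+T2-prep
signal equations are implemented for reference and for the reduction
identities they satisfy, not as the primary synthesis path: the calculated
PSIR images deliberately use the linear rate formulation below.

## Protocol

The default mapping protocol acquires 30 images in 45 heartbeats: 3 anchor
images (3 recovery beats each), 6 T2-prepared SR images at TE = 55 ms
(1 recovery beat each), 21 plain SR images at TS = 300 ms (no recovery
beats); so 3·4 + 6·2 + 21·1 = 45 beats. The heartbeat interval RR defaults
to 1000 ms (60 bpm) and is a free parameter. Event ordering within the
schedule is not physically constrained under the full-saturation assumption
(each frame's signal depends only on its own preparation), so the default
places anchors first, then T2-preps, then SRs; fits are invariant under
event permutation, and this is tested. Conventional bright-blood
(8 images / 16 beats, paired IR and proton-density beats) and dark-blood
(16 images / 32 beats) LGE protocols are represented for heartbeat
accounting only; their frames are not simulated.

## Joint fitting

Per-pixel trust-region reflective least squares (`scipy.optimize.
least_squares`) over (A, T1, T2) with the analytic Jacobian. Initialisation:
A₀ = max anchor signal; T1₀ = −TS/ln(1 − S_SR/A₀) from the mean SR signal,
clipped to [100, 3000] ms; T2₀ = −TE/ln(S_T2prep/S_SR(TS)) from the mean
T2-prepared signal, clipped to [10, 500] ms. Bounds: T1 ∈ [50, 5000] ms,
T2 ∈ [5, 1000] ms, A > 0. Cost tolerance 1e−10, at most 200 function
evaluations. A fit that ends pinned at a bound, fails, or starts from
degenerate signals (e.g. all zeros, where no amplitude estimate exists) is
flagged `converged = False` and excluded from downstream medians; it never
raises. Joint estimation makes the T1 estimate independent of T2 and vice
versa, which is what permits accurate T2 at short post-contrast T1.

The public API follows the Model/Results convention: `MSashaModel(series,
protocol).fit(mask)` returns an `MSashaResults` carrying amplitude/T1/T2
maps, an RMS residual map, a convergence mask, `summary()`, and derived
products (rate maps, reference estimation, PSIR synthesis, plotting).

## Calculated PSIR synthesis

Bright-blood: `BB = R1 − R1m`. Dark-blood:
`DB = R1 − R1m/(a_DB·R2/R2m + (1 − a_DB))` with
`a_DB = (R1m·R2m/(R1b − LGEb) − R2m)/(R2b − R2m)`, the unique weight that
keeps normal myocardium nulled while placing the blood operating point
(R1b, R2b) exactly at LGEb. Properties relied on (and tested): DB ≡ BB
wherever R2 = R2m; the blood pixel evaluates to LGEb for any LGEb in a
sweep; both images are exactly zero at the myocardial reference point; BB is
affine in contrast concentration through the relaxivity model.

Reference values (R1m, R2m) and (R1b, R2b) are medians of the fitted maps
over user-supplied myocardium and blood masks (phantom labels in tests).
The median over the whole myocardial segment — scar included — estimates the
normal value; it is robust while abnormal tissue covers less than half the
segment, and the PSIR formulation tolerates moderate reference error (the
images can be window-leveled, like retrospectively re-nulling an acquired
PSIR). Automatic segmentation is intentionally out of scope: masks are
explicit inputs. LGEb defaults to −0.5 Hz; the choice is a display/contrast
preference, not a physical constant, and `lgeb_sweep` exposes the trade-off.

Pixels where the DB denominator is non-positive (possible only for extreme
a_DB and short T2) become NaN and are counted on the image object.

Edema attenuation: for acutely injured myocardium both T1 and T2 rise, and
the elevated R2 term attenuates the calculated DB signal. The attenuation
surface is reported as the ratio DB(T1, T2)/BB(T1) at equal T1 — unity when
the edematous T2 equals remote T2, decreasing in T2, and undefined (NaN)
where BB is zero (T1 equal to remote). A difference-based ordinate would
carry the same information; the ratio was chosen because it is
dimensionless and independent of the T1 offset, and this was a genuinely
open design choice.

## Phantoms and noise

The vial phantom places 9 circular vials (radius 10 px on a 128×128 grid)
with ground-truth (T1, T2) equal to the long-TR spin-echo reference values
of the standard 9-vial quality-assurance plate, spanning post-contrast
myocardium to native blood. The cardiac phantom is a circular blood pool,
a myocardial annulus (radii scale with the grid; 28/40 px at 128), and a
scar sector (default 75°), subendocardial for infarct scenarios and
subepicardial for myocarditis; tissue values are post-contrast group means
(chronic: MI 441/43.8, remote 668/42.4, blood 466/142.4 ms; elevated-T2
scenarios: 392/58.3, 608/41.7, 396/141.8 ms). Proton density is 1.0
everywhere by default (the calculated PSIR depends only on the rates).

Noise is zero-mean additive Gaussian on the magnitude frames with
sd = (amplitude scale)/SNR, where SNR is referenced to the anchor image —
the moderate-to-high SNR regime of motion-corrected averaged images, where
the Rician distribution is effectively Gaussian; a Rician option exists for
low-SNR work. Frames are generated pre-registered: respiratory motion and
motion correction are not simulated, so the phantom validates the
estimation chain, not motion robustness. Partial-volume effects, coil
sensitivity profiles and flow artefacts are likewise absent — passing tests
demonstrate correctness of the estimator and synthesis algebra under the
stated noise model, not clinical image quality.

## Monte-Carlo SNR/CNR

The calculated images are non-linear in the fitted parameters, so their
noise statistics are propagated by simulation: per region (scar, remote,
blood), Gaussian noise at sd = (region anchor signal)/SNR is added to the
region's noise-free 30-point signal vector, the joint fit is run, and the
BB/DB formulas are evaluated on the estimates; means and standard
deviations over trials (default 10,000) give region signal statistics, and
CNR = (mean difference)/(sd of the reference region — by convention the
second-named region, configurable). Failed fits are dropped and counted,
with a warning above a 5% failure fraction. A linearised mode samples
(A, T1, T2) from the Gauss–Newton covariance σ²(JᵀJ)⁻¹ at the true
parameters instead of fitting each trial; it agrees with the full chain at
moderate-to-high SNR and is used where speed matters. Patient-study CNR
magnitudes are not reproducible without the per-region raw anchor SNRs of
real scans, so the suite asserts distributional properties instead: the
remote-region mean BB signal is statistically zero, dispersion falls with
SNR, and the scar-to-blood CNR of the dark-blood image exceeds the
bright-blood one under matched conditions.

## Problem sizes and numerical choices

Map-level tests fit 64×64 phantoms (vial radius 5–6 px) or mask-restricted
128×128 grids; the SNR-40 recovery check fits all ~2,800 vial pixels of the
full-size plate; the Monte-Carlo test uses 1,000 full-fit trials per region.
These sizes were chosen so the whole suite runs in well under a minute on a
laptop core while keeping every ROI large enough (≥ 25 px enforced) for
stable medians. Determinism: every stochastic step takes an explicit
`numpy.random.default_rng` seed, and identical invocations produce
bit-identical series, maps and bundles.

## Known limitations

* The fitted model is validated against its own forward simulation; scanner
  data with readout-driven recovery, imperfect saturation or off-resonance
  would need the corresponding model extensions.
* Post-contrast T2, though accurately estimated, is not a substitute for
  native T2 in edema assessment (myocardial T2 is itself reduced by
  gadolinium).
* Severe T2 elevation attenuates the calculated DB signal (see the
  attenuation surface); with deep blood suppression this can mask enhancing
  edematous tissue, mitigated by choosing a greyer LGEb.
* The scar-region T2 of real subendocardial infarcts is contaminated by
  adjacent blood; phantom regions are homogeneous and do not reproduce this.
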