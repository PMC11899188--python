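# Methods

This note records the models, numerical choices and their rationale, in the
order the pipeline runs them.

## Study design emulated by the synthetic cohort

The cohort generator reproduces the design of a paired pre-/post-operative
plasma study: 20 healthy volunteers measured once and 10 colorectal-cancer
patients measured preoperatively and 7 days after surgery. Patient metadata
(age, sex, staging, hemogram values) ship as a packaged fixture transcribed
from the study's clinical table; the volunteers' individual data are not
published, so `data/volunteers_synthetic.csv` contains synthetic stubs whose
ages span the published 26–65 range with the published mean of 52.

Each subject contributes:

* **Two CPMG decays** (echo times 70 µs and 500 µs, 3000 echoes, recycle
  delay 3 s, 64 scans). The forward model is a discrete multi-exponential,
  M(τ_k) = Σ_j a_j e^(−τ_k/T₂j) + ε_k, with iid Gaussian noise. The default
  truth per group is (1.5 ms, 0.05), (8 ms, 0.10) plus a dominant soluble
  component at 550 ms (healthy), 400 ms (preoperative) or 480 ms
  (postoperative) — the qualitative geometry of plasma T₂ distributions
  (one large long-T₂ peak, small short-T₂ peaks) with surgery recovering the
  soluble peak partway. The noise default, 0.002 of the initial amplitude
  (SNR 500), is a free choice: raw decay SNRs are not published for this
  kind of benchtop instrument, and 500 is typical of 64-scan CPMG on a
  20 MHz magnet. Gaussian rather than Rician noise is used because CPMG
  magnitude data at this SNR are far from the Rician floor and the Gaussian
  case keeps every oracle exact.
* **One FT-IR spectrum** on the axis 350 + 4k cm⁻¹, k = 0..912 (913 points;
  the nominal 350–4000 range at 4 cm⁻¹ sampling ends at 3998). Spectra are
  sums of Gaussian bands: 10 bands below 1850 cm⁻¹ (fingerprint, amide II/I,
  lipid ester), one weak broad band near 2100 cm⁻¹, and 11 bands in the
  2700–3800 cm⁻¹ stretching massif, with apex absorbances in [0.08, 1.0].
  Band centers follow conventional plasma assignments; widths and spacings
  were fixed once so that the 11 high-wavenumber bands are *identifiable* at
  the benchmark noise level — a benchmark whose truth cannot be recovered
  even from the true starting point (as happens when two σ ≈ 60–70 cm⁻¹
  bands overlap heavily) tests nothing. Disease enters as group-dependent
  amplitude offsets: preoperative samples gain amide-I/II and amide-A/O-H
  amplitude (+0.18/+0.06/+0.10); postoperative samples recover halfway along
  that axis *and* gain C-H stretching amplitude (2940: +0.10, 3120: +0.06).
  The second, orthogonal displacement is what makes the postoperative group
  a distinct cluster rather than a point on the healthy–preoperative line,
  matching the healing-state phenomenology the analysis is meant to detect.
  Between-subject variability is a lognormal jitter (CV 2 %) on every band
  amplitude; spectral noise is white with σ = 0.003 absorbance.

Randomness is split per (master seed, subject index, measurement stream)
through `numpy.random.SeedSequence`, so any single measurement regenerates
in isolation and a rerun with the same seed is bit-identical.

What the generator does **not** emulate: baseline drift and scattering
artifacts, water-vapour lines, correlated (instrument) noise, pathlength
variation, non-Gaussian line shapes, and any real biochemical covariance
between bands. Passing tests therefore demonstrate the correctness of the
algorithms under the stated statistical model, not the clinical separability
of real cohorts — the synthetic group structure is deliberately much cleaner
than the published AUCs (≈ 0.55–0.70) suggest real data are.

## T₂ inversion

The inverse Laplace transform is discretized on a log-spaced grid
(default 0.1 ms – 10 s, 128 points; the 70 µs × 3000-echo window reaches
0.21 s, and the decade of margin on both sides keeps edge artifacts away
from real peaks). The solver is NNLS on the augmented system
[K; λL] f = [M; 0] with L = I (zeroth-order Tikhonov) by default; a
second-difference L is available. Identity regularization was chosen as the
default because the planted truths are near-discrete spikes, for which a
smoothness prior biases positions more than a norm prior does.

λ selection: with a known noise level the discrepancy principle picks the
smallest candidate whose absolute RMS residual reaches the noise floor;
without one, the maximum-curvature corner of the discrete L-curve
(log residual vs log solution norm) over the candidate ladder
(9 points, 10⁻⁴–1). In the pipeline one λ per echo time is selected on the
first subject and shared: cohort noise is homogeneous (one instrument, one
protocol) and per-subject selection would multiply the inversion cost by
the ladder length for no accuracy gain at SNR 500.

Peak handling: apexes are local maxima above `min_rel_height` (default 1 %)
of the distribution maximum; peak supports extend to flanking interior
minima (each minimum belongs to the left peak only, so area fractions sum
to ≤ 1); the reported position is the amplitude-weighted mean in log T₂,
which is stable against the symmetric broadening regularization introduces.
Peaks at ≥ 100 ms are classified soluble, below insoluble; the threshold is
configurable and sits in the wide empty band between the insoluble cluster
(< 10 ms) and the soluble peak (≥ 400 ms) of the default truth.

Pre→post comparison: the main (largest-area) peak's shift in decades,
log₁₀(T₂post/T₂pre); peak sets matched greedily by nearest log-position
within a 0.15-decade gate; magnitude classes none/small/medium/large at
0.05/0.15/0.4 decades, promoted to at least medium when a peak appears or
vanishes. The thresholds operationalize the qualitative no/small/medium/
large language such studies use; all are parameters.

## Band deconvolution

Bounded least squares (`scipy.optimize.least_squares`, TRF) over center,
σ and amplitude per band (center inside the window, σ ∈ [2 cm⁻¹, window
width], amplitude ≥ 0), pure Gaussian by default; a pseudo-Voigt mix is
available (`eta`), as is a co-fitted linear baseline. The fit quality
metrics (residual RMS, R²) are definitional: the fitted model plus the
residual reconstructs the data exactly.

Initialization matters more than optimization here. Auto-initialization
takes candidate centers from the local minima of the Savitzky–Golay
(window 13, cubic) second derivative — a Gaussian band leaves a sharp
negative d² lobe at its center even when it only appears as a shoulder —
keeps the candidates exceeding 4× the propagated noise floor, then grows
the model greedily: fit, seed the next band at the largest smoothed
residual, refit. Two refinement passes follow: collapse near-duplicate
bands (gap < max(3 steps, 0.6 σ)) by relocating the weaker one to the worst
residual, and, while the residual RMS exceeds the noise-floor estimate
(MAD-robust), try relocating bands weakest-first, keeping only
cost-improving moves. On the default synthetic truth this recovers all 11
high-wavenumber centers within ±3 cm⁻¹ at 0.5 % noise; an explicit `init`
list (the practitioner's band table) bypasses the search entirely.

## PCA, evolution vectors, ROC

PCA is fit once on all 40 rows (mean-centering only — columns share
absorbance units, so variance scaling would inflate noise channels; SNV is
deliberately not applied by default because the generator plants no
pathlength variation). Component signs are fixed by making each loading's
largest-magnitude element positive; score plots are therefore reproducible,
but the *orientation* of PC1 relative to "healthy" is data-dependent, which
is why the planted-drift test asserts sign-consistency (patients move along
PC1 in the direction of the healthy cluster) rather than a literal sign.
The full 350–3998 cm⁻¹ axis enters the PCA; restricting to a window is a
parameter.

Evolution vectors are the pre→post displacements of each patient in the
PC1–PC2 plane, labeled `pc1_increasing` (conventionally drawn black) or
`pc1_decreasing` (red); zero displacement ties break to increasing.

ROC curves sweep the raw score with "greater ⇒ positive" orientation; AUC
is the trapezoid area, equal (to rounding) to the Mann–Whitney pair-count
statistic, which the tests verify. AUC < 0.5 sets `partner_positive` rather
than flipping the curve, preserving the reported convention that the
"true positive component was the partner". The optimal cut-point maximizes
Youden's J; no confidence intervals are attached (out of scope).

## Probability maps

`MLPClassifier` with layers (16, 16), ReLU, L2 10⁻⁴, softmax output,
L-BFGS solver, `max_iter` 2000, fixed seed. The architecture is a design
choice — nothing about it is published — sized for ~40 training points:
big enough to carve non-convex regions, small enough that L-BFGS converges
deterministically in milliseconds. Training uses all points without a split
(the map describes the training geometry; `loo_accuracy` exists as a
separate diagnostic) and without class reweighting (matching the 20/10/10
design as analyzed). The map grid is the training bounding box padded 10 %
at 200×200 resolution; probabilities at every cell sum to 1 by construction.
Band labels use lower-inclusive/upper-exclusive edges (a cell at exactly
0.70 is "high").

## Pipeline and reproducibility

Stages run in fixed order (cohort → relaxometry → FT-IR → chemometrics →
prediction), each writing CSV/JSON tables under its own subdirectory, with
stage-tagged errors. FT-IR deconvolution in the pipeline runs on the three
group-mean spectra (the per-subject fits add cost but no information the
chemometrics stage uses; the deconvolution API itself is per-spectrum). The
run manifest records config, seed, package versions and SHA-256 of every
output file; in synthetic mode rerunning the same config and seed
reproduces every byte, which the acceptance checks verify. A full default
run (40 subjects, 80 inversions on a 128-point grid, six band fits, PCA,
8 ROC analyses, 200×200 map) takes a few seconds on one core.

## Known limitations

* The inversion's resolution limit is physical: components closer than
  ~half a decade merge at realistic SNR, and positions of components whose
  T₂ exceeds the sampled window (500 ms vs a 0.21 s window at TE 70 µs) are
  recovered with a few percent bias.
* Band-fit identifiability degrades continuously with overlap; the rescue
  sweeps reduce but cannot eliminate local-minimum risk for band systems
  far from the benchmark geometry.
* The classifier map is a descriptive device over ~40 points; its regions
  are not calibrated probabilities for new patients.
* Deproteinization is modeled only as damping of insoluble decay fractions;
  its spectroscopic consequences (solvent bands, protein removal) are not
  simulated.
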