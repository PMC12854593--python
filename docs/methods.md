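# Methods

## Measurement model

Each SORS acquisition yields two spectra of the same jar on a common
wavenumber axis. The package's working model is a two-layer linear mixture:

    zero   = a_z · container + b_z · fluid + noise
    offset = a_o · container + b_o · fluid + noise

with the subsurface-enrichment condition `b_o/a_o > b_z/a_z` (the offset
geometry sees relatively more of the fluid behind the wall). The analysis
never needs the four weights individually — only the two ratios that null
one layer: `SF_f = a_o/a_z` (container-null, fluid isolation) and
`SF_r = b_z/b_o` (fluid-null, container isolation).

## Scaling-factor estimation

The forward factor is estimated by three deterministic candidates, each of
which can only err on the over-subtraction side in its blind regime, so the
smallest is used:

* **Window regression** — non-negative least-squares coefficient of the
  zero against the offset spectrum inside a container-dominant window
  (default 1720–1800 cm⁻¹, the high edge of the analysis region beyond the
  fluid bands). Exact when the window is container-pure; any fluid leakage
  (water-band tails, fluid fluorescence) biases it high.
* **Raw negativity search** — both layers are non-negative, so
  `offset − SF·zero` stays non-negative until the container is
  over-subtracted. The largest SF on a grid (default step 0.01, two decades
  of refinement) whose negativity penalty `Σ min(residual, 0)²` stays at an
  estimated noise floor. Near-exact at low noise; a smooth fluorescence
  floor delays the onset of negativity, biasing it high.
* **High-passed negativity search** — the same search after subtracting a
  Savitzky–Golay locally-quadratic smooth (window 31 points, wider than any
  Raman band). The high-pass is linear, so channel mixing ratios are
  preserved; smooth floors are removed, making sharp (polymer) container
  bands detectable, but featureless glass becomes invisible (the candidate
  then runs off the top of the grid and never wins the minimum).

The feasibility threshold combines a white-noise floor (noise σ estimated
from the median absolute second difference, which annihilates smooth
signal) with the negativity the inputs carry on their own (high-pass side
lobes); a per-point depth test catches concentrated dips that do not move
the total penalty. The allowances deliberately do not scale with SF: the
residual's intrinsic negativity has coefficient `b_o − SF·b_z`, which
shrinks as SF grows.

The reverse factor is not identifiable from non-negativity when the glass
fluorescence never vanishes (there are no fluid-only pixels). It is instead
chosen so that the high-passed container branch is orthogonal to the
high-passed forward-isolated fluid spectrum, restricted to strong
fluid-detail pixels; the role-exchanged negativity search is the fallback
for degenerate inputs. Reverse errors are conservative (under-subtraction
leaves a small positive fluid residue in the container branch), which the
downstream curve resolution tolerates.

## Container deflation and baseline

Residual container signal left by an imperfect SF is removed in two ways,
split by the character of the reference container profiles bundled with
the package:

* profiles with substantial sharp content (polymers: PMMA, LDPE, PP) are
  fitted to the fluid branch in the high-pass domain and subtracted
  (ordinary least squares — the fit is unbiased because the references are
  fluid- and noise-free);
* featureless envelopes (the three glasses) extend the baseline model:
  the baseline fit is an iteratively clipped least-squares fit of a
  5th-order polynomial *plus* the glass envelope shapes (20 iterations;
  points above the fit are replaced by it, so peaks do not drag the
  baseline up). Since these shapes are smooth, any error in their
  coefficients only changes smooth background the baseline would remove
  anyway.

Subtraction and baseline fitting run on the full measured axis (default
600–1900 cm⁻¹) and the result is truncated to the closed analysis window
750–1800 cm⁻¹ afterwards, so the poorly-determined polynomial edges fall
outside the analysis region. SNV normalization ((x − mean)/sd per
spectrum) is applied to the fluid branch only; the container branch keeps
physical magnitude so curve-resolution scores remain interpretable as
contributions.

## Classification

PCA is a mean-centered SVD with loadings sign-fixed (largest-magnitude
element positive). The retained dimension covers 99.9 % of cumulative
variance, capped at 10 and at half the sample rank. The 99 %-variance rule
was tried first and discarded: with 13 classes the discriminating
directions for percent-level components (methanol, formaldehyde) live in
low-variance PCs and were being truncated away.

KNN uses k = 4 and Euclidean distance in score space; ties break by the
smaller mean neighbor distance, then lexicographic label order. A query is
refused as out-of-calibration when either of two calibration-anchored
limits is exceeded, both at the 99th percentile of leave-one-out
statistics:

* the mean k-neighbor distance (scores live inside the calibration
  subspace), anchored on per-replicate leave-one-out distances;
* the off-model residual norm (Q statistic; novel chemistry is orthogonal
  to the calibration subspace and invisible to score distances), anchored
  on held-out *averages of replicate pairs*, because classification
  queries are replicate averages and in-sample residuals understate what
  an unseen spectrum produces.

Outcome flags: a sample is AMBIGUOUS when its replicate-level labels
disagree but share one main-excipient family, or when the nearest-class
margin is below 10 %. The margin compares squared distances to the nearest
member of each class (squaring cancels the common noise-energy floor;
single-link does not penalize classes that legitimately span a
concentration range) and is only evaluated when the k-neighbor vote was
contested. FAILED marks refused queries, measurements without usable
zero/offset contrast (subtraction RMS below 5 % of the offset RMS), and —
when a ground-truth table is supplied — predictions that contradict it.

Residual analysis subtracts the assigned class reference scaled by least
squares, refits the scale excluding pixels the contaminant dominates (one
robust pass at 3 robust-σ), and reports peaks whose prominence *and*
height exceed a threshold (default 5) times the MAD-based residual noise
σ. The height requirement matters: peak-to-valley prominence of pure noise
reaches about 6 σ.

## Container typing

Non-negative MCR-ALS: rows are min-shifted to non-negativity, the start is
a deterministic SVD-based non-negative factorization (NNDSVDa; the seed
only adds a 1e-10 symmetry-breaking jitter), and scores/spectra alternate
through non-negative least squares until the relative reconstruction-error
change drops below 1e-8 (cap 2000 iterations; non-convergence returns a
flagged result, not an exception). Components are ordered by total score
mass and scaled to unit maximum. Each component is matched to the
reference container profile with the highest cosine similarity, and each
sample takes the material of its highest-scoring component; exact ties and
all-zero rows yield "indeterminate".

## Synthetic world

The simulator renders components as pseudo-Voigt band sets. Two band
positions are anchored to the values the analysis itself keys on (methanol
1034 cm⁻¹, potassium acetate 926 cm⁻¹); the rest are plausible constants,
and every test depends only on internal consistency. Choices that shape
the difficulty of the problem, made once:

* **Calibration classes** — C1–C13 follow the mock-fluid table; C14–C20
  are stand-in recipes for the named historic formulations (Steedman's,
  Kaiserling III, Bouin's variants) whose full compositions are not
  tabulated. Each class is one prepared solution at its tabulated
  (mid-range) composition; replicates model repeat measurements across
  days with independent noise and ±2 % relative re-preparation
  variability. A printed range (e.g. ethanol 70–80 %) is treated as a
  nominal description of one solution, not a uniform population — a
  continuum reading makes the range's endpoints coincide with the
  contaminated point classes (70 % ethanol + 1 % formaldehyde), which
  would leave the documented percent-level discrimination unattainable in
  principle.
* **Scattering strengths** — components mix by volume fraction times a
  relative scattering strength (default 1). Formaldehyde is set to 2.5 so
  that a 1 % admixture stands a few σ above both the shot noise and
  percent-level ethanol concentration differences — the sensitivity
  through-container Raman demonstrably has for low-level formaldehyde.
  The default counts scale (1e5 counts per unit intensity) was chosen on
  the same ground.
* **Containers** — the three glass families peak at clearly different
  emission positions (below, inside, and above the analysis window), the
  premise behind fluorescence-based glass discrimination; polymers carry
  sharp Raman bands over weaker, per-polymer fluorescence pedestals.
  Earlier drafts with near-collinear envelopes (pairwise cosine > 0.95)
  made the non-negative factorization rotationally ambiguous — no correct
  algorithm can separate profiles the world does not distinguish.
* **Mixing** — zero = 0.8 container + 0.2 fluid, offset = 0.3 + 0.7;
  any weights obeying the enrichment condition must (and do) pass the
  recovery tests.
* **Noise** — Poisson shot noise on counts, additive read noise (1e-3),
  a random cubic drift (coefficient σ 0.01) per channel, and an optional
  broad fluid-fluorescence envelope (scale 0.1). Counts are clipped at
  zero, so the linear-mixture expectation holds only where the signal is
  clear of the detector floor.
* **Cohort scenarios** — the default 46-sample cohort holds 40
  in-calibration fluids (classes C1–C13 cycled over all six container
  materials, nominal compositions — a jar at the edge of a
  concentration-range class is a deliberately ambiguous scenario, not a
  routine one) and 6 formulation-strength out-of-calibration fluids
  (quaternary-ammonium fixative at 5 % and 10 %, formaldehyde + ethylene
  glycol, 35 % ethylene glycol, phenoxetol + formaldehyde, potassium
  acetate + picric acid). One jar holds one fluid: composition jitter is
  drawn per sample, never per replicate.

What a green synthetic run does **not** establish: performance on real
museum spectra. The simulator has no cosmic rays, no wavenumber
miscalibration between instruments, no specimen autofluorescence
structure, no container aging or wall deposits, and its component library
is internally consistent rather than literature-accurate. The synthetic
tests establish that the *algorithms* do what they claim under the stated
model, with honest noise.

## Numerical conventions

* Truncation interval closed on both ends; axis mismatches raise rather
  than silently interpolate; resampling is explicit linear interpolation
  with no extrapolation.
* The csv2col file dialect (`# key: value` headers, `wavenumber,intensity`
  rows, `repr` floats) round-trips bit-exactly, which is what makes the
  byte-identity determinism checks meaningful.
* Model serialization is a single sorted-key JSON document (axis, PCA
  mean/loadings/explained variance, KNN scores/labels/k, class references,
  both refusal limits).
* Negative values after subtraction are retained in the fluid branch
  (clipping would bias SNV); curve-resolution input is min-shifted per
  spectrum instead.
* One SF pair is computed per replicate, not per sample.

## Known limitations

* The reverse scaling factor is only approximately recovered under noise;
  its conservative bias is harmless for container typing but the container
  branch should not be read quantitatively.
* The out-of-calibration limits assume query replicates are processed like
  calibration replicates; a cohort acquired with a very different
  accumulation scheme would need recalibrated limits.
* Deflation relies on the bundled container references; an unanticipated
  Raman-rich container material would leak into the fluid branch and most
  likely surface as a refused (OUT_OF_SET) sample.
* With k = 4 and very small calibration sets (fewer than ~4 replicates per
  class), neighbor votes necessarily cross class boundaries; the pipeline
  warns but does not stop.
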