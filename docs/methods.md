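# Methods

## Problem and model

Structural MRI separates cortex from white matter through myelin-dependent
contrast (T1w: cortex dark, WM bright; T2-FLAIR: the opposite).  In
malformations of cortical development (MCD) — periventricular and
subcortical heterotopia (PH, SH), focal cortical dysplasia (FCD),
polymicrogyria (PMG) — myelin content is unreliable, so lesions that look
uniformly cortex-like on structural images may in fact contain
axon-rich, white-matter-like tissue.  Diffusion MRI is sensitive to axons,
but the conventional fractional anisotropy (FA) confounds microscopic
anisotropy with orientation coherence: dispersed or crossing axons lower FA
without any change in the underlying microstructure.

Tensor-valued diffusion encoding resolves the confound.  Each measurement
is described by a b-tensor **B** (ms/μm²): *linear* encoding, **B** =
b·**nn**ᵀ, is the conventional single-direction case; *spherical* encoding,
**B** = (b/3)·**I**, weights diffusion isotropically.  Modeling each voxel
as a distribution of Gaussian diffusion tensors, the q-space trajectory
imaging (QTI) cumulant expansion of the powder signal is

    log s(B) = log S0 − B:⟨D⟩ + ½ (B⊗B)::C ,

with ⟨D⟩ the mean tensor (μm²/ms) and **C** the fourth-order tensor
covariance (μm⁴/ms²).  From the fitted moments (second moment
M = C + ⟨D⟩⊗⟨D⟩):

- MD = tr⟨D⟩/3
- V_I = C::E_bulk (variance of component mean diffusivities),
  E_bulk = (1/9)·I⊗I
- ⟨V_λ⟩ = M::E_shear (mean eigenvalue variance of the components),
  E_shear = (1/3)·I₄sym − E_bulk
- MK_I = 3·V_I/MD², **MK_A = (6/5)·⟨V_λ⟩/MD²**, MK_T = MK_I + MK_A
- FA = √( (3/2)·V_λ(⟨D⟩) / (V_λ(⟨D⟩) + MD²) ), and optionally
  μFA = √( (3/2)·⟨V_λ⟩ / (⟨V_λ⟩ + M::E_bulk) )

MK_A measures anisotropy of the microscopic environments regardless of
their orientation coherence.  For mixtures of identical axisymmetric
components, MK_A is invariant under orientation dispersion while FA falls
from 1 (coherent sticks) through √½ (90° crossing) toward 0 (uniform) —
the property the analysis and its tests are built around.

All tensor algebra uses a scaled Voigt convention
([xx, yy, zz, √2·yz, √2·xz, √2·xy], and the analogous 21-component mapping
for symmetric 6×6 matrices) so that every double contraction is a plain dot
product and results are bit-reproducible.

## Identifiability with two encoding shapes

With only linear and spherical b-tensors, the design matrix of the
28-parameter regression has rank 23, not 28: B⊗B of a rank-1 tensor is
totally symmetric (a 15-dimensional family) and spherical encoding adds a
single isotropic functional (I⊗I), so only 16 of the 21 covariance
components are constrained.  This is intrinsic to the two-shape
acquisition, not a protocol defect.  The fit therefore takes the
minimum-norm (pseudoinverse) solution.  Both E_bulk and the isotropic
fourth-order trace lie inside the identifiable row space — verified
numerically in the test suite — so MD, FA, V_I, ⟨V_λ⟩ and all kurtosis
metrics are *exactly* identifiable; on noiseless model data they are
recovered to better than 1e−8.  Only the unreportable mixed-symmetry part
of **C** is unconstrained.  Parameter vectors with orientationally
isotropic covariance (powder ensembles) lie entirely in the identifiable
subspace and round-trip in full.

## Estimator

The regression runs on log signals.  Log-transformed magnitude data are
heteroscedastic (variance ∝ 1/s²), so measurements are weighted by the
squared model-predicted signal: an ordinary least-squares pass followed by
four reweighting iterations (truncated iteratively reweighted least
squares).  Four iterations were chosen because the estimator's Rician-noise
bias in MK_A plateaus there; a single reweighted pass leaves roughly twice
the plateau bias, and unlimited iteration does not converge pointwise for
occasional ill-conditioned voxels, which would break determinism.  No
positivity constraints are imposed on ⟨D⟩ or **C**; raw estimates are kept
and maps may be clamped for display only.  Nonpositive signals are dropped
per voxel; a voxel is invalid when fewer than 28 usable measurements
remain, when dropping measurements reduces the design rank below the
protocol's intrinsic rank, or when the weighted design's condition number
exceeds 1e8.  Voxels with MD ≤ 0 are marked undefined and excluded
downstream.

Remaining noise bias: at SNR 30 (b=0), the median MK_A of a coherent
white-matter voxel is biased upward by the Rician noise floor at high
b-values; the acceptance script measures this bias (≈ +0.13–0.16 at the
default protocol).  Concomitant-gradient effects — a separate source of
positive MK_A bias in real spherical-encoding acquisitions — are out of
scope here.

## Acquisition protocol

The study acquisition is specified only as linear plus spherical encoding
with b up to 2.0 ms/μm²; the exact shell table is not public.  The package
default is therefore a config-exposed choice: b ∈ {0.1, 0.7, 1.4, 2.0}
ms/μm² with {6, 6, 10, 16} linear directions and {3, 3, 6, 6} spherical
repeats plus two b=0 volumes — 58 volumes, full two-shape identifiable
rank.  Linear directions come from a seeded electrostatic-repulsion
optimization on the projective sphere (antipodally symmetric, deterministic
given the seed).

## Digital phantom

The phantom stands in for the 7 T patient data, emulating *aligned*
multi-contrast volumes on a 32×32×16 grid with 2×2×4 mm voxels: an
ellipsoidal brain with a two-voxel cortical shell, interior white matter
(with an anterior crossing-fiber strip), two deep-gray nuclei, ventricular
CSF, and procedural lesions of the four MCD types (PH nodule on the
ventricular border, SH blob in deep WM, FCD patch straddling the gray-white
boundary, PMG ribbon along the shell).

Each voxel carries a discrete Gaussian-tensor mixture.  Defaults (explicit
config values, not published tissue parameters): WM components 2.2/0.2
μm²/ms (coherent, or 90°-crossing in the strip); cortex 1.2/0.7 and deep
gray 1.3/0.75 with uniform dispersion over six icosahedral directions
(mean tensor exactly isotropic); CSF isotropic 3.0 μm²/ms.  These give the
expected contrast ordering: MK_A ≈ 1.42 in WM against ≈ 0.09 in cortex, FA
high only in coherent WM.

Lesion voxels always take cortex-level structural intensity (misplaced
cortical tissue), while a designed fraction f* of them — exactly
round(f*·n), chosen deepest-first by distance below the cortical surface —
takes the coherent WM tensor distribution.  The depth rule encodes where
white-matter-like microstructure is expected (deep parts of SH, gray-white
boundary of FCD) and makes the WM-like region spatially contiguous, as in
real lesions, rather than salt-and-pepper.  The default phantom carries one
lesion of each type with f* = 0 (PH), 0.40 (SH), 0.30 (FCD), 0.50 (PMG).

Signals are the exact multi-Gaussian attenuations (not the cumulant form),
so fitting them exposes genuine cumulant-truncation bias; the bias shrinks
monotonically as b_max decreases, which the suite checks.  Rician noise is
the magnitude of (s+ε₁, ε₂), ε ~ N(0, S0/SNR), SNR 30 by default; a
Gaussian/noiseless path exists for analytic checks.  Pseudo-T1w and
pseudo-FLAIR are per-label means, monotone respectively increasing and
decreasing in a myelin surrogate across parenchyma (CSF dark in both,
fluid attenuation), with Gaussian noise (SD 0.03).  Everything is
reproducible bit-exactly from (spec, seed).

What the phantom does *not* emulate: realistic anatomy and partial-volume
chains, EPI distortion, coil artifacts, concomitant-gradient bias,
T2-relaxation compartment effects, time-dependent diffusion.  Passing
tests therefore demonstrate the correctness of the estimator and the
classification procedure under controlled conditions, not clinical
performance; the patient-data AUC and WM% values are explicitly not
reproduction targets.

## Preprocessing

Volumes are smoothed per axis with σ = 0.42 × the voxel dimension
(i.e. 0.42 voxels on the grid).  The kernel is the *discrete Gaussian*
T(n, t) = e^(−t)·I_n(t), t = σ²: at such small widths a sampled-and-
truncated continuous Gaussian badly violates the semigroup property
(smoothing twice with σ vs once with σ√2 disagrees at the 1e−1 level),
whereas the discrete Gaussian satisfies it exactly on the grid and has
exactly variance σ² per axis.  Boundaries use nearest replication to avoid
rim darkening inside brain masks.  ROI voxels with CSF contamination are
removed by a mean-diffusivity threshold (default 1.5 μm²/ms, configurable)
— the study identified such voxels visually, so any automatic rule is a
stand-in; MD separates free water from parenchyma robustly on the phantom.
A manual integer 3-D shift is available as an explicit option and is never
applied automatically.

## Classification

Intensities are extracted per ROI after CSF exclusion.  T1w samples are
normalized by the mean of the adjacent normal-white-matter ROI, FLAIR
samples by a homogeneous deep-WM reference region (anterior corona radiata
stand-in); FA and MK_A are dimensionless and pass through.  Per contrast,
per-ROI histograms on common bin edges (pooled 1st–99th percentile, 64 bins
by default) are averaged with equal ROI weight — ROIs, not voxels, are the
sampling unit.  The ROC sweeps the bin edges with white matter as the
positive class; polarity is resolved automatically so AUC ≥ 0.5 (WM-high
for T1w/FA/MK_A, WM-low for FLAIR).  The operating point maximizes
Youden's J (the optimality rule behind the thresholds is not stated in the
source analysis; Youden is the standard, reproducible choice), and the AUC
is the trapezoidal area.  A lesion voxel is white-matter-like iff it lies
strictly on the WM side of the threshold (ties → cortex-like, a fixed
conservative convention).  One global threshold per contrast is used for
all lesions.  The report lists per-lesion voxel counts and WM% per
contrast, with per-type mean (SD) rows recomputed from the lesion rows;
percentages are kept at full precision internally and rounded to integers
only for display.

## Problem sizes and numerical conventions

Default analyses run a 32×32×16 phantom (~9500 brain voxels) with the
58-volume protocol; the Monte-Carlo noise checks use 500 repetitions; these
sizes make every check cheap while leaving the estimators' asymptotics
visible.  Computation is float64 throughout with float32 on disk; all
coordinates are 0-based voxel indices and physical space enters only
through the NIfTI affine.  Each stage is deterministic given its config and
seed, and the run manifest records both.

## Known limitations

- The mixed-symmetry part of **C** is unobservable by design of the
  two-shape acquisition; only moment functionals of the identifiable
  subspace should be interpreted.
- MK_A carries a positive Rician-noise bias at SNR 30 and a
  cumulant-truncation bias on strongly dispersed tissue at b_max = 2.0;
  both are measured by the suite rather than corrected.
- The ROC operates on binned averaged distributions; its threshold is
  resolved only to bin resolution.
- Phantom geometry is deliberately coarse (no atlas dependency); lesion
  morphologies are schematic.
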