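# Methods

This note documents the models, numerical choices and synthetic-data design
behind `indentmap`, and what the green test suite does and does not
establish.

## Thin-layer elastic indentation

**Model.** The instantaneous (rapid-loading) response of articular cartilage
is treated as that of a homogeneous, isotropic, incompressible (ν = 0.5)
elastic layer of thickness h perfectly bonded to rigid subchondral bone,
indented by a frictionless rigid sphere of radius R. For contact radius
a = √(R ω₀) (Hertzian convention; paraboloidal tip approximation, valid for
ω₀ ≪ R) the load is

    P = 2 a ω₀ κ(a/h, ν) E / (1 − ν²).

The instantaneous modulus E is obtained by evaluating the measured force at
ω₀ = 0.2 h on the loading ramp (linear interpolation on a dense ramp) and
inverting this relation. 20 % strain keeps the response in the regime where
linear elasticity and flow-independence are defensible for a ~1 s ramp.

**Correction factor.** κ(a/h, ν) is defined by the mixed boundary-value
problem of the bonded layer. Per Hankel mode the layer's surface normal
compliance is the half-space value times

    w(x) = (2k₀ sinh 2x − 4x) / (2k₀ cosh 2x + 1 + k₀² + 4x²),
    x = λh,  k₀ = 3 − 4ν,

which we re-derived and verify in the tests against an independent
Love-stress-function boundary-value solution (machine precision for
ν ∈ [0.3, 0.5]). The contact problem is solved by discretising the contact
circle into N = 120 concentric rings of piecewise-constant pressure with
edge-clustered boundaries (s_j = sin(πj/2N)); the half-space part of each
ring's influence uses the closed-form uniform-disk solution (complete
elliptic integrals), and the finite-thickness part adds a Hankel integral
weighted by w(λh) − 1, evaluated by composite 12-point Gauss–Legendre panels
to λ_max = 25/h (the weight decays like e^{−2λh}). Convergence: relative
changes < 7 × 10⁻⁵ from N = 80 to 160 over a/h ≤ 4; the Hertz limit 2/3 is
recovered to 2 × 10⁻⁶.

The default κ path interpolates a packaged table (64 aspect nodes, geometric
in [0.01, 4.5]; ν ∈ {0.300, 0.325, …, 0.500}), linear in log(aspect) and in
ν on a log(κ) scale; below the smallest node κ blends linearly to the exact
limit 2/3 at aspect 0, above the largest an extrapolation error is raised.
Interpolation error vs the solver is < 0.1 % at ν = 0.5 and < 1 % at
off-node ν. The table is generated by the package's own solver (the
published table of the classical formulation was not obtainable offline) and
is labelled synthetic; independence of the check chain comes from the
boundary-value kernel oracle, the Hertz limit and monotonicity/asymptotic
tests, not from the table.

**Ramp-fit RMSE.** Pointwise apparent moduli E_i are computed by inverting
the relation at every ramp sample with 0.05 h ≤ ω ≤ 0.2 h (≥ 5 points
required); the RMSE of E_i about the fitted E, in MPa, reports model
adequacy. With multiplicative force noise σ the RMSE is ≈ σE. Note that a
thickness error δh also produces a nonzero RMSE (≈ 0.1 MPa per 0.5 µm at
h = 40 µm) because the κ-profile along the ramp is evaluated at the wrong
aspect ratios — in a fitted study the RMSE is therefore dominated by
thickness uncertainty, not force noise.

An optional edge-pressure-zero contact condition (`contact_radius_hayes`)
enlarges a until the rim pressure vanishes; the default Hertzian convention
is used throughout the pipeline, and the two coincide in the half-space
limit.

## Surface orientation

At each site four contact heights (front/back/left/right, ±0.075 mm) define
two chords whose normalised cross product (oriented +z) is the surface
normal; θ = arccos(n_z). Sites with θ ≥ 60° are invalid and excluded (the
manufacturer-recommended reliability limit). The centre height is not used
for orientation. For analytic planes the recovered angle is exact to 1e-6°
and azimuth-invariant. The packaged grid layout (two anterior→posterior
columns per condyle, 0.15 mm pitch; anterior/posterior split L1–L7/L8–L14,
M1–M8/M9–M17) is a declared configuration default: the source schematic is
not dimensioned, and downstream analysis consumes only labels and angles.

## Curve QC and features

A record is *atypical* when any of: > 10 % of ramp force increments are
negative; any ramp drawdown exceeds 20 % of the running peak; the peak
occurs later than 0.5 s after ramp end; or ramp SNR (peak over a
second-difference noise estimate) is below 5. These thresholds are package
defaults, config-exposed — the source study reports only the *count* of
atypical curves, not a criterion. Peak force is the maximum over the ramp
plus 1 s of hold (tolerates sampling jitter at the ramp/hold junction);
equilibrium force is the mean over the final 10 s of the hold.

## Needle-probe thickness

Surface: first position where force exceeds baseline mean + 5 SD (first
~50 samples) and stays above for 10 samples, with sub-sample interpolation
of the crossing. Interface: first position past the surface where the
Savitzky–Golay-smoothed loading rate (window 21 samples, order 2, times the
insertion speed) exceeds 0.25 N/s and remains above it until the 0.5 N stop
force, again interpolated; when no such crossing exists, the fallback is the
maximum of the smoothed second derivative of F(z) — the programmatic
analogue of the study's manual correction. Records that never reach the
stop force are failures (the stop criterion is part of the measurement's
definition). Thickness = (z₂ − z₁)·cos θ with the indentation-mapping angle;
insertion speed defaults to 100 µm/s (not stated in the source; it only
enters through the N/s conversion).

## Volumetric thickness

Segmentation is by threshold (Otsu default, fixed optional) with removal of
26-connected components under 100 voxels and optional morphological closing
(the stand-in for manual mask correction at needle-track voids). Condyles
are split by 26-connected labelling, keeping the two largest components
ordered along the mediolateral axis. Local thickness follows the
maximal-inscribed-sphere definition: LT(p) = 2·max{DT(q) : |p−q| ≤ DT(q)}
with DT the Euclidean distance transform. It is computed *exactly* — one
EDT per distinct DT value, largest radii first — rather than via a ridge
approximation; slab and ball phantoms are exact to a voxel, a 30°-rotated
slab agrees within a voxel. The mean is voxel-weighted over the map (the
assumption about the source's "mean thickness" statistic). Site statistics
intersect the mask with a 75 µm sphere at each landmark and average the
disk's thickness map; with a 4.39 µm voxel the disk comfortably contains
the maximal spheres of 30–90 µm cartilage.

## Statistics

Site CV = 100·SD/mean of ≥ 2 repeats (sample SD); intra-assay CV is the
unweighted mean of non-missing site CVs. ICC(A,1) (two-way, absolute
agreement, single measurement) from the ANOVA decomposition with
McGraw–Wong exact F confidence limits; incomplete rows dropped listwise;
cross-checked against pingouin. Bland–Altman bias ± 1.96 SD limits,
oriented XRM − NP. Pooling averages available sites per specimen per region
(missing excluded, never imputed), then summarises specimen means; group
contrasts are Welch t / one-way ANOVA (parametric path) or Mann–Whitney U
(genotype contrasts), with Bonferroni correction over the fixed family of
pairwise regional contrasts. Normality screening is deliberately out of
scope; the parametric/non-parametric choice is a config switch.

## Synthetic studies

The generator emulates the study's stated world: 31 sites × (10 control +
6 knockout) specimens × 3 repeats; 20 µm/1 s ramp + 90 s hold; R = 150 µm;
ν = 0.5; needle stop 0.5 N; 4.39 µm voxels. Group-level thickness and
modulus (mean ± SD at specimen level) use the printed values — control
lateral/medial 60.3 ± 6.3 / 39.8 ± 2.9 µm and 10.85 ± 1.73 / 19.52 ± 2.44
MPa; knockout 67.9 ± 3.5 / 56.3 ± 3.7 µm and 8.73 ± 2.39 / 8.67 ± 1.79 MPa —
plus within-specimen site scatter (7/3 µm lateral/medial; 12 % relative for
E, from the printed per-site ranges). Thickness is clipped to [28, 95] µm so
that 20 % strain stays on the 20 µm ramp. Surface angles are uniform in
[5°, 40°] with random azimuth, realised as four-point patches so the
geometry module is exercised end to end.

Indentation force noise is decomposed into a per-repeat multiplicative
scale (σ = 4.7 %, the printed intra-assay CV — repositioning scatter) and
per-sample instrument noise (σ = 0.1 %, calibrated to the printed ~0.017 MPa
ramp-fit RMSE scale). A single per-sample σ of 4.7 % would flag every ramp
as non-monotone, contradicting the printed 2.26 % atypical rate. Atypical
curves (pure noise records) and truncated needle records are injected at
the printed 2.26 % and 2.58 % rates. The relaxation hold uses a Prony
reduced-relaxation g(t) = 0.3 + 0.4 e^{−t/1s} + 0.3 e^{−t/10s} — a plausible
shape generator only; no viscoelastic model is fitted anywhere. Needle
curves rise at 0.10 N/s in cartilage and 0.40 N/s in bone (logistic slope
transition, width 2 µm), placing the 0.25 N/s interface criterion at the
transition midpoint — the calibration such a threshold presumes; baseline
noise 0.2 mN (post-smoothing effective noise, well under the load cell's
3.5 mN raw resolution). Condyle phantoms are half-cylindrical shells
(bone radius 180 µm) with site-anchored thickness fields, two-material
intensities (20/120) and Gaussian noise.

What the generator does **not** emulate: depth-dependent tissue anisotropy
and poroviscoelastic flow, needle cutting/friction mechanics, scanner
partial-volume and beam-hardening artifacts, tissue swelling after needle
damage, and anatomical curvature beyond the cylindrical shell. A green
end-to-end test therefore establishes the correctness of the *analysis*
under the model's assumptions, not the realism of murine cartilage itself.

## Known limitations

- The per-site CV transcription of the packaged peak-force table averages
  to 4.21 %, while the source's printed intra-assay summary is 4.7 %; no
  estimator of the printed table reproduces 4.7 (see `check-tables`). The
  printed summary was presumably computed on unrounded raw triplicates that
  were not deposited.
- MHA volumes are unsupported (no SimpleITK in the environment); TIFF
  stacks and NIfTI are.
- The exact thickness transform is O(#distinct radii) EDTs; for volumes far
  larger than the packaged phantoms a ridge-based approximation would be
  preferable.
- The Hertzian contact-radius convention is asserted, not derived from the
  source, which does not state its convention; the edge-pressure-zero
  alternative is provided and coincides in the half-space limit.
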