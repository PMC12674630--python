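# Methods

`optiwrist` implements a complete synthetic counterpart of a multimodal
optical digital-wrist workflow: statistical construction of a canonical
labeled wrist mesh, region-based time-domain diffuse optical tomography
(TD-DOT) with the generalized pulse spectrum technique (GPST), and
spatial-frequency-domain imaging (SFDI) lookup-table quantification of the
superficial layer.  This note records the models, the defaults and why they
were chosen, and what the synthetic studies do and do not demonstrate.

## Geometry and the synthetic digital wrist

The canonical domain is a cylinder of radius 27 mm and height 60 mm, z along
the wrist axis with z = 0 at the distal face, all lengths in mm.  Meshes are
structured: a unit-disk point layout with ring-proportional azimuthal counts
is triangulated (2-D Delaunay) and extruded into triangular prisms, each
split into three conforming tetrahedra by the minimum-global-index diagonal
rule.  This gives reproducible node counts (within ±15% of a requested
target), near-isotropic elements, and no dependence on an external mesher;
everything downstream consumes only `(nodes, tets, labels)`.  Truncated
cones reuse the same lattice with a z-linear ring radius.

The synthetic wrist labels five tissues — muscle (1), bone (2), vessel (3),
lipid (4), skin (5).  Defaults: two large forearm-bone tubes; four straight
z-parallel vessels, two arterial analogues at mid depth (radius ≈ 1.3–1.4 mm)
and two large subcutaneous vein analogues (radius ≈ 2.0–2.2 mm) sitting just
under the lipid band, reflecting that the named superficial wrist veins are
the dominant, consistently oriented vascular structures; a ~3 mm lipid band;
a fixed 1.5 mm skin shell.  Inter-individual variation is emulated by a
fractional jitter (default 10%) on structure radii, centre positions and
lipid thickness, plus ±8% global size jitter.  Because vessels are thinner
than the default node spacing (~3 mm at 6,000 nodes), each vessel also
labels the mesh node nearest to every axis sample, so vessels always keep a
connected node chain (the same nearest-structure assignment a coarse
segmentation produces).

What the generator does **not** emulate: real cross-sectional ellipticity
(aspect ratio up to ~1.27 at the styloid level), tissue-proportion
variability across body types (counts here vary only through geometric
jitter, so the count-based template error metric is much smaller than
in-vivo values), tendons/nerves, and curved vessel courses (a sinusoidal
wobble is available per tube but defaults to zero, matching the observation
that wrist vessels keep consistent directional orientations).

## Template construction and personalized scaling

Subjects are normalised onto the canonical cylinder by per-node radial
factors `R_cy / R_surface(ray)` — the surface radius along a node's radial
ray, using the nearest intersected lateral-facet centroid as control point —
and the axial factor `H_cy / H`.  Labels transfer to the fixed canonical
node set by minimum-distance registration (ties to the lower donor index).
Consensus: per-node majority vote for muscle/bone/lipid (ties to the class
with the larger cohort-wide count, then the lower index); vessels use
coordinate averaging — the subject whose vessel centroid is nearest the
cohort mean donates its vascular morphology, volume-adjusted at the tube
extremities until it matches the cohort-mean vessel volume within one nodal
volume share.  The superficial 1.5 mm is then relabeled skin.

Deployment inverts the normalisation: uniform in-plane factor `R_T0/R_cy`
(cylinder) or a z-linear factor interpolating `R_T1 → R_T2` (truncated
cone), axial factor `H_T/H_cy`.  Scaling factors are always
target-dimension / source-dimension applied to source coordinates, which
makes canonicalisation and personalized scaling exact inverses; the
printed form of the normalisation ratio reads the other way around but is
used here in the normalising direction, since the personalized-scaling
equations fix the convention.

## Diffusion forward model

Light transport uses the diffusion approximation,
`-div(kappa grad Phi) + (mu_a + p/c) Phi = q`, `kappa = 1/[3(mu_a+mu_s')]`
(absorption included in kappa; switchable), Robin boundary
`Phi + 2 A kappa dPhi/dn = 0` with A from the Groenhuis internal-reflection
fit at n = 1.4 (A ≈ 3.25), c = c0/n with c0 = 0.29979 mm/ps.  Galerkin FEM
on linear tets; per-region operator blocks are cached so the inversion loop
re-assembles systems as weighted sums.  Sources are isotropic points one
transport mean free path below the surface (barycentric injection into the
enclosing tet); detector readings sample the field with the detector's own
injection vector times 1/(2A).  This adjoint-consistent detector operator
was chosen over surface-node sampling because it makes source–detector
reciprocity exact to solver precision rather than approximate.

Accuracy at the default study resolution: shell-averaged fluence around an
interior source agrees with the infinite-medium Green's function to better
than 5% (radial shells 5–11 mm, 16k-node mesh), and the Laplace transform
of the time-stepped TPSF agrees with the direct Laplace-domain solve to
~0.1% (p = 0) and ~0.6% on average (p = 3e-3 ps^-1; worst short-separation
pairs ~3%, an early-time discretisation effect that largely cancels in the
reference calibration ratio).

TPSFs are generated by Crank–Nicolson stepping (default dt = 12.2 ps, the
TCSPC bin width; T_max = 5 ns) with implicit-Euler start-up half-steps to
damp the impulsive-source ringing.  The instrument response is a unit-area
Gaussian (default FWHM 250 ps, below the 300 ps instrument bound), applied
by discrete convolution.  Noise follows the signal-dependent model
`G_i -> G_i (1 + Q 10^(-SNR_i/20))`, `SNR_i = SNR_min G_i / min(G)` with
SNR_min = 20 dB, applied over time bins (the datum index is read as a time
bin; applying it to the Laplace-domain features instead is available via
`apply_snr_noise`).  Bins below 1e-9 of the dataset peak are treated as
empty so `min(G)` is a meaningful count.

## Region-based GPST inversion

Measurements are Laplace transforms of the (IRF-convolved, noisy) TPSFs at
two real factors and are calibrated against a size-matched homogeneous
reference "phantom" measured identically:
`Gamma_hat = (Gamma_tar / Gamma_ref) x Gamma_model(ref)`, which cancels the
IRF and any per-pair coupling factor exactly in the ratio.  The reference
optical properties (and the reconstruction initial guess) are the published
muscle means (mu_a = 0.0134/0.0122/0.0115 mm^-1, mu_s' =
1.3975/1.2860/1.1572 mm^-1 at 670/830/905 nm).

The inversion estimates one (mu_a, mu_s') pair per tissue region — muscle,
bone, vessel, merged lipid+skin — through the hard-prior mapping matrix
`G_{n,c}`.  Each outer iteration: forward-solve at the current properties,
assemble the region-reduced adjoint Jacobian
`J = -(1/4) sum_e <Gamma Phi>_e V_e` (mean over element nodes), solve
`J O = Gamma_model - Gamma_hat` by Kaczmarz sweeps (ART) at both factors,
and separate the updates by the exact linear-in-p algebra

    O(p)  = -dmua - (mua + p/c) dmusp / musp
    dmua  = ((mua c + p2) O(p1) - (mua c + p1) O(p2)) / (p1 - p2)
    dmusp = (O(p1) - O(p2)) musp c / (p2 - p1).

The sign of the scattering term in O follows from the region-wise
divergence identity applied to the diffusion operator (the interface flux
term is neglected — the standing approximation of the single-kernel
scheme); the absorption line is insensitive to that sign because the cross
terms cancel identically.  The derivation fixes the denominators shown
above; note that an absorption-only perturbation gives `dmua = -O` exactly.

Numerical policy: ART relaxation 0.2, 40 sweeps, deterministic row order;
outer loop up to 40 iterations with a fractional trust region per step
(50% for mu_a, 25% for the noise-amplified mu_s' channel), positivity
floors at 1e-4 mm^-1 and ceilings at 1.0 / 3.0 mm^-1; stopping on a
residual floor (1e-6 of the data norm), a relative residual change below
1e-4, or no new best residual for 12 iterations; the best-residual iterate
is returned.  A sustained residual above twice its initial value raises a
divergence error carrying the partial state.  An optional dynamic-range
cutoff can exclude pairs below a configured fraction of the strongest pair
(default off: the time-bin noise model leaves even the weakest pairs usable
at the default factors).

**Laplace factors.** The factors are free parameters of the method.  The
defaults are p1 = 0 and p2 = 3e-3 ps^-1.  The choice balances two failure
modes measured in calibration experiments: the scattering separation noise
is amplified by `musp c / (p2 - p1)` (favouring large p2), while the
p2-transform of long-separation pairs is dominated by early, low-count time
bins whose noise survives calibration (mean calibrated-data error ~0.5% at
p = 0, ~2% at 3e-3, ~8% at 6e-3).  Vessel mu_s' remains the least
identifiable parameter — a small compact region whose scattering kernel is
most affected by the neglected interface term — and its estimate leans on
the initial value; this is visible in the per-region error tables.

## Simulation study design

A consensus template is built from 8 jittered synthetic subjects; each
trial draws an independent subject (own anatomy jitter, ±8% size) and
per-tissue properties uniformly from the default ranges, generates the
target and reference datasets with the FEM time-domain forward model (IRF +
noise), calibrates, and reconstructs with either the generating anatomy
("target") or the personalized-scaled template ("cylinder"/"cone").  Skin
is tied to the lipid draw in the study generator because the reconstruction
treats lipid+skin as one compartment (and SFDI, not TD-DOT, is the method's
answer for skin); the merged-region truth is the node-count-weighted mean.

Default property ranges (830 nm, mm^-1) are *reconstructions*, anchored to
the published muscle means ±40% and literature conventions: muscle mu_a
0.0073–0.0171, mu_s' 0.77–1.80; bone 0.008–0.020 / 1.0–2.2; vessel
0.02–0.08 / 1.1–1.9; lipid 0.004–0.012 / 0.9–1.8; skin 0.010–0.025 /
1.2–2.4.  The vessel region is treated as a partial-volume compartment of a
~2 mm structure, not whole blood: at whole-blood absorption (10x the
background) the linearised region scheme demonstrably diverges regardless
of solver, so moderate contrast is both the physically sensible label for a
region value and the regime in which a region-based linearised method is
validated.  Ranges are user-overridable (`PropertyRanges`).

Because the data generator is the same diffusion FEM used in inversion
(no Monte-Carlo model mismatch), published error levels for the equivalent
studies act as upper bounds for this package's studies.  The default study
scale — 5 trials on a ~6,000-node mesh, chosen as the package's desk-scale
default — yields mean errors over 4 regions x 5 trials; individual regions
(especially vessel) fluctuate far more than the means.

An IRF-sensitivity sweep (`irf_sensitivity_study`) re-runs the study per
FWHM value and reports mean errors as an observation table.

## SFDI

A white Monte Carlo run (Henyey–Greenstein g = 0.9, mu_s = mu_s'/(1-g),
n = 1.4, semi-infinite medium, Fresnel boundary, pathlength-roulette tail
termination at 2.5 m with unbiased reweighting) records escape (radius,
pathlength) weights on a 500 x 600 (linear rho, log L) histogram.
Absorption enters afterwards as Beer–Lambert weights exp(-mu_a L), reduced
scattering by similarity rescaling of rho and L, and the spatial frequency
by the order-zero Hankel sum over bin centres — so one photon set serves
the whole published lookup grid (mu_a 0.001–0.5 step 0.001; mu_s' 0.5–1.5
step 0.01 mm^-1) at fx = 0 and 0.2 mm^-1.  Monotonicity of the table in
mu_a is exact by construction; the launch weight excludes the ~3% normal
specular reflection.  Agreement with the diffusion closed form at
(0.01, 1.0) is ~1% at fx = 0 (the 15% tolerance quoted in tests covers the
diffusion approximation itself, not MC noise).

The single-pixel chain projects orthonormal 2-D DCT patterns; the measured
scalar is the inner product of the pattern with the scene's diffuse
response at the frequency nearest the pattern's own physical x-frequency
(`kx / (2 N pitch)` cycles/mm).  Demodulation reconstructs the planar map
by inverse 2-D DCT of the full coefficient matrix and extracts the AC map
from the single column nearest the target frequency; for a homogeneous
scene the AC component image is identically zero (non-DC patterns integrate
to zero against a flat response), so quantification studies calibrate
per-frequency reflectance values directly rather than through the pattern
chain.  Both the direct-coefficient and image-reconstruction readings are
available.

Inversion restricts LUT candidates to rows whose planar reflectance lies
within the measured min/max bounds ±5% (configurable; empty set falls back
to the full grid with a warning) and minimises the two-frequency squared
distance, ties toward smaller mu_a then smaller mu_s'.  The quantification
study draws homogeneous scenes from the grid interior (mu_a 0.02–0.45,
mu_s' 0.6–1.4), simulates measurements with an *independent-seed* MC
forward, applies 1% multiplicative Gaussian measurement noise and the
reference calibration against the (0.01, 1.0) phantom, and reports mean
absolute relative errors.  The layered-phantom context is represented as
homogeneous inversion of the top layer; layered MC is out of scope.

## Known limitations

- Vessel mu_s' is weakly identifiable by design of the single-kernel GPST
  scheme; its errors dominate the scatter of the mean error tables.
- The count-based template error metric is nearly blind to positional
  mismatch; reconstruction accuracy with the template prior is governed by
  vessel-position mismatch near the probes, which the count metric does not
  see.
- The published in-vivo, phantom-hardware and template-vs-MRI error figures
  require the original cohort and instruments and are not reproduced here;
  the simulation studies are their synthetic analogues only.
- The diffusion approximation is least valid in the low-scattering lipid
  band and at sub-mfp' source-detector geometry; SFDI (Monte Carlo based)
  covers the superficial layer for that reason.
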