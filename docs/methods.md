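# Methods

`pttsim` simulates nanoparticle-assisted photothermal therapy of a
superficial skin tumor: a near-infrared laser irradiates a four-layer
skin stack containing a gold-nanorod (GNR) loaded cylindrical tumor;
light transport determines where energy is absorbed, heat diffusion
determines the temperature history, and dose metrics score how well a
pulsed heating/cooling schedule keeps the tumor in the apoptosis window
while sparing the surrounding tissue.

## Optical model

Tissue optics are characterized by the absorption coefficient mu_a, the
scattering coefficient mu_s (both mm^-1) and the Henyey–Greenstein
anisotropy g. GNR loading adds

    mu_np = 0.75 f_v Q / r_eff,

linear in the volume fraction f_v, where r_eff is the radius of the
sphere with one rod's volume (a 67 x 10 nm cylinder gives
r_eff = 10.79 nm) and Q a dimensionless efficiency. Mixed-tissue
coefficients are host + nanoparticle sums; the mixture keeps the host
anisotropy, since the additive model carries no phase-function
information for the rods.

The efficiencies Qa, Qs for a given rod geometry normally come from
electromagnetic solvers (DDA/Mie), which are out of scope. Instead the
default configuration *calibrates* them from one known mixed-tissue
column (f_v = 1e-3: mu_a = 118.419, mu_s = 6.101 mm^-1) against the
bare-tumor baselines (0.08, 1.28 mm^-1); the backed-out values
(Qa ≈ 1.70, Qs ≈ 0.069) reproduce the entire loading table by linearity
but should not be quoted as electromagnetically computed efficiencies.

## Geometry

The skin domain is a 30 x 30 x 10 mm cuboid, z downward from the
surface: epidermis 0.08 mm, papillary dermis 0.5 mm, reticular dermis
0.6 mm, subcutaneous fat 7.82 mm, with fat extended to fill the
remaining depth (the deepest layer is the natural filler for the
unassigned margin). The tumor is a cylinder of diameter 10 mm and
length 3.5 mm, top at 0.1 mm depth, coaxial with the beam.

Voxels are uniform (default 0.25 mm for single runs, 0.5 mm for
sweeps). Layers thinner than a voxel are handled by sub-voxel blending:
a z-boundary voxel gets thickness-weighted mu_a and mu_s (preserving
the column optical depth), scattering-weighted g, volume-weighted rho
and rho*cp, and an arithmetic-mean k. The alternative — a locally
refined z grid — was rejected because the explicit heat solver's stable
step shrinks with the square of the smallest spacing, inflating run
time roughly 40-fold for a sub-voxel-accurate epidermis of marginal
thermal consequence.

The normal-tissue region of interest for hazard scoring is the
Euclidean shell of non-tumor voxels within half a tumor diameter (5 mm)
of the tumor surface, in *all* directions (heat conducts in all
directions, not just radially), computed by a distance transform on
voxel centers.

The validation-phantom preset is a GNR-loaded cylinder (10 mm diameter,
10 mm deep, f_v = 2e-5) in a plain acrylamide cylinder (40 mm diameter,
30 mm long; rho 1070 kg/m^3, cp 3810 J/kg K, k 0.56 W/m K), initial
temperature 20 °C. Its host *optical* properties are an assumption
(water-dominated gel at 1064 nm: mu_a 0.012 mm^-1, mu_s 0.1 mm^-1,
g 0.9) — the thermal properties are established, the optical ones are
not, so phantom simulations are structural rather than quantitative.

## Photon transport

Standard voxelized Monte Carlo with hop–drop–spin: path lengths
S = -ln(xi)/mu_tot, weight deposition dW = W mu_a/mu_tot per
interaction, Henyey–Greenstein deflection sampling (the isotropic g = 0
branch is 2 xi - 1), azimuth uniform on [0, 2 pi). Direction updates
use the standard spherical scattering rotation with the usual |mu_z| ≈ 1
pole special case; this is the unique form that preserves unit norm and
the sampled deflection cosine (some printed variants of these update
formulas contain sign/index typos — the rotation here is verified
against an independent orthonormal-frame construction in the tests).

Heterogeneous media consume a single sampled optical depth -ln(xi)
across voxels scaled by the local mu_tot, interacting where it is
exhausted — unbiased, and equivalent to per-material exponential steps.
Interfaces are index-matched (no Fresnel reflection/refraction;
refractive indices are not part of the configuration). Photons leaving
any face (or entering an inactive voxel) are tallied as escaped.
Russian roulette terminates weights below 1e-4 with survival
probability 0.1 (survivors boosted 10x), keeping termination unbiased.

The beam is a top-hat disc (default 10 mm, matching the tumor
diameter) at normal incidence, centered on the tumor axis. The kernel
runs a single sequential seeded random stream: identical seeds give
bit-identical absorption grids.

## Heat solver

Plain heat diffusion with a volumetric source,
rho cp dT/dt = q + div(k grad T); blood perfusion and metabolic heat
are deliberately absent from the model. The explicit seven-point
stencil uses harmonic-mean face conductivities 2 k k_n/(k + k_n), which
make the discrete two-material steady flux exact. The time step is the
per-voxel stability bound times a 0.5 safety factor; for treatment runs
it is additionally rounded down to divide the snapshot interval so
snapshots and (integer-second) phase switches land on step boundaries.

The source is q = P_l x (deposited fraction per voxel)/voxel volume,
so its volume integral equals the laser power times the absorbed
fraction; it switches on/off with the heating/cooling cycle
(tau_h on, tau_c off, repeating; the total treatment time tau_tot
includes cooling phases and truncates the last cycle). Boundaries are
adiabatic by default — the conservative closure, testable by exact
energy conservation; fixed-temperature far faces and a convective top
surface (h, T_amb) are available options. Initial temperature is 37 °C
for skin and 20 °C for the phantom. Internally the solver works in SI.

## Dose metrics

At each snapshot: theta_A is the tumor volume fraction strictly inside
the apoptosis window 43 < T < 50 °C; theta_H,n is the hazard-weighted
mean over the normal-tissue ROI, with left-closed temperature bands
weighted 1 (≤ 43 °C, no damage) through 8 (above 300 °C). Exactly
43 °C is hazard weight 2 but *not* apoptotic (the window is open);
exactly 300 °C falls in the top band. Time averages (the starred
retention values) use the trapezoidal rule on snapshots (default 1 s
interval; 2 s in sweeps — the metrics are smooth enough that refining
from 1 s to 0.5 s moves the average by < 1e-3). The objective is
theta_A,eff* = theta_A*/theta_H,n*, an exact quotient. Volumes are
voxel counts times voxel volume; partial-voxel effects are ignored.

## Sweeps

The planning grid crosses tau_tot (120–960 s step 120), laser power
(0–2000 mW step 50), f_v (1e-3–1e-6 decades) and symmetric
heating/cooling times (15, 20, 30, 60 s). Two exact linearities reduce
the cost: the absorption grid depends only on f_v (one Monte Carlo run
per loading), and the temperature rise is proportional to power (one
unit-power heat run per f_v x cycle-time; per-power fields are
rescaled rises). Shorter treatment times are evaluated as prefixes of
the longest run with the same cycle structure. The per-treatment-time
optimum maximizes theta_A,eff*, ties broken by lower power then shorter
heating time.

Default sweep resolution is desk-scale — 0.5 mm voxels, 1e5 photons,
2 s snapshots — chosen so a reduced grid runs in seconds and the full
grid in minutes. Absolute starred values shift a few percent with grid
resolution and photon count (which is why optimum *conditions* and
monotone trends, not fourth-decimal objective values, are the
reproducible quantities); the trends — optimal power decreasing with
treatment time, hazard increasing with power, lowest hazard at the
lowest loading — are stable.

## What the synthetic setups do and do not show

All inputs are generated programmatically from printed tissue and
design parameters; there are no measured data in the package. Passing
tests therefore demonstrate correctness of the transport, conduction
and scoring machinery under the stated model assumptions — homogeneous
layers, uniform GNR distribution, constant properties, no perfusion, no
refractive-index mismatch, rigid cylindrical tumor — not fidelity to
any particular patient or bench measurement. The RMSE operation exists
to compare simulated probe traces against user-supplied thermocouple
measurements; no such traces ship with the package.

## Numerical notes

- Monte Carlo voxel traversal snaps the crossing coordinate to the face
  it crosses, preventing floating-point drift of the voxel index.
- A photon whose weight reaches exactly zero (pure absorber) is killed
  immediately rather than left to roulette.
- The stability bound is refused, not silently clamped, when a caller
  supplies an overlong step.
- Dose metrics on sweep-rescaled fields use float32 snapshot storage;
  band-threshold flips from the rescaling round-off are possible in
  principle but below the metric quantization (one voxel in ~2e3).
- Efficiency calibration raises on a mixed coefficient below the host
  baseline (negative efficiency) and on f_v = 0.
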