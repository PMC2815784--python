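# Methods

`interbeam` models the dosimetry of interlaced microbeam radiosurgery: arrays
of ~50 µm-wide planar kilovoltage X-ray beams, delivered from several ports
with sub-spacing lateral shifts so the beams tile the inter-beam gaps only
inside a small deep-seated target. This note records the models, the
numerical choices, and what the synthetic tests do and do not demonstrate.

## Source spectrum

The wiggler emission is modelled with the universal synchrotron spectrum:
photon number density n(E) ∝ G1(E/E_c) with G1(y) = ∫_y^∞ K_{5/3}(x) dx,
parameterized by a single critical energy E_c. The beamline filter stack
(Be 0.5 mm, C 1.5 mm, Al 1.5 mm, Cu 1.0 mm) multiplies each bin by
exp(−Σ µ_i(E) t_i); the transported band is truncated (not tapered) to
[50, 350] keV. E_c is then calibrated by bisection so the filtered median is
107.0 ± 0.05 keV (the calibration lands at E_c ≈ 70 keV). Only the band and
the median are experimentally constrained; the spectral *shape* between them
is a one-parameter model, and every result that depends on the full shape
(most visibly the far scatter tail) inherits that uncertainty.

Energies are sampled by inverse transform of the cumulative bin weights with
linear interpolation inside bins, from a seeded `numpy` generator.

## Interaction data

Mass attenuation coefficients for Be, C, Al, Cu and water are embedded on a
fixed 10–1000 keV grid (NIST-style compilation values) with log–log
interpolation. Partial water cross-sections are constructed
self-consistently rather than embedded separately:

* incoherent (Compton): exact integrated Klein–Nishina per free electron ×
  electron density (binding corrections are <1 % above 50 keV and are not
  modelled — see Limitations);
* coherent (Rayleigh): a power law anchored at 30 keV
  (0.035 cm²/g × (E/30 keV)^−1.75), adequate for the few-percent branching
  fraction it represents;
* photoelectric: total − incoherent − coherent, clamped at zero; below the
  10 keV table knot it is extrapolated as E⁻³.

Electron collision stopping power is evaluated from the Berger–Seltzer
(Bethe) formula with I = 75 eV for water (the density-effect correction is
negligible below 1 MeV); it reproduces the public compilation within ~1–2 %
at 10–300 keV. CSDA ranges follow by numerical integration from the 1 keV
cutoff.

## Monte Carlo transport

A single rectangular top-hat microbeam (default 50 µm × 2 mm) enters the flat
top face of a water cylinder (rat head: r = 1.5 cm, h = 3 cm; human head:
r = 8 cm, h = 16 cm) parallel to its axis; beams are perfectly parallel (the
synchrotron divergence is negligible on these scales). Transport is analogue:
exponential free paths from the total attenuation coefficient, interaction
type proportional to the partial cross-sections, Klein–Nishina sampling of
the Compton energy/angle by the standard composition-rejection method, and a
1 keV cutoff for both photons and electrons (residuals deposited locally).

Secondary electrons are emitted along their *kinematic* direction: for
Compton events the direction follows from momentum conservation between the
incident and scattered photon; photoelectrons (a rare channel above 50 keV)
are emitted isotropically. This matters: with isotropic emission the
high-energy Compton electrons — the only electrons with ranges beyond the
inter-beam gap — are aimed sideways instead of forward, and the valley dose
between microbeams comes out a factor ~2–3 too high.

Electron transport modes, selectable in `TransportConfig`:

* `condensed_history` (default): stepwise continuous slowing down
  (15 % fractional energy loss per step) with Gaussian multiple-scattering
  deflections per step (Highland angle, X₀ = 36.08 g/cm²). This is the mode
  that reproduces the published valley doses; multiple scattering is what
  carries electron energy laterally into the valleys.
* `kernel`: straight-line CSDA track along the kinematic direction. Cheaper
  and useful for bounding, but it under-fills the valley (no lateral
  diffusion).
* `local`: deposit at the interaction point (diagnostic).

Rayleigh scattering is enabled by default. For a 50 µm beam every coherent
deflection removes the photon from the peak, so ignoring it overestimates
the in-beam depth penetration by ~3 % at 7.5 cm. The angular model is a
forward-peaked form-factor approximation — a Rayleigh-distributed polar
angle with scale 0.07·(100 keV/E) rad (~4° median at 100 keV) — rather than
the Thomson distribution, whose ~57° mean angle would misplace the scattered
photons.

A `diagnostic_mode` replaces analogue transport with an absorb-on-first-
collision expected-value estimator (each sampled photon deposits its
analytic expected dose per depth bin along the unscattered ray). It exists
to validate the geometry and normalization chain against the closed-form
spectrum-averaged exponential depth dose, which it matches to <0.5 %.

### Scoring

Dose is scored in 2-D voxels — transverse bins of 1 µm inside and near the
beam, geometrically widened (ratio 1.07) out to the phantom radius, × 1 mm
depth bins — collapsing the beam-height axis over the central 80 % of the
slit height (translational symmetry along the slit). Doses are normalized to
the mean of the centermost 10 µm of the entrance depth row ("peak-dose
units"); absolute doses follow by multiplying with the prescribed entrance
peak dose (200 Gy per port for the rat plan, 100 Gy target for the human
planning table). Per-voxel relative uncertainties come from ≥10 independent
batches; energy bookkeeping (emitted = deposited + escaped) is exact by
construction and asserted to 0.1 %. Runs are bit-reproducible for a fixed
seed (single-threaded, per-batch seeding).

Typical problem sizes: 3 × 10⁶ – 1.2 × 10⁷ histories per kernel (a few seconds to
~1 min per phantom on one core with the numba-compiled core), which puts
~2–3 % statistical error on windowed peak estimates and ~5–10 % on composite
valley estimates at depth.

## Composition, interlacing, planning

Array profiles are exact linear superpositions of the single-beam profile
resampled onto a uniform 1 µm grid (conservative rebinning preserving the
integral). PVDR uses the centermost beam (mean over the central 10 µm) and
the centermost gap midpoint (mean over the central 20 µm); the windows
suppress Monte Carlo noise and are small against the 50 µm beam width. For
even beam counts ties break to the negative side. The 90–10 % penumbra is
measured beyond the outermost edge peak after 3 µm smoothing, with linear
interpolation between grid points and a first-crossing convention (flagged)
for non-monotone tails.

Ports are laterally shifted copies of one array at the common target depth —
all ports traverse the same water depth to the cross-firing point, so each
delivers an identical profile there regardless of incidence angle. Canonical
plans shift port p by p·(spacing/n_ports) (50 µm steps for 4 ports at
200 µm). The interlaced plateau is the contiguous central region holding
≥90 % of the plateau mean, detected on a profile smoothed over one tiling
step so the criterion sees the macroscopic profile rather than the 50 µm
tiling microstructure; heterogeneity is (max−min)/mean inside it. The
interlacement enhancement factor is Int.EF = plateau / single-array in-beam
dose − 1.

The planner inverts the chain for a prescribed target dose D_t:
D_ib = D_t/(1+Int.EF), D_valley = D_ib/PVDR, D_entrance = D_ib/A with A the
depth attenuation factor (in-beam peak at depth / entrance peak, composite
peaks when an array is given so neighbour scatter is included at both
depths). "table" rounding mode rounds the in-beam dose to integer Gy before
the valley division — the convention the published planning table follows
(88/51 = 1.73 is only reproducible that way); "exact" keeps full precision.
The printed table is not perfectly self-consistent: with exact-mode inputs
the entrance doses agree within ~1.6 %, the 8.7 Gy valley cell within 1.8 %,
and the 0.45 Gy cell within 0.01 Gy (2.2 %); the package reports both modes
rather than reconciling those cells.

## Film module

Film images are box averages of a dose map onto pixels through a monotone
dose→OD response (identity by default — no absolute film calibration is
modelled; a saturating curve is available), plus seeded additive Gaussian
noise. Profile recovery inverts the response after row averaging and masks
saturated pixels. These images are geometric verification artifacts, not
absolute dosimetry.

## Synthetic fixtures

The analytic kernel — top-hat ⊗ Gaussian core plus two-sided exponential
tails — has closed-form values and closed-form (geometric-series) array
sums, so superposition, PVDR, interlacing and the planner can be tested
exactly, independent of the Monte Carlo engine. `kernel_with_composite_pvdr`
solves the series for the tail amplitude that makes a given array's PVDR
exact. The fixture classes carry the published planning-table and rat
dosimetry constants with source strings attached. What the analytic-kernel
tests demonstrate is the correctness of the *geometry pipeline*; they say
nothing about transport physics. Conversely the Monte Carlo tests validate
the physics only within the stated tolerances and only for quantities pinned
by the published values.

## Validation snapshot

With the defaults above (seeds as in the test suite), the pipeline
reproduces: rat in-beam dose at 1 cm 173–176 Gy (published 175), composite
PVDR 56 ± 5 (≈56), valley 3.1 ± 0.3 Gy (3.1), interlaced plateau
198–213 Gy (200), plateau width ≈1.95 mm (2 mm); human depth attenuation at
7.5 cm 0.31–0.32 (0.30), Int.EF 0.16/0.23/0.43–0.51 for the
2×2 mm²/1×1 cm²/3×3 cm² fields (0.14/0.22/0.43–0.52), with the printed PVDR
ordering and the ×3 valley increase on halving the spacing reproduced.

## Known limitations

* The spectral shape beyond band and median is a model; far scatter tails
  and entrance-site PVDRs are the quantities most sensitive to it.
* Incoherent scattering functions (binding suppression of small-angle
  Compton) are not modelled; coherent scattering uses an approximate
  forward-peaked angular law. Together these make the out-of-field tail
  decay too shallow: the computed dose fraction 10 mm from the center of an
  8 mm interlaced field is ~3 % versus the published 1.5 %, and the
  interlaced-edge 90–10 % falloff — whose 10 % threshold sits within ~1
  percentage point of the out-of-field scatter shoulder — is accordingly
  unstable and larger than the published ≤50 µm (the single-array edge
  falloff, 23–29 µm, is robustly below it).
* The 1-D shifted-copy port model (shared with the published calculation)
  superposes all ports' tails outside the target, where real ports diverge;
  out-of-target doses are conservative (over-)estimates.
* Water-only, homogeneous phantoms; no bone/air, no pair production
  (band ≪ 1.022 MeV), no polarization, no dose-rate effects.
* Condensed-history steps use a fixed 15 % energy-loss fraction with
  Highland deflections — adequate for 100 µm-scale lateral spread, not a
  substitute for single-collision electron transport below ~10 µm.
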