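# Methods

## Scope and model overview

`microdosim` estimates absorbed doses delivered by the complete electron
emissions of ¹⁷⁷Lu and ¹⁶¹Tb (β⁻ spectra, conversion electrons, Auger
electrons) to spherical water targets at the cellular scale: the nucleus of
a single labelled cell, the nuclei of cells in a 19-cell simple-cubic
cluster, and whole water spheres. Everything is unit-density water; photons
are neglected (their absorbed fraction over ≤50 µm is negligible);
half-life never enters because results are normalised to a fixed energy
released per unit volume rather than to activity or time.

## Emission models (the synthetic-data generator)

Each decay emits exactly one β electron plus discrete lines.

**β spectra.** Each nuclide carries its known branch structure
(¹⁷⁷Lu: endpoints 498.3/385.3/177.0 keV with fractions 0.794/0.090/0.116 to
¹⁷⁷Hf; ¹⁶¹Tb: 593.7/518.2/460.2 keV with 0.10/0.66/0.24 to ¹⁶¹Dy) with the
allowed-transition shape p·E_tot·(Q−E)² times the non-relativistic Fermi
function F = 2πη/(1−e^(−2πη)), η = Zα/β. Because the published summary
characteristics are authoritative here, a single global endpoint scale
factor (≈0.96 for both nuclides) is solved by root finding so that the
model mean β energy equals the reference values exactly (133.3 and
154.3 keV). A single-branch "effective" variant with the endpoint fitted to
the mean is available (`single_effective_beta=True`). Branch energies are
sampled by inverse-CDF interpolation on 4096-point grids.

**CE/AE lines.** The full nuclear-data line lists are not embedded.
Instead each nuclide carries a compact effective set (4 CE + 4 AE lines)
solved in closed form so that, per component, Σ E·w, the yield-weighted
average energy and the energy span match the published decay
characteristics exactly (¹⁷⁷Lu: CE 13.52 keV/decay averaging 87 keV over
6.2–206.3 keV, AE 1.13 keV/decay averaging 1 keV; ¹⁶¹Tb: CE
39.28 keV/decay averaging 28 keV over 3.3–98.3 keV, AE 8.94 keV/decay
averaging 0.8 keV). Users with a full ICRP-107-style table can supply it as
delimited text (`kind, energy_keV, yield_per_decay`) and it supersedes the
effective set. Line counts per decay are sampled as
floor(w) + Bernoulli(w − floor(w)) — the integer count with expectation w —
so Auger cascades (w > 1) preserve the energy budget without modelling
cascade correlations.

What the generator does *not* emulate: the fine structure of the true line
spectra (dozens of lines collapse onto a few effective energies),
coincidence correlations within a decay, photons and X-rays, and shape
deviations of first-forbidden β transitions. Tests passing against this
generator therefore validate the transport/scoring chain and the energy
bookkeeping at the stated spectral summary level, not line-by-line nuclear
data fidelity.

## Geometry

The cell is a set of nested spheres: nucleus radius 5 µm, inner membrane
surface at 6.99 µm, cell radius 7 µm (volume 1436.8 µm³, nucleus
523.6 µm³). Region classification uses half-open radial shells — the
nucleus boundary belongs to the cytoplasm, the inner membrane surface to
the membrane, the outer surface to the outside — so deposits are assigned
deterministically at boundaries. The membrane counts toward cell volume but
is never a source or target. "Cell surface" sources sit on the outer 7-µm
sphere by default (options: mid-membrane or distributed through the 10-nm
shell; at transport resolution the three are indistinguishable).

The cluster places 19 cells on a simple cubic lattice with pitch one cell
diameter (14 µm, cells in contact; configurable): one central cell, 6 first
neighbours at one pitch, 12 second neighbours at pitch·√2 ≈ 19.8 µm.
Octahedral symmetry makes one representative target per neighbourhood
sufficient; an all-19-targets mode exists and is used to verify symmetry
statistically.

Positions are sampled uniformly (volume-weighted radii via the r³
transform; directions isotropic via normalised Gaussians).

## Electron transport

The reference experiment used event-by-event track structure. Re-deriving
water cross-sections is out of scope here, so transport is the
**straight-line CSDA dose point kernel**: an electron of energy E travels a
straight path of length equal to its CSDA range R(E), losing energy at the
collision stopping-power rate S(E). The cumulative radial deposition
profile is F(r, E) = 1 − E_res(r)/E with E_res(r) = R⁻¹(R(E) − r).

S(E) comes from the standard Møller/ICRU collision stopping-power formula
for liquid water (Z/A = 0.55509, I = 75 eV, no density-effect correction,
which is <1% below 1 MeV). It reproduces the reference tabulation to <1%
above 10 keV (22.56 MeV cm²/g at 10 keV) and remains positive down to
0.1 keV, the table floor; it ships as package data (240 log-spaced rows,
0.1–2000 keV, log-log interpolated) and can be replaced by a user file.
CSDA ranges are log-grid quadratures of 1/S closed below the floor with a
constant-S term (~5 nm). Electrons at or below the floor deposit locally —
their range is below every geometric scale in the problem.

**Scoring.** The expected energy deposited in a spherical target of radius
R_t whose centre is at distance ρ from the source is
∫ f_shell(ρ, r) dF(r, E), where f_shell is the closed-form fraction of a
sphere of radius r centred at ρ that lies inside the target:
(R_t² − (ρ−r)²)/(4ρr) in the partial-overlap regime. The integral is
evaluated exactly on the fully contained part (r ≤ R_t − ρ) plus a
128-point quadrature over the geometric overlap window
|ρ − R_t| < r < ρ + R_t; integrating over the window rather than over
deposit-fraction quantiles keeps thin windows resolved (a 100-keV electron
passing a 5-µm nucleus spends <5% of its F-profile inside), and 64- vs
512-point kernels agree to 0.1%. Cytoplasm-shaped (shell) targets are
differences of two ball targets.

Each sampled decay scores its *expected* deposit (the kernel integral) —
variance reduction relative to per-track binary outcomes, with the same
mean. Per-decay deposits use cached radial profiles: exact profiles per
discrete line, and a (ρ × log E) bilinear table of deposit fractions for
the continuous β energies (140 log-energy points; the ρ grid has 400 points
concentrated around the target boundary where sub-µm-range electrons
switch between full and zero deposit).

**Track mode** is retained for cross-validation: stepped straight-line
transport with step length a fraction (default 5%) of the residual range,
each step's energy loss deposited into the region containing its midpoint,
and the residual deposited locally once it falls below the cutoff (7.4 eV,
the electronic excitation threshold of water; in practice the
stopping-power table floor, reached within nm of the same point). Deposits
telescope to the initial energy exactly. Kernel and track agree within MC
error once the step fraction is below ~1%; at the default 5% the midpoint
assignment carries a percent-level boundary bias, which is why validation
tests use finer steps.

**Known limitations** (all deliberate): no angular scattering — straight
tracks overestimate penetration depth; δ-ray energy is deposited along the
primary path; no bremsstrahlung. For spherically averaged scoring with
isotropic sources the detour effects partially cancel, but a systematic
deficit remains for sources separated from the target by a few µm of
intervening medium. Measured against published track-structure doses this
implementation lands within −30%…+4% for absolute nucleus doses (worst for
cell-surface/cytoplasm sources of ¹⁶¹Tb, whose low-energy CE are most
sensitive to path structure), within a few percent for sphere doses, and
considerably closer for ¹⁶¹Tb/¹⁷⁷Lu dose *ratios* and for self-dose
fractions, which are the comparison quantities of interest.

## Dose normalisation and uncertainty

Per-decay tallies are scaled to N = ρ_E·V_cell/Ē equivalent decays
(ρ_E = 1 MeV/µm³ by default → 1436 MeV per cell; Ē is the analytic model
mean energy per decay), then converted with
1 MeV = 1.602176634 × 10⁻¹³ J over the target mass. The infinite-medium
equilibrium dose at 1 MeV/µm³ is 160.22 Gy; an intranuclear source with
forced local deposition gives the closed-form bound
(V_cell/V_nucleus) × 160.22 ≈ 439.6 Gy — both serve as analytic anchors in
the tests, the former recomputed through the full spectral/kernel chain by
deterministic radial quadrature (`equilibrium_dose`).

In cluster runs every cell releases the same normalised energy; one
template set of positions/emissions is sampled and translated to each cell
(common random numbers — unbiased for means, and it makes the cluster
self-dose reproduce the single-cell dose almost exactly). Self-dose is the
target cell's own contribution; cross-dose is everything else; they sum to
the total by construction.

Uncertainties are standard errors over 20 equal batches of decays. The
study-size runs (10⁶ decays) have relative SEMs of ~0.1%, far below the
model bias, so reported uncertainties characterise Monte Carlo noise only.

## Problem sizes and defaults

Defaults mirror the study design: 10⁶ decays per simulation, 20 batches,
1 MeV/µm³, pitch 14 µm. The sphere experiments sample 10⁵ source positions
(the 2-mm sphere is insensitive to more, since each position contributes an
expected-value deposit). Example scripts use 2×10⁵ decays, which already
gives ~0.2% statistical precision, and the validation suite uses
10⁴–10⁵-decay runs for structural checks where statistical power, not
absolute accuracy, is at stake.

## Design choices where the design was open

* Lattice pitch defaults to one cell diameter (cells in direct contact);
  any larger pitch is accepted, smaller raises an overlap error.
* Boundary tie-breaks are half-open shells (see Geometry); deterministic
  quadrature grids everywhere; randomness only in positions, β energies,
  line counts and track directions, all driven by one seeded generator per
  run — identical configs and seeds give bit-identical reports.
* The effective line sets place their yields at a small number of energies
  consistent with the published summary moments; this is the main
  unquantifiable input approximation, bounded by the acceptance tolerances.
* Enhancement factors are reported as raw ratios; table renderers round
  them to one decimal as conventionally quoted, keeping full precision in
  the JSON output.
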