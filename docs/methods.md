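# Methods

This note documents the physics models, the calibration procedure, the
numerical choices, and what the desk-scale problem sizes do and do not
establish.

## Beta-plus decay and spectra

Each isotope is described by its total beta-plus branching ratio and one or
two branches (endpoint kinetic energy, intensity, optional coincident
prompt gamma), stored in `src/petmrsim/data/isotopes.yaml` so users can add
isotopes without code changes.  The two high-energy emitters carry a
gamma-coincident branch: 82Rb with 13.1% of beta decays feeding a 777 keV
prompt gamma, and 68Ga with a 1.2% gamma-coincident branch whose gamma
energy defaults to the 1077 keV zinc-68 de-excitation line (configurable in
the data file, since decay compilations differ in how they group this
branch).

Branch spectra use the allowed-transition Fermi shape
N(T) ∝ F(Z,T) · p · (T + m_e c²) · (Q − T)² with the nonrelativistic
point-charge Coulomb correction for positrons, F = 2πη/(1 − e^(−2πη)),
η = −Zα/β, Z the daughter's charge; screening is neglected.  For these
light-to-medium nuclei the allowed shape reproduces mean energies at the
percent level (18F mean kinetic energy 250.4 keV on the default grid),
which is well inside the spread of the published range tables the transport
is compared against.  Sampling is inverse-transform on a 1024-point
tabulated CDF with linear interpolation; the table normalization and the
sampled-vs-tabulated Kolmogorov-Smirnov distance are test invariants.

Half-life decay during an acquisition is not simulated: every acquisition
runs at a fixed stated activity, matching a protocol that steps through
discrete activity levels rather than following one decaying fill.

## Positron transport

Condensed-history scheme with three ingredients:

* **Continuous slowing-down** at the Berger-Seltzer collision stopping
  power for positrons (Bethe theory with the positron correction term
  F⁺(τ)), I = 75 eV water-like for tissues.  Radiative (bremsstrahlung)
  loss is neglected — below 2% of the stopping power under 3.4 MeV in
  tissue — a documented deviation from a full GEANT4 process list.
  Steps lose a fixed 5% energy fraction, capped at `max_step` = 1 mm.
* **Multiple scattering**: after each step the polar deflection is
  Rayleigh-distributed with width
  θ₀ = (13.6 MeV / βcp) √(x/X₀) · (1 + 0.038 ln(L/X₀)), azimuth uniform.
  The √(x/X₀) factor keeps the accumulated variance independent of the
  step subdivision; the Highland logarithmic correction is evaluated at the
  particle's residual CSDA path L (interpolated from a per-material table)
  rather than the substep thickness, because applying it per thin substep
  both breaks variance additivity and overscatters — with per-substep
  widths the 18F soft-tissue mean range comes out ~20% short, with the
  residual-path anchor it lands within a few percent of the reference
  tables.
* **Magnetic field**: between scattering nodes the trajectory is the exact
  analytic helix segment for the step's path length (rotation angle
  φ = 0.2998·B·s/p, positive charge, d′ ∝ d × B), not a small-step pusher.
  This is unconditionally stable and testable against the closed form: the
  loss-free 1 MeV orbit in 3 T reproduces the 1.581 mm gyroradius to
  machine precision at finite step size in the position update and to <1%
  including the direction update.

Energy cutoff 10 keV (residual range in unit-density tissue well under
10 µm); the positron annihilates at rest at the cutoff point.  Annihilation
in flight is ignored (≲2% at these energies); both photons are emitted
back-to-back from the at-rest endpoint, with an optional non-collinearity
blur that defaults to off.

Material boundaries are respected by bisecting the helix parameter when the
endpoint of a step lands in a different material (12 iterations), scaling
the energy loss to the traversed fraction.  A step that fully straddles a
feature thinner than `max_step` in a low-stopping medium can miss it; the
thinnest feature in the shipped phantoms (the 0.5 mm line source) only
matters as a positron source, so this error is negligible here.  Positrons
crossing air gaps fly nearly loss-free at the step cap and are recorded as
escaped once they leave the bounding box of all placed shapes — escaped
positrons contribute no photons, which is the mechanism that depresses the
thin-sleeve sensitivity points of high-endpoint emitters (82Rb).

**Transversal-range convention.**  The transversal mean is the mean of the
absolute 1D projections, (|Δx| + |Δy|)/2, under which isotropic clouds obey
transversal = axial = mean3D/2 — the signature the reference tables show at
zero field.  The in-plane radial norm √(Δx² + Δy²) is available as an
option.

**Lung composition caveat.**  Tissues are density-scaled water (the source
material specification gives densities only).  The reference tables' lung
ranges exceed the inverse-density scaling of their soft-tissue values
(ratios ≈ 4 -- 4.5 vs 3.33), implying a lung composition with a lower
effective density than 0.3 g/cm³ density-scaled water.  Accordingly this
package's 18F/15O lung cells sit near the lower edge of the published
values; the 82Rb lung cells, which dominate the field-effect conclusions,
agree within a few percent.

## Photon transport and detection

Photons are tracked with Woodcock (delta) tracking against the majorant
attenuation of the world's materials, so no boundary-distance computations
are needed and the tracker vectorizes over the full photon batch.
Attenuation is Compton (Klein-Nishina total cross-section per electron
times electron density; water at 511 keV comes out 0.0958 cm⁻¹) plus a
small photoelectric part anchored at 511 keV with E⁻³ scaling (significant
only for the LYSO crystal).  Compton interactions sample the Klein-Nishina
differential via Kahn's rejection method and increment the photon's scatter
count; Rayleigh scattering is not modeled (≈1% of the water cross-section
at these energies), so "scatter history" means Compton history.  Photons
below 300 keV are dropped — they cannot blur into the 425 keV window edge.

A photon leaving the phantom flies ballistically to the detector cylinder;
the hit maps through the block/crystal tiling (17 × 4.0 mm crystals per
70 mm block arc, 9 × 5.3 mm crystals per 50 mm ring pitch, dead space
between) and is absorbed with probability 1 − exp(−μ_LYSO(E)·25 mm), then
thinned by the global efficiency factor (below).  Inter-crystal scatter and
depth-of-interaction are not modeled.

The digitizer blurs energies with a Gaussian of 10.5% FWHM at 511 keV
(√E scaling), applies the 425-650 keV window, then per-block dead time
(paralyzable by default; the non-paralyzable variant is selectable), in
that order.  Coincidence sorting pairs time-ordered singles within the
4.57 ns window with a take-all-goods policy for multiple coincidences;
self-pairs on one crystal are excluded.  Randoms arise naturally from
Poisson pile-up of distinct decays inside the window — no delayed-window
estimator exists, consistent with an analysis that never needs a separate
randoms estimate.  Classification uses the decay identity carried by every
photon: different decays → random; same decay with any Compton history →
scattered; otherwise true.

## Calibration (done once, then frozen)

Two scalars connect the desk-scale chain to the absolute scale of the
modeled system; both are calibrated on 18F only and then frozen for every
other isotope, so all cross-isotope comparisons are blind predictions:

* **Efficiency factor 0.948** — per-single detection thinning set so the
  fitted attenuation-free 18F sensitivity matches the 21.5 cps/kBq
  reference.  The uncalibrated chain gives 23.9 cps/kBq, 11% high, which
  the factor absorbs together with everything not modeled (packing
  fraction, optics, electronics).  The fitted aluminum attenuation
  coefficient of the sleeve series, 0.0226 mm⁻¹, agrees with the physical
  511 keV value and is not calibrated.
* **Dead time** — per-block paralyzable τ set so the 18F count-rate curve
  peaks at the reference peak-NECR value (216.8 kcps).  The peak *activity
  concentration* is not separately matched — one scalar cannot pin both,
  and in this model the randoms rate at matched trues is higher than the
  reference system's, which pulls the peak to lower concentration.  Peak
  NECR values and orderings, not peak locations, are the comparison
  surface.

## NEMA analyses at desk scale

**Sensitivity.**  Acquisition batches accumulate until every
single-slice-rebinned slice holds the required trues (10,000 in the
protocol; tests scale this down).  The fit is ordinary least squares in
log space — matching an exponential-regression-with-R² presentation — with
both S₀ and μ_Al free; R² is computed on log-space residuals.  A fixed-μ
variant is exposed.

**Sinograms.**  320 angles × 640 radial bins over ±300 mm per
single-slice-rebinned slice (89 slices).  Because a list-mode record
localizes a photon only to a crystal, each LOR endpoint is drawn uniformly
across its 4 mm crystal face when binning (deterministic seed).  Binning
crystal centers instead creates a ~2 mm LOR comb that the peak alignment
phase-locks to the profile center; the 40 mm strip edge then falls exactly
on a comb tooth (20 mm = 10 × 2 mm) and the background estimate biases the
recovered trues by several percent.  Face sampling removes the comb and the
bias (the labeled-fixture recovery tests pin this).

**Strip analysis.**  Mask beyond 120 mm, align each angle row's maximum to
the center bin (ties to the lower index; all-zero rows unshifted), sum
rows, then split the profile with the 40 mm strip: background inside the
strip is the mean of the two linearly interpolated edge values times the
fractional bin count (42.67); counts above that inside the strip are
trues; everything else is background-type.  Masked-out counts never enter
any total.  At desk-scale counts individual slices and angle rows are too
sparse to carry their own alignment, so by default all slices are collapsed
into one plane before alignment, and for multi-level count-rate curves the
per-angle shifts are measured once on the high-statistics low-activity
acquisition and reused across levels — the shift pattern is a property of
the static source geometry, not of the activity.  The full per-slice
analysis remains available for full-scale data.

**Count rates.**  The scatter fraction is measured in a dedicated
acquisition at 0.2 MBq, where the predicted randoms-to-trues ratio is below
1%, and held fixed across the curve to split background into scatter and
randoms (S = T·SF/(1−SF), R = B − S); NECR = T²/(T+S+R) with no factor-2
randoms variant.  The curve's peak is the grid maximum over the activity
levels (default 11 log-spaced points over 1-800 MBq).  Rates are reported
as observed — no dead-time correction.  The phantom volume used for
activity concentration is the geometric 22.65 L, not the nominal 22 L.

## Synthetic fixtures

The list-mode generator emulates the three coincidence populations with
exactly known rates: trues on LORs through the off-axis line source with
1 mm jitter, scatter with a flat ±70 mm radial kernel around the source,
randoms uniform in (angle, radial offset).  Kernel widths default to values
that keep every generated event inside the 120 mm analysis mask, so the
configured rates are exactly what the strip method should recover.  The
fixtures share the crystal-pair representation with the real chain but skip
photon physics entirely — passing the recovery tests validates the
*analysis* pipeline, not the transport; the transport is validated
separately against closed forms and the published range tables.

## Problem sizes and statistical power

Default desk-scale sizes: 10⁵ decays per range cell (MC standard error
≈ 0.5% on a mean range), 1-2 × 10⁶ decays for scatter-fraction
acquisitions (SF standard error ≈ 0.5 points), 10⁶ decays per count-rate
level.  At these sizes the large cross-isotope NECR deficit of 82Rb
(~20%) is resolved at several standard errors, while the few-percent
Ga68-vs-18F peak separation is resolved only marginally — the strip
estimator's variance is dominated by the two edge bins of the summed
profile, and pinning a 4% peak difference would need ~50× more decays.

## Known limitations

* Tissues are density-scaled water (see the lung caveat above).
* Crystal response is binary absorption at the entry crystal: no
  inter-crystal scatter, partial deposits, or depth of interaction, and no
  time-of-flight kernel.
* The MR bore shielding layers are not modeled as photon absorbers.
* Dead time acts on in-window singles; a real digitizer chain may apply it
  upstream of the energy window.  The calibrated τ absorbs this ordering
  choice.
* The NECR peak activity concentration is systematically below the
  reference system's (see Calibration).
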