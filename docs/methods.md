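# Methods

`uvcbox` is a well-mixed (zero-dimensional) chemical box model for indoor
air under germicidal UVC lighting. This note records the model equations,
the data and parameter choices behind the bundled scenarios, the numerical
strategy, and the limitations a user should keep in mind when interpreting
results.

## Governing equation

For every integrated species *i* (number density C_i, molecules cm⁻³):

    dC_i/dt = Σ_j R_ij  +  λ_r (C_i,out − C_i)  −  Σ_m v_d,i,m (A_m/V) C_i  +  k_i(t)

* **Σ_j R_ij** — gas-phase chemistry: every reaction contributes
  −rate to each reactant and +yield·rate to each product, with
  rate = k·Π[reactants]. O2, N2, M and H2O are held fixed at the values
  implied by temperature, pressure and relative humidity.
* **λ_r** — the air change rate (converted to s⁻¹). Species with an
  outdoor diurnal profile exchange against it; all others are purely
  diluted (outdoor concentration zero).
* **v_d (A/V)** — material-resolved irreversible surface deposition
  (velocities in cm s⁻¹, area-to-volume ratios in m⁻¹).
* **k_i(t)** — indoor sources: occupant breath (schedule-gated), constant
  primary emissions from painted/wooden surfaces, and at-surface ozone
  reaction products, which are proportional to the instantaneous ozone
  concentration (yield × deposition flux, per material).

## UVC photolysis

The 200–300 nm range is tiled by ten 10 nm bins named by their midpoint
(UV205 … UV295). For each photodissociation channel,

    j = Σ_bins h(bin) · I(bin),   h(bin) = (10 nm)⁻¹ ∫_bin σ(λ) φ(λ) dλ,

where I(bin) is the spherically integrated photon flux the lamp delivers in
that bin, obtained from the spectral irradiance via I = R/E and E = hc/λ.
The (10 nm)⁻¹ normalization makes h a bin average, so for a monochromatic
lamp j collapses to σφ·I as it must. Bin averaging is the method's
intrinsic discretization: with a 222 nm line the UV225 bin average of the
O2 cross-section (≈4.5×10⁻²⁴ cm²) sits ~8% below the line value, and
lamp-driven ozone production inherits that bias.

Cross-section/quantum-yield tables are bundled as 1 nm piecewise-linear
digests of standard kinetics evaluations, each carrying a source note, and
are exportable to (and re-loadable from) a two-column text format:

| channel | notes |
|---|---|
| O2 → 2 O(3P) | effective 1-atm Herzberg continuum (includes the pressure-enhanced component), φ=1; zero above 242 nm, with the weak 240–242 nm tail truncated at 240 nm so bins at/above UV245 carry exactly zero |
| O3 → O(1D)/O(3P) | Hartley band; φ(O1D)=0.9, remainder O(3P) |
| H2O → OH + H | far-UV tail, 200–232 nm |
| H2O2 → 2 OH, NO2 → NO + O(3P), HONO → OH + NO | UV digests |
| HCHO (radical/molecular) | onset ~240 nm; radical-channel products carried to their immediate fates in air |

Lamps: **GUV222** is a synthesized filtered-KrCl spectrum — a 222 nm line
(FWHM 4 nm, ~92% of energy) plus a short-wavelength shoulder near 216 nm
(~8%), giving ~82% of energy in UV225 and ~18% in UV215, consistent with
the published per-bin behaviour of filtered KrCl lamps. The shape is a
swappable input; results depend only on the per-bin irradiances.
**GUV254** is a monochromatic 253.7 nm line. A lamp is normalized so its
spectral integral equals the stated average room irradiance (µW cm⁻²), and
a daily on/off clock schedule gates all UVC photolysis exactly (j ≡ 0 when
off, and during the entire spin-up day).

## Reduced mechanism

Full near-explicit VOC mechanisms run to thousands of species; indoor
UVC perturbations are dominated by O3/HOx/NOx physics plus a small set of
product carbonyls, so the bundled mechanism reduces to 40 integrated
species and 68 reactions:

* O3, O(3P), O(1D), H, OH, HO2, H2O2 — including both Hartley-band
  branches and explicit O(1D) quenching by N2 and O2, so the ~7–10%
  O(1D)+H2O → 2 OH branching at indoor humidity is emergent, not imposed;
* NO, NO2, NO3, N2O5, HNO3, HONO;
* CO, CH4, HCHO oxidation; CH3CHO with one acyl-peroxy/PAN couple and a
  thermal PAN decomposition; one lumped organic nitrate (RNO3) fed by RO2+NO
  branching; isoprene (breath) and limonene (terpene) with O3-initiated OH
  yields (0.25 and 0.66); 6-MHO and 4-OPA as skin-lipid chemistry markers;
* the straight-chain carbonyls glyoxal, acrolein, propanal…decanal, each
  with an OH loss (acyl channel lumped into the CH3CO3 pool).

Rate coefficients are hand-transcribed digests of JPL/IUPAC-style
evaluations with per-reaction source notes (`Mechanism.document()`).
Falloff reactions (OH+NO2, OH+NO, CH3CO3+NO2, N2O5 decomposition) use
1-atm effective values — adequate because every bundled scenario sits at
1 atm and 293–296 K. HO2+HO2 keeps its M and H2O enhancement terms. The
lumped RO2 diagnostic is the sum of CH3O2, ISOPO2, LIMO2 and CH3CO3.
"Total organic nitrates" and "total PANs" in the secondary-product metric
map to the lumped RNO3 and PAN species.

A tagged sub-network (O(3P)+O2+M; both O3 photolysis branches; O(1D)
quenching) conserves Ox = O3+O(3P)+O(1D) exactly, which the property suite
checks, along with exact agreement between the vectorized tendency
evaluation and a naive per-reaction summation oracle.

## Surfaces and occupants

Inanimate materials take up O3 at 0.0345 cm s⁻¹ and H2O2 at 0.045 cm s⁻¹
(the all-surface office values). Skin takes up O3 at 0.55 cm s⁻¹ — within
the measured range for people and roughly 16× the inanimate default —
which makes 22 m² of occupant skin the dominant ozone sink in the occupied
classroom (surface loss ≈ 4 h⁻¹ occupied vs ≈ 1.6 h⁻¹ empty). HNO3, N2O5
and the organic acids deposit at 0.07 cm s⁻¹; carbonyls at a weak
0.0005 cm s⁻¹; NO2 at an effective 0.05 cm s⁻¹ chosen to reproduce the low
indoor/outdoor NO2 ratios of furnished rooms (its surface hydrolysis is
not modelled explicitly).

Deposited ozone re-emits secondary products at fixed molar yields per
material: skin → 6-MHO (0.10), decanal (0.09), nonanal (0.07), acetone
(0.05), 4-OPA (0.035), formic/acetic acid (0.03 each), hexanal (0.02);
wood → formaldehyde (0.10), acetaldehyde (0.07), acrolein (0.05), C5–C6
aldehydes; paint/linoleum → C3–C10 aldehydes at 0.01–0.03, including
decanal entries that can be toggled off (reported decanal emissions from
building materials may reflect skin-oil contamination of the tested
samples). All yields are configuration-exposed; the bundled values are
literature-informed defaults, not fitted constants. 4-OPA has a second,
gas-phase route via 6-MHO ozonolysis (yield 0.75).

Occupants: adults 2 m², children 1 m² of skin; breath emissions of
acetone (1.0 mg h⁻¹ per adult), isoprene (0.35) and NO (0.012), children
scaled ×0.6 (10-year-olds), all gated by the presence schedule. Painted
and wooden surfaces carry small constant primary emissions (HCHO,
acetaldehyde, pentanal, hexanal) plus a limonene background, sized to give
ppb-level baseline VOCs; these are placeholders where measured emission
inventories would slot in.

## Scenarios

* **Office** (evaluation): 33 m³, S/V 1.0 m⁻¹, unoccupied, ACR 0.79 h⁻¹,
  constant 3 ppb outdoor O3, 295.7 K / 50% RH, GUV222 at 0.86 µW cm⁻²
  cycling 3 h on / 3 h off with an on-phase anchored at 21:00 (the
  anchor is an assumption; only the phase, not the physics, depends on it).
* **Kitchen** (per-bin experiment): 25 m³, S/V 2.53 m⁻¹, one adult,
  19.9 °C / 53.8% / 0.5 h⁻¹, suburban outdoor profiles, lit 07:00–19:00 by
  a single 10 nm slice of the KrCl lamp's emission; the slices are scaled
  so UV225 carries 93.8 µW cm⁻² — the at-20-cm fluence of the source lamp,
  used without renormalization to a room average.
* **Classroom**: 178 m³; paint 144 / wood 26 / linoleum 60 m²; 20 children
  + 1 adult present 09:00–12:00 and 13:00–15:00 (lamp on the same
  schedule); 295 K / 37.5% RH (60% variant available); ACR
  0.125/0.5/2.0 h⁻¹ × GUV222 (1/3/5 µW cm⁻²) or GUV254 (9/12/15 µW cm⁻²,
  already including the 30% partial-room factor); three lamp-off baselines;
  simulations 19–21 unoccupied.

Outdoor air uses smooth 24 h-periodic synthetic profiles: O3 15–40 ppb
peaking 15:00 (sinusoid), NO 0.5–8 and NO2 4–16 ppb double-peaked at the
morning/evening rush, constant CH4, near-constant CO, and small HCHO /
acetaldehyde / isoprene / acetone backgrounds. These emulate a suburban
diurnal cycle; they contain no weather, no weekend effects and no
pollution episodes, so model-to-model comparisons (lamp vs baseline) are
meaningful while absolute outdoor-driven levels are only representative.

## Numerics

The system is stiff in the extreme: O(1D) and H live for ~1 ns–1 µs
against a 48 h window. Integration is piecewise over the intervals where
every schedule (lamp, occupancy, emissions) is constant, each segment in
segment-local time (so post-switch radical transients are not limited by
floating-point spacing), with scipy's BDF, an analytic dense Jacobian,
rtol 10⁻⁶ and atol 10⁻³ cm⁻³. The tight absolute tolerance is deliberate:
with a loose atol the solver may accept spurious excursions in the
fast radicals that leak into the ozone budget; at 10⁻³ cm⁻³ the
source-minus-loss closure of the ozone budget holds to better than 0.2%
relative RMS on every bundled scenario (audited by the test suite at 1%),
and the integration is also faster. Concentrations are reported every
60 s; negative values (only ever below solver tolerance) are floored at
zero and counted. Every run begins with a 24 h lamp-off spin-up so the
analysis day starts chemically relaxed. A 48 h office run takes ~2 s on
one CPU; the full acceptance script ~20 s.

## Diagnostics

* **PR** (mg h⁻¹): baseline-differenced total ozone source — in-room
  photochemical production (the O(3P)+O2+M flux, gross, i.e. including
  re-formation of photolyzed ozone) plus positive net ventilation inflow
  max(λ_r(C_out−C_in), 0) — averaged 09:00–12:00 and converted with the
  room volume and M(O3) = 48 g mol⁻¹. Negative net exchange is booked as
  ventilation loss, keeping the production and loss columns disjoint.
* **TLR** (h⁻¹): (Σ loss fluxes)/[O3] at the ozone peak, taken over
  lamp-on samples when a lamp exists (the quantity characterizes lamp
  operation); loss shares partition surfaces / photolysis (gross) / NOx /
  VOCs-and-other-gas-phase / ventilation (gross outflow λ_r[O3]) and sum
  to 100%.
* **ΔSPCP_mod** (ppb): window-averaged (09:00–15:00), baseline-subtracted
  sum over ozone, lumped organic nitrates, lumped PANs, glyoxal,
  formaldehyde, acetaldehyde, acrolein and the C3–C10 straight-chain
  aldehydes.
* **OH reactivity** (s⁻¹): Σ k(OH+X)·[X] over every mechanism reaction
  consuming OH, excluding OH itself.
* **Species budgets**: per-reaction signed contributions from the archived
  reaction rates, ranked by window-integrated magnitude; their sum is
  checked against the archived chemistry tendency.
* The **office decay rate** is extracted the way chamber studies fit
  measured decays: a log-linear least-squares fit of the raw O3 series
  over the first hour after switch-off, without background subtraction.
  (Subtracting the ventilation-supported background first would instead
  recover the full eigenvalue, deposition + ventilation ≈ 2 h⁻¹.)

## Design choices where the design was open

* Eq-level normalization of h: per-10 nm bin average (see above), not a
  (100 nm)⁻¹ prefactor, which would understate every j by 10×.
* O(1D) integrated explicitly with its quenching reactions rather than
  imposed at steady state, so humidity sensitivity of the OH source is
  emergent.
* The kitchen "single-bin lamp" keeps the source lamp's absolute per-bin
  fluence (no renormalization), which is what makes the UV225 kitchen run
  two orders of magnitude more intense than the office lamp.
* TLR's peak search is restricted to lamp-on periods.
* Skin deposition velocity 0.55 cm s⁻¹ (not a small multiple of the paint
  value): only a people-scale uptake velocity reproduces the observed
  occupied-vs-unoccupied contrast in indoor ozone.

## Limitations

* The reduced mechanism carries no explicit RO/alkoxy chemistry, no
  Criegee intermediates, and lumps all acyl-peroxy radicals into one
  species; VOC-derived ozone loss and nighttime NO3 chemistry are
  correspondingly coarse.
* No aerosol/SOA formation, no reversible sorption, no transport-limited
  deposition, no spatial gradients (well-mixed by construction), no
  visible-light photolysis (dark baseline only).
* Primary surface emissions and product yield tables are placeholder-grade
  defaults; absolute product concentrations inherit their uncertainty
  (ozone-budget quantities do not, to first order).
* Synthetic outdoor profiles and synthetic lamp spectra: scenario outputs
  are faithful to the stated per-bin irradiances, not to any particular
  physical lamp.
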