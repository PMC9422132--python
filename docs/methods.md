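# Methods

## Scope

`csfosmo` implements the quantitative physiology chain that tests
whether conventional or local (standing-gradient) osmosis can account
for CSF secretion across the rat choroid plexus, together with the
small regression problems of the supporting transporter assays and
synthetic-data generators for each.  Wet-lab acquisition (surgery,
imaging, electrophysiology, sequencing) and inferential statistics
beyond simple summaries are out of scope; inputs are plain CSV time
series and printed physiological constants.

## Secretion analysis

The dye-dilution estimator Vp = ri·(Ci − Co)/Co is applied per 5-min
fraction; window means give baseline (50–65 min), treatment
(100–120 min) and osmotic-challenge (50–75 min) estimates, all
configurable.  Negative per-fraction values (net absorption) are
retained in window means rather than clipped — clipping would bias the
osmotic-challenge regression, whose hyposmolar side genuinely
approaches and can cross zero net secretion.  Percent inhibition is
computed per animal first (each animal is its own control), then
averaged.  The secretion-vs-osmolality slope is an ordinary
least-squares fit of Vp on ΔOsm; its published fold-change phrasing
("0.4% per mOsm") is not reproduced because the normalization
denominator is ambiguous (0.023/6.8 = 0.34%); the package reports the
slope and slope/baseline ratio at full precision instead.

## Geometry

Microvilli are modelled as cylinders of base radius r at areal density
ρ on a square lattice (spacing p = 1/√ρ — the functional unit is the
void between four microvilli, which a square arrangement realises).
Surface amplification is 1 − ρπr² + ρ·2πrl; the bulbous tip is ignored
by default since the published 12-fold figure is consistent with the
plain cylinder formula, and an optional hemispherical-cap correction
(+ρ·2πR_tip²) is available behind a flag.  The apparent epithelial
area follows from wet mass / (density · cell height).  Note an
internal inconsistency in the published constants: a choroidal volume
of 4.6e-9 cm³ is quoted alongside 4.6 mg at 1 g cm⁻³ (= 4.6e-3 cm³);
the downstream area of 4.6 cm² requires the latter, which is what the
package computes.

The inter-microvillar void (cross-section a_v = p² − πr²) maps to a
hydraulically equivalent circular cylinder.  Default equivalence is
equal cross-sectional area, d = 2√(a_v/π) (preserves volume flow for a
given mean velocity and keeps the one-dimensional solute balance
exact); matching the hydraulic radius (d = 2a_v/(πr)) is available as
a config option.  Channel length defaults to the brush-border depth
(1.5 µm) rather than the microvillus length (1.71 µm), since the
brush border is the diffusion-restricted region; both are selectable.
Per-unit wall area is the unit's share of the microvillar lateral
membrane plus the void base.  Point estimates only: the published ±SEM
values are not propagated, by design.

## Permeability calculus

Internally the chain works in CGS with concentrations in osmol cm⁻³
(mOsm, nominally per kg, is treated as per litre at the published CSF
density of 1.00 g ml⁻¹); the API reports the conventional units.
L_p,trans = slope/area; per-membrane L_p is double (two membranes in
series); luminal L_p per true area divides by the amplification.  The
printed slope and area give L_p = 8.33e-5 cm s⁻¹ Osm⁻¹ against the
published 8.7e-5 — a 4% gap attributable to input rounding (the
published value evidently used the unrounded slope); both numbers are
carried in the reference config, and the published point estimate is
used downstream exactly as printed, as the original chain did.
van't Hoff pressures use R = 8.314 J mol⁻¹ K⁻¹ at a default 310 K.

## Standing-gradient model

One functional unit is a cylinder of length L closed at x = 0 (cell
base) and open at x = L (tip mouth, bath osmolarity C₀).  Solute is
supplied at uniform flux density φ = (total solute rate)/(total
lateral+base wall area) — the steady-state identity that what bulk CSF
drainage removes, the walls must supply.  The wall and base inputs are
folded into a single distributed source with s_eff = wall area /
(L·A_c), the wetted area per unit channel length per cross-section.
With σ the reflection coefficient, the coupled steady-state balances
are

    (vC − D C′)′ = s_eff φ
    v′           = s_eff L_p σ (C − C₀)

with v(0) = 0, C′(0) = 0, C(L) = C₀, and the intracellular osmolarity
taken equal to C₀ (isotonic cell; the minimal assumption).  L_p here is
volumetric (cm s⁻¹ Osm⁻¹), so the partial molar volume of water enters
only if converting from mole-fraction permeabilities; it is carried in
the problem definition (18 cm³ mol⁻¹) for that purpose.

Nondimensionalised (ξ = x/L, u = (C − C₀)/C₀, w = vL/D) the system has
two dimensionless groups, α = s_eff·L_p,cgs·σ·C₀·L²/D (osmotic
coupling) and β = s_eff·φ·L²/(D·C₀) (solute loading, ≈ twice the peak
relative excess).  For the measured parameters α ≈ 6.6e-4 and
β ≈ 3.1e-4: deep in the linear regime.  The full system is solved with
a collocation boundary-value solver (`scipy.integrate.solve_bvp`,
tolerance 1e-8, automatic mesh refinement from 101 nodes; mesh
doubling moves the per-unit flow by < 1e-13 relative).  Dropping the
advective solute term gives the closed form u = β(1 − ξ²)/2,
w = αβ(ξ − ξ³/3)/2, used as an independent oracle; it agrees with the
full solve to 0.03% here.  Solute and water conservation at the mouth
hold to better than 1e-12 relative.

Tunable constants the source data do not fix: the solute diffusion
coefficient in the channel, D = 1.5e-5 cm² s⁻¹ by default (aqueous
NaCl near body temperature), σ = 1 (semipermeable walls), and the
channel length choice above.  In the linear regime the per-unit flow
scales as q ∝ W²·L_p·σ·φ·L/(3·D·A_c), so the absolute whole-tissue
prediction is proportional to L/D; with the defaults it computes to
~1.5e-3 µl min⁻¹ (0.022% of the observed 6.8 µl min⁻¹), the same order
as the published ~4e-3 µl min⁻¹, whose exact constant depends on
parameter choices not stated in the source text.  The scientific
conclusion — local osmosis supplies < 0.1% of CSF secretion — is robust
across any reasonable D and L, and remains so when the analysis is
rerun at the lower "direct-method" secretion scale (solute rate
rescaled with it, the fraction is unchanged by linearity).  The
emergent osmolarity (solute flux / water flux at the mouth) is
enormous (~1.4e6 mOsm) precisely because almost all solute leaves by
diffusion rather than advection; it decreases toward isotonicity only
as the osmotic coupling grows.  A sensitivity sweep is exposed as
`csfosmo standing-gradient --sweep`.

## Kinetics fits

⁸⁶Rb⁺ efflux: the ³H-mannitol channel estimates the extracellular
background, subtracted count-for-count (the source method says
"corrected for" without a formula; direct subtraction is the natural
reading and is isolated in `background_correct` so it can be swapped);
values that would go negative are clipped to zero with a warning.  The
rate constant is the negated OLS slope of ln(A_T/A_0) on time,
reported in min⁻¹ whatever the input time units.  Imaging rates are
plain OLS slopes with SE.  Dose-response curves use the four-parameter
logistic Y = Y_min + (Y_max − Y_min)/(1 + (IC50/X)^h), fitted by
bounded nonlinear least squares (h ∈ [0.1, 10], IC50 > 0) initialised
from the response extremes and the geometric mean of the doses
bracketing half-maximum; plateaus are free, so decreasing curves fit
with the plateau estimates swapped and are reported with ordered
plateaus and an orientation flag.

## Synthetic data

The generators embed known truth with the noise family each assay
exhibits: multiplicative Gaussian (CV 3%, plate-reader scale) on
outflow fluorescence, with a saturating-exponential equilibration ramp
confined to the first 30 min (cosmetic — outside every analysis
window, so zero-noise recovery in the windows is exact); additive
Gaussian scatter on the osmotic-challenge line, with the SD calibrated
in closed form to a target regression R² (default 0.48, the fit
quality of the reference experiment, over 11 animals spanning
±50 mOsm); Poisson counts around a mono-exponential efflux decay
sampled at 0–80 s; additive Gaussian noise on the Hill curve over a
half-log dose ladder.  Each generator takes one explicit seed and is
bit-reproducible.  What they deliberately do not emulate: dextran
leakage into parenchyma (shown negligible), drift, outliers, animal-
to-animal heterogeneity beyond the modelled noise, and detector
nonlinearities — so passing recovery tests demonstrates estimator
correctness under the stated noise model, not robustness to artefacts
real recordings may contain.

With only three 5-min fractions per analysis window, the per-window SE
estimate has two degrees of freedom; estimator calibration is
therefore assessed against the true sampling SE across replicates
(where ±2 SE covers ≥ 90%), while the per-run SE is checked for
unbiasedness.

## Known limitations

Point-estimate chain throughout (no uncertainty propagation);
single-solute, electroneutral channel model (no Nernst–Planck
electro-diffusion, no tip-bulb constriction, steady state only); the
basolateral compartment is not modelled (anatomically implausible site
for luminal-side standing gradients here); absolute standing-gradient
flow depends on the unmeasured D and channel length as q ∝ L/D, though
its < 0.1% bound does not.
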