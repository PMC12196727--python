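# Methods

## Scope and model structure

`vitrodist` predicts how a chemical dosed into a microplate well distributes
among medium water, serum constituents (albumin-like protein and lipid),
cells (water, lipid, protein), labware plastic, and headspace, and carries
the resulting in vitro bioavailability into quantitative in vitro to in vivo
extrapolation (QIVIVE). Four model flavors are provided:

| flavor | type | compartments | extra processes |
|---|---|---|---|
| `equilibrium_media_cell` | equilibrium | media + cells | — |
| `equilibrium_full` | equilibrium | media + cells + plastic + headspace | solubility cap with salting-out |
| `kinetic_permeability` | time-dependent | media + cells + plastic + headspace | permeability-limited uptake, optional metabolism |
| `kinetic_neutral_fate` | time-dependent | media + cells + plastic + headspace | evaporation, abiotic degradation, cell growth; neutral chemicals only |

All four share one canonical linear mass balance. Each compartment *i* has a
capacity κ_i = K_i·V_i (mL of equivalent aqueous volume), so at equilibrium

    C_free = dose / (V_w + Σ_i K_i·V_i),

with F_free,media = C_free/C_nominal, A_media and A_cell the summed amounts
in the media and cell sub-compartments. The flavors differ only in which
capacities they include and which loss processes they add. This shared
structure is deliberate: the model families in routine use differ mainly in
compartment coverage and kinetics, and representing them as one mass balance
makes their cross-comparisons exact rather than approximate.

## Chemical parameterization

**Speciation.** Ionizable chemicals are screened at the assay pH (7.4): an
acidic pKa ≥ pH + 2 or a basic pKa ≤ pH − 2 leaves the compound
predominantly neutral and is ignored. The retained pKa gives the neutral
fraction by Henderson–Hasselbalch, f_neutral = 1/(1 + 10^(s·(pH − pKa))),
s = +1 for acids and −1 for bases. If both an acidic and a basic pKa survive
the screen, the one closer to the system pH is retained and classifies the
compound; zwitterions are outside the applicability domain.

**Partition coefficients.** Serum protein and cell protein use the
albumin–water distribution ratio D_BSA/w; serum and cell lipid use the
liposome–water ratio D_lip/w (cell protein additionally scaled by a
configurable factor, default 1, because cell-protein affinity is not
separately characterized). Measured ratios take precedence; otherwise they
are predicted from hydrophobicity by single-parameter regressions
log D = a·log Kow + b, with defaults a = 0.71, b = 0.42 (albumin) and
a = 1.01, b = 0.12 (liposomes), taken from the published neutral-organic
relationships of Endo & Goss (2011) and Endo, Escher & Goss (2011). For
ionizable chemicals the regression input is first corrected to the
octanol–water distribution ratio log D_OW = log Kow + log10(f_neutral), i.e.
only the neutral species partitions. A configuration switch can add a fixed
log-offset ionic-sorption term; it is off by default because ion-specific
sorption is poorly constrained.

**Salting-out.** When no measured Setschenow constant is supplied it is
estimated as K_salt = 0.04·log Kow + 0.114 (L/mol). The aqueous solubility
used by the full-system flavor is S = S_w/10^(K_salt·I) with I the medium
ionic strength (default 0.16 mol/L). If C_free exceeds S the free
concentration is capped at S, bound compartments re-partition proportionally
to their capacities, and the excess is booked as precipitate — reported, and
retained in the conservation ledger, but excluded from A_media.

**Headspace and plastic.** Headspace partitioning uses the supplied log K_AW
for the neutral species only (no temperature re-correction by default; the
chemical table can carry H37 for users who prefer the 37 °C Henry constant).
Plastic sorption is area-based with capacity K_pl·A_plastic·f_neutral, where
log10 K_pl [L/m²] = 0.97·log Kow − 6.94 by default (polystyrene–water
sorption scale); the wetted area comes from a cylindrical-well geometry
(96-well: 360 µL, 6.4 mm diameter; 384-well: 112 µL, 3.3 mm).

## Volume bookkeeping

Serum constituent volumes are concentration × media volume ÷ density with
all constituent densities defaulting to 1 g/mL; the error from unit density
is far below model error and keeps the volume-equivalent bookkeeping exact.
100% FBS defaults to 23 g/L albumin and 2.5 g/L lipid, scaled by the serum
percentage; measured media concentrations (e.g. 4.19 mg/mL protein and
0.22 mg/mL lipid for the application-stage medium) override the scaling when
supplied. Cell volume is count × mass/cell ÷ density, split by the water,
lipid, and protein mass fractions. Because the constituents displace media
water, a chemical that binds *less* avidly than water (D < 1, log Kow below
about −0.6) can have a free concentration marginally above nominal; the
reported free fraction is capped at 1, and the sub-percent excess is an
excluded-volume artifact, not a mass-balance error.

## Kinetic flavors

The medium pool (water + serum constituents) is assumed internally
equilibrated at all times, so its free concentration is a_media/κ_media.
Cells, plastic, and headspace relax first-order toward their
partition-equilibrium targets, da_i/dt = k_i(C_free·κ_i − a_i), rather than
through explicit permeability × area mechanics: this form reproduces the
correct equilibrium and is governed by two interpretable rates. Default
exchange rates are fast (10 h⁻¹) so 24 h predictions sit at equilibrium
unless the user slows them. Metabolism (first-order on the cell pool),
abiotic degradation (on the media pool), and evaporation (air-side, open
wells) drain into explicit loss ledgers; cell growth scales the cell
capacity exponentially (capacity growth, not dilution of intracellular
amount). Integration uses LSODA with rtol 1e-8 / atol 1e-10 because
trajectory-wise conservation to 1e-6 relative is a tested guarantee. The
metabolism/degradation/growth paths are validated by property tests
(monotone loss, conservation, growth direction) only, as no measured data
exercise them.

## Evaluation

Predictions and observations are compared on the log10 scale: MAE for
accuracy, ME for bias, Pearson r on logs and Spearman ρ on average ranks for
association, all optionally weighted (the inverse-variance case used for
confidence-interval-bearing in vivo PODs, with SE = log10 CI half-width /
1.96). Whether literature correlations are computed on logs or raw values is
ambiguous; logs were chosen for consistency with MAE/ME. Zero or negative
predictions are floored at 1e-12 before the log with a warning. Censored
bound-percent measurements reported as "<10" or ">99" are replaced by the
interval midpoints (5% and 99.5% bound → 0.95 and 0.005 unbound); no other
substitution is ever made, and no tobit-style likelihood is attempted —
midpoint substitution is the method being mirrored. Residual-trend
regressions fit ordinary least squares of log residuals on each chemical
property separately, with no multiple-testing correction across the eight
properties (raw significance is reported); a trend is labelled "material"
when p < 0.05 and R² ≥ 0.10.

## Sensitivity analysis

The factorial design crosses chemicals × cell types × plate format (96- vs
384-well, with 20,000 cells/150 µL and 5600 cells/40 µL defaults) × serum
level (2% vs 20% FBS) × model flavor at 1 µM nominal dose. Factors are
lumped categories: chemical identity absorbs all chemical-related
parameters, cell type all cell-related ones. η² = SS_factor/SS_total comes
from a main-effects ANOVA (no interactions) on the log10-transformed
response — predictions span orders of magnitude, so raw-scale shares would
be dominated by a handful of extreme wells; a raw-scale mode is available by
flag. Unbalanced designs (rows dropped where the neutral-only flavor meets
an ionizable chemical) use type-I sequential SS in the fixed order chemical,
cell, FBS, labware, model; balanced designs are order-invariant, and their
shares plus residual sum to 1 exactly.

## QIVIVE

The steady-state plasma concentration per 1 mg/kg/day is analytic:
dose rate ÷ (GFR·fub + Q_h·fub·CLint_s/(Q_h + fub·CLint_s)), with CLint
scaled from µL/min/10⁶ cells via hepatocellularity and liver mass. No
empirical adjustment of fub or CLint is applied. Steady state (not C_max) is
the exposure metric since the in vitro predictions are 24 h or equilibrium
concentrations. Physiology defaults are standard-human: 70 kg body weight,
GFR 6.7 L/h, hepatic blood flow 90 L/h, 110 × 10⁶ hepatocytes/g liver,
1820 g liver; all overridable per chemical, so closed-form checks and
user-supplied TK tables are both possible. OED = POD/Css; the adjusted
variant multiplies by the correction factor fub_media/fub_plasma, the ratio
a nominal-concentration IVIVE implicitly ignores. Constant-POD modes ship
the two iTTC constants 0.01 µM (internal NOAEL) and 1 µM.

## Synthetic data

The generators define the study conditions for all self-contained tests:
log Kow uniform on [−2, 8]; log10 solubility (mg/L) = 3.5 − 0.7·log Kow +
N(0, 0.6); log K_AW = −5 + 0.4·log Kow + N(0, 1.2); molar mass lognormal
around 250 g/mol; a 70/15/15 neutral/acid/base mixture (matching the roughly
70% neutral share of typical screening sets), with class pKa values drawn
inside the non-ignorable window. The default cell panel (13 types) includes
one extreme-lipid type (f_lipid = 0.953) and one very low-mass type to
exercise known outlier behavior. Observations are truth × 10^ε with
ε ~ N(0, 0.3) by default — factor-two scatter typical of inter-laboratory
free-fraction measurements — and bound-% values outside [10, 99] are
censored to the verbatim markers. POD pairs place the in vivo POD at the
adjusted OED of a known truth times lognormal scatter, so concordance
identities are exact at zero scatter. All generators take explicit seeds and
are bit-reproducible.

What the synthetic data do **not** emulate: real measured-vs-predicted
discrepancy structure (model misspecification), correlated errors across
endpoints from shared analytics, chemical-class-specific binding chemistry
(e.g. per- and polyfluoroalkyl surfactant behavior), or measured
cell-composition tables. Passing tests therefore demonstrate internal
consistency, correct algebra, and correct statistical machinery — not
predictive accuracy on real assay data, which requires user-supplied
measurement tables.

## Numerical choices and limitations

- Bisection against the closed form, conservation ledgers, and re-integration
  oracles are tested at 1e-9/1e-6 relative tolerance respectively.
- Spearman ties use average ranks.
- Free fractions are capped at 1 (see volume bookkeeping).
- Whether wells are sealed is a labware flag (default open); volatile
  chemicals without log K_AW raise a parameterization error rather than
  silently dropping the headspace.
- No saturable (Michaelis–Menten) transport or metabolism; no
  lysosomal/mitochondrial ion trapping; no structure-based property
  prediction — properties arrive as numbers.
- The sensitivity and concordance stages reproduce published summary values
  only when the corresponding measured parameter tables (cell panels,
  chemical properties, TK data) are supplied by the user.
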