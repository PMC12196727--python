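# vitrodist

**In vitro chemical distribution (mass balance) models for microplate
bioassays and QIVIVE.**

Nominal concentrations reported for in vitro bioassays are not the
concentrations cells actually experience: serum proteins and lipids, the
cells themselves, labware plastic, and well headspace all sequester chemical
from the medium water. `vitrodist` is for toxicologists and risk assessors
doing quantitative in vitro to in vivo extrapolation (QIVIVE) who need the
*freely dissolved* medium concentration (F_free,media), the amounts in media
and cells (A_media, A_cell), and the downstream effect of in vitro
bioavailability on oral-equivalent-dose (OED) estimates.

## The model

All four model flavors solve one canonical equilibrium mass balance. With
each compartment *i* assigned a capacity κ_i = K_i·V_i (its partition
coefficient against water times its volume-equivalent),

```
C_free = dose / (V_w + Σᵢ Kᵢ·Vᵢ),      F_free,media = C_free / C_nominal
```

Serum/cell protein use the albumin–water distribution ratio D_BSA/w and
serum/cell lipid the liposome–water ratio D_lip/w, predicted from log K_OW
when unmeasured; ionizable chemicals are first speciated at pH 7.4
(Henderson–Hasselbalch with a ±2-log ignore rule) and partition via
log D_OW = log K_OW + log₁₀ f_neutral. The flavors differ in compartment
coverage and kinetics:

- `equilibrium_media_cell` — media + cells only;
- `equilibrium_full` — adds plastic, headspace, and an aqueous solubility
  cap with salting-out (K_salt = 0.04·log K_OW + 0.114);
- `kinetic_permeability` — first-order exchange toward partition
  equilibrium, optional intracellular metabolism;
- `kinetic_neutral_fate` — neutral chemicals only; optional evaporation,
  abiotic degradation, cell growth.

Downstream, `evaluation` scores predictions against measurements on the
log10 scale (MAE/ME, Pearson, Spearman, censored bound-fraction handling),
`sensitivity` attributes prediction variance to input categories via ANOVA
η², and `qivive` converts in vitro PODs to OEDs with and without the
bioavailability correction factor f_ub,media/f_ub,plasma. A `synthetic_data`
module generates chemicals, cell panels, observations, and POD pairs so the
whole pipeline runs without external data. See `docs/methods.md` for the
full model description.

## Worked example

```python
from vitrodist import (
    SyntheticSpec, generate_chemicals, generate_cell_types, default_plate,
    ExposureSystem, MediumComposition, predict_distribution,
    TKParams, css_steady_state, qivive_chemical,
)

chem = generate_chemicals(SyntheticSpec(n_chemicals=3, seed=42))[0]
cell = generate_cell_types(1, seed=42, include_extremes=False)[0]
cells_per_well, media_uL, labware = default_plate("96-well")

well = ExposureSystem(chem.id, nominal_conc=1.0, media_volume=media_uL,
                      cell_count=cells_per_well, cell_type=cell,
                      medium=MediumComposition(fbs_percent=10.0), labware=labware)

dist = predict_distribution(chem, well, "equilibrium_full")
print(f"F_free = {dist.f_free_media:.4f}  A_media = {dist.a_media:.4f} nmol")

tk = TKParams(chem.id, fub_plasma=0.1, clint=5.0)
res = qivive_chemical(chem.id, pod_invitro=1.0, tk=tk, mw=chem.mw,
                      fub_media=dist.f_free_media)
print(f"Css = {res.css_1mgkg:.3f} µM per mg/kg/day")
print(f"OED = {res.oed:.4f}  adjusted = {res.oed_adjusted:.4f} mg/kg/day")
```

prints, for this hydrophobic weak acid (log K_OW ≈ 5.0, MW 261):

```
F_free = 0.0231  A_media = 0.1434 nmol
Css = 1.771 µM per mg/kg/day
OED = 0.5647  adjusted = 0.1302 mg/kg/day
```

Only ~2% of the 1 µM nominal dose is freely dissolved — the serum lipid and
protein hold most of it — so a 1 µM in vitro POD corresponds to a free
concentration of 0.023 µM. Because this chemical is more strongly bound in
media than its plasma free fraction (0.1) implies, the correction factor
f_ub,media/f_ub,plasma = 0.23 *lowers* the OED; for most chemicals in
typical (low-protein) media the factor exceeds 1 and the adjusted OED is
higher, i.e. less conservative.

The same workflows are available from the shell:

```bash
vitrodist simulate-data --seed 1 --out-dir data/
vitrodist predict --chemicals data/chemicals.csv --flavor equilibrium_full --out pred.csv
vitrodist sensitivity --chemicals data/chemicals.csv --cells data/cells.csv --out sens.json
vitrodist qivive --pods data/pods.csv --tk data/tk.csv --chemicals data/chemicals.csv --out oed.csv
```

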