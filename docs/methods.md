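# Methods

`nfixbox` is a sixteen-box model of the coupled ocean nitrogen, iron,
carbon and oxygen cycles, built to study how aeolian iron fertilisation of
low-latitude N₂ fixers strengthens the biological carbon pump and draws
CO₂ out of a freely evolving atmosphere. This note documents the model,
its assumptions, the choices made where the design was open, and what the
synthetic configuration does and does not represent.

## Model structure

**Geometry.** Eight surface boxes (eastern and western tropical Pacific,
tropical Atlantic/Indian, two subtropical gyres, subarctic Pacific, North
Atlantic, Southern Ocean), four thermocline boxes (100–1000 m), two
intermediate boxes (1000–2000 m) and two deep boxes (2000–5000 m), with a
total volume of 1.33 × 10¹⁸ m³. This is the smallest arrangement that
separates the regions the mechanism distinguishes: an upwelling zone with
a suboxic shadow thermocline beneath it, a warm pool, oligotrophic gyres
where diazotrophs live, and the three high-latitude source regions.
Sub-grid bathymetry is emulated by a per-box *sediment contact fraction*:
the share of sinking organic matter entering a depth level that is routed
to the sedimentary remineralisation pathway. The eastern tropical
thermocline carries the largest contact fraction (shelf emulation).

**Circulation.** Closed advective loops (volume conservation is exact by
construction) plus bidirectional mixing: an AABW-like lower cell, an
NADW-like upper cell, Pacific subtropical cells feeding equatorial
upwelling in the east, an Atlantic tropical cell, North Pacific
intermediate water and Subantarctic mode water. Four named states span
interglacial to glacial conditions; their lower- and upper-cell strengths
(7.2/11.5/11.4/39.0 and 20.3/18.4/13.0/13.0 Sv), volume-mean temperatures
(5.3/3.9/3.5/1.4 °C), salinities and ice covers follow the tabulated
global properties of the corresponding climate states, and equatorial
upwelling is ranked warm > mild ≥ cool > cold. In the cold state most of
the greatly expanded lower cell recirculates at depth without surface
contact, so the glacial abyss is the oldest water in the set even though
the cell itself is the strongest — the model's stand-in for the
radiocarbon contrast between the states.

**Tracers.** DIC, alkalinity, PO₄, NO₃, ¹⁵NO₃, dissolved Fe, O₂ and ideal
age, plus a single well-mixed atmospheric CO₂ reservoir (5.1 × 10²¹ g of
air at 28.97 g mol⁻¹, so 1 ppm = 2.114 Pg C).

## Biogeochemistry

**Producers.** Export production is computed directly from surface-box
environment (no explicit biomass, no light limitation). Diazotrophs use
the static law

    P_exp^D = S_E:P^D · μ_D(T) · max(0.01, min(PO4_lim, NO3_lim, Fe_lim)) · (1 − ico)
    μ_D(T)  = max(0.01, −0.0042 T² + 0.2253 T − 2.7819)
    PO4_lim = PO4/(PO4 + 10⁻¹⁰),  NO3_lim = e^(−NO3),
    Fe_lim  = max(0, tanh(2 Fe − 0.3))

with C:N:P:Fe = 331:50:1:0.00064. Their remineralisation demands close
stoichiometrically to O₂:P = C:P + 2 N:P = 431 and NO₃:P = 0.8 C:P +
0.6 N:P = 294.8. The export:production scale `S_E:P^D` is not a published
number; the default (3 × 10⁻⁴ mmol P m⁻³ day⁻¹) is calibrated so that
the tropical thermocline sits in its observed low-oxygen regime and the
glacial drawdown falls in the published 7–16 ppm window. This puts
baseline global fixation at ~160–240 Tg N yr⁻¹ across the states —
above the canonical 100–150 — a deliberate trade-off: the model
bifurcates in this parameter, and on the lower branch the tropical
thermocline stays oxygenated and the drawdown mechanism collapses.

The general group uses Michaelis–Menten limitation in NO₃ (K = 0.75),
PO₄ (K = 0.1) and Fe (K = 0.1 μmol m⁻³, one third of the diazotroph
value; the MM form — rather than the diazotrophs' tanh — keeps the
eastern upwelling surface softly Fe/N co-limited instead of hard-bound
at the upwelled iron concentration), with a phosphate-dependent C:P ratio
C:P = 1/(a·PO₄ + b) clipped to [55, 170] — carbon enrichment under P
scarcity. The coefficients (a = 0.0058, b = 0.0024) are chosen so that a
glacial-scale surface-PO₄ decline of ~0.2 mmol m⁻³ enriches exported
matter by roughly 14 C:P units *within this model's surface-PO₄ dynamic
range* (≈0.9–2.3 mmol m⁻³; a coarse box ocean holds more residual surface
PO₄ than a gridded one, so the law is re-centred rather than copied).
N:P is 16 and the remineralisation demands use the same closure per
export event. The general group's Fe:P is set very low
(4 × 10⁻⁵ mol mol⁻¹, ~0.4 μmol Fe per mol C): in this geometry the
upwelling boxes must remain nitrogen-limited for the fixed-N pathway to
operate, and a larger quota made them iron-bound instead. Diazotrophs
remain sixteen-fold more iron-hungry, which is what the mechanism needs.
Calcifiers produce PIC at 8% of the general group's organic carbon
production; PIC dissolves down-column with a 2000 m e-folding and is not
buried.

**Surface sub-stepping.** Surface nutrient pools are small compared with
one coupling step of uptake, so production is sub-stepped at 0.05 yr
within each coupling step; limitation terms then act on smoothly
declining concentrations. Without this the e^(−NO3) niche term is
evaluated at the post-transport refill peak and the iron sensitivity of
fixation aliases away entirely.

**Redox cascade.** Sinking flux attenuates with a Martin-type power law.
The exponent varies smoothly with ambient oxygen between 0.9 (oxic) and
0.4 (suboxic) through a tanh ramp of width 8 mmol m⁻³ centred on the
suboxia threshold (10 mmol m⁻³): deoxygenation deepens particle transfer
continuously. A binary switch at the threshold was tried first and made
the coarse model bistable — ladder experiments jumped between branches —
so the ramp is a deliberate smoothing, not a tuning afterthought.
Water-column denitrification takes the fraction
f_den = (1 − e^(−0.5·7.5) + e^(O₂−0.5·7.5))⁻¹ of local remineralisation,
capped by r = 0.5 + 0.5 tanh(0.25 NO₃ − 0.25·30 − 2.5) so NO₃ is not
stripped below ~30–40 mmol m⁻³. Sediment denitrification removes
(0.08 + 0.1·0.98^(O₂−NO₃)) mol NO₃ per mol C delivered, relaxed toward
zero below ~1 mmol NO₃ m⁻³; sediment aerobic respiration may draw at most
two-thirds of the overlying O₂ and is throttled by
0.5 + 0.5 tanh(0.2 O₂ − 5) under hypoxia; whatever remains is
remineralised by sulfate reduction (no O₂ or NO₃ consumed). Organic
nitrogen routed through a denitrifying pathway leaves as N₂ (that is what
the NO₃:P closure assumes); the aerobic and sulfate pathways nitrify it.
Matter that cannot be remineralised in a box is passed to the next deeper
box, so every budget closes exactly; the bottom level intercepts
everything (no burial, consistent with carbon conservation).

**Iron.** Aeolian deposition is the external source. All subsurface boxes
and the three high-latitude surface boxes are relaxed to 0.6 μmol m⁻³ on
a one-year timescale (the subsurface nudging that renders eutrophic
high-latitude regions insensitive to extra dust); only the five
low-latitude surface boxes carry freely evolving iron, set by deposition,
upwelled supply and biological uptake. Iron in organic matter is released
wherever P is released; there is no explicit scavenging, so the
relaxation is the only abiotic source/sink and the iron budget diagnostic
closes on deposition + net relaxation.

**Carbonate system and gas exchange.** Full DIC/ALK equilibrium with
carbonate, borate and water balances (Weiss solubility, Lueker K₁/K₂,
Dickson K_B, Millero K_W) solved by Newton iteration on pH, warm-started
between steps and verified against an independently coded bracketed-root
solver. Air–sea CO₂ flux uses a uniform 3 m day⁻¹ piston velocity,
masked by ice; surface O₂ is restored to Garcia–Gordon saturation on the
same gas-exchange timescale. Alkalinity follows the conventional charge
balance: ±1 per mol NO₃ consumed/created, ±2 per mol PIC
dissolved/formed.

**Nitrogen isotopes.** ¹⁵NO₃ is carried as a subset of NO₃. Fractionation
uses a linear open-system rule per (sub)step — a flux removing fraction f
of a pool with factor ε carries δ_pool − ε(1 − f) — which conserves ¹⁵N
exactly by construction. Defaults: ε = 25‰ (water-column
denitrification), 3‰ (sedimentary), 5‰ (assimilation); newly fixed N at
−1‰, deposited N at −2‰; all configurable, since the source
parameterisation lives in a separate publication. The organic-matter
diagnostic δ¹⁵N_org is the export-weighted δ of assimilated plus fixed N
with a diagenetic correction of +0.9‰ per km of seafloor depth.

## Time stepping

Explicit Euler with a coupling step of 0.1 yr by default; the experiment
layer uses 0.25 yr and the headline protocol 0.3 yr, which changes
equilibrium diagnostics by ~1-2% (checked: the mild-state glacial
drawdown is 14.27 ppm at 0.25 yr and 14.13 ppm at 0.3 yr). Relaxation-type terms (iron
nudging, surface O₂ restoring) use their exact exponential update and
are unconditionally stable at any step. A process may consume at most
the pool available in a (sub)step — demand is rescaled proportionally
and the event logged — which is what keeps conservation exact in place
of higher-order stiffness handling. Forcings are monthly climatologies
sampled at the fractional year. Spin-ups start from a vertically
structured warm-start profile whose conserved inventories (P, ALK) are
rescaled to the uniform-initial values, so conservation statements are
unaffected; it only shortens convergence.

## Experiments

Every state is spun to its fixed-280 ppm equilibrium (drift of the NO₃,
PO₄, O₂, DIC inventories and pCO₂ below 10⁻⁴ % yr⁻¹, with caps of
8,000–13,000 years; the hard cap of 10,000 years elsewhere follows the
source protocol). Free-atmosphere scenarios start from that equilibrium,
so modern-iron runs hold ~280 ppm by construction. The iron ladder runs
50, 80, 100% (modern pattern), 500 and 2500% (glacial pattern: global
integral 5× and 25× modern, tropical Pacific only ~2× and ~10×); the
K_Fe ladder varies the diazotroph iron half-saturation (0.15/0.3/0.6)
at modern deposition. Scenario caps of 3,000–4,000 years with the same
drift exit are the desk-scale problem size; each result carries its
equilibration flag and drift. The ablation suite re-runs the mild ladder
with fixers removed (and denitrification and N deposition disabled, so
the NO₃ reservoir is the control inventory held constant), with fixer
C:P = 0, and with C:P = 165; the fixed-N share of the respired-carbon
gain is the C:P = 0 gain over the default gain, both relative to the
no-fixer run. Low-latitude PO₄ utilisation is 1 − (surface PO₄ / supply
PO₄) with supply taken as the volume-weighted thermocline PO₄.

## What the synthetic configuration does and does not show

The four circulation states, dust patterns, deposition climatology and
bathymetry fractions are *emulations* with the structural properties the
analysis needs (rankings, integrals, contrasts), not downscaled
reanalysis fields. Consequently: passing tests demonstrate that the
mechanism — iron-stimulated fixation, nitrogen-fuelled low-latitude
export, suboxic deepening of carbon injection, CO₂ drawdown at a few
tenths of a ppm per Tg N yr⁻¹ — operates and quantitatively reproduces
the headline numbers at box scale; they do not validate the gridded
spatial fields, the stratification metrics of the physical states (not
constrained beyond the circulation ranking), or comparisons against real
sediment cores at true coordinates. A sixteen-box ocean also holds more
residual surface PO₄ than a gridded model, which is why the frugality
law is re-centred (above) and why regional δ¹⁵N_org is reported as
glacial-minus-modern *shifts* per region rather than absolute coretop
values.

## Numerical choices and degenerate inputs

Availability caps clamp working pools at zero before computing Michaelis–
Menten ratios (round-off residuals would otherwise flip their sign).
δ¹⁵N of an empty pool is a missing value. The carbonate Newton iteration
halves [H⁺] on overshoot and converges to 10⁻¹⁰ relative from a warm
start in a handful of iterations. Tendencies are attributed per process
and their sum equals the applied state change exactly, up to the logged
zero-clipping of round-off negatives. Transport of a uniform field is
machine-precision null because inflow and outflow coefficients cancel
row-wise by construction.

## Known limitations

No explicit biomass, grazing, light cycle, ligands, scavenging, carbon
isotopes, or CaCO₃ sediment feedback. The deoxygenation/deep-transfer
feedback is strongly nonlinear at box scale: state-to-state differences
in drawdown are sensitive to the OMZ oxygen margins in a way a gridded
model smooths out, and the cold state's weak response rests on its
prescribed stratified circulation. The 10,000-year cap means a handful
of strongly forced scenarios (2500% rungs in the most responsive states)
are reported slightly short of full equilibrium, flagged as such.
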