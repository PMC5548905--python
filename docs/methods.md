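# Methods

This note documents the models implemented in `coralcarb`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Seawater CO₂ system

The solver works on the total hydrogen-ion pH scale with concentrations in
mol kg-seawater⁻¹ (µmol kg⁻¹ appears only at I/O boundaries). Given measured
(pH_T, A_T, T, S), the carbonate alkalinity is obtained by subtracting the
borate, hydroxide and free-proton terms from A_T, and DIC follows in closed
form from the carbonic-acid speciation fractions at the given [H⁺]. The
alkalinity model omits phosphate, silicate and ammonia: these are not part of
routine mesocosm monitoring and contribute negligibly in oligotrophic coastal
seawater. Pressure dependence and pH-scale conversions are out of scope.

Constant formulations (pluggable by name, defaults in parentheses):
K₁/K₂ (Lueker et al. 2000; Roy et al. 1993 available), K_B (Dickson 1990),
K₀ (Weiss 1974), K_w (Millero 1995), aragonite K_sp (Mucci 1983), total boron
(Lee et al. 2010; Uppström 1974 available), calcium 0.010282 × S/35
(Riley & Tongudai). Lueker K₁/K₂ is the default because it is the standard
choice of the major CO₂-system packages and gives the best joint agreement
with monitored treatment chemistry in our validation; Roy constants raise
pCO₂ slightly but degrade Ω_arag by ~7%, which is why they are not the
default.

Salinity is rarely reported alongside tank pH/alkalinity; the package default
is S = 35.5 (subtropical Western Australian coastal water), configurable
everywhere. Sensitivity is ~1–2% on pCO₂ and Ω per salinity unit.

Treatment-level summaries solve **every observation** and then average,
rather than solving at the mean pH. pCO₂ is convex in pH, so with realistic
monitoring jitter (pH SD ≈ 0.05) the mean of per-observation pCO₂ runs
~1–3% above the solve at the mean pH; averaging per-observation solutions is
also how monitored treatment tables are conventionally produced.

## Boron-proxy reconstruction

pH_cf from δ¹¹B uses the borate-incorporation model with δ¹¹B_sw = 39.61‰
and α_(B3−B4) = 1.0272; pK_B is evaluated at ambient T and S (no
fluid-specific ionic-strength correction — the convention of the proxy
literature). The algebraic inverse is provided for round-trip testing and
data synthesis; the pair round-trips to ~10⁻¹² pH units.

[CO₃²⁻]_cf from B/Ca assumes the calcifying fluid carries seawater total
boron at ambient salinity, speciated at pH_cf. The distribution coefficient
is K_D = K_D0 exp(−k_KD[H⁺]) with K_D0 = 2.97×10⁻³ and k_KD = 0.0202. The
unit of [H⁺] in the exponent is a genuine ambiguity in the calibration
literature; the package default expresses [H⁺] in µmol kg⁻¹, which makes the
attenuation negligible (<0.01%) at calcifying-fluid pH and reproduces
published coral reconstructions (e.g. DIC_cf ≈ 3.8–3.9 mmol kg⁻¹ and
Ω_cf ≈ 14 for a fast-calcifying *Acropora* at ambient pH). The nmol kg⁻¹
convention is available (`BoronConstants(h_unit="nmol")`); it lowers the
reconstruction by ~6% at pH_cf 8.5. The printed uncertainty of k_KD in the
source calibration exceeds the value itself (a suspected typo), so only the
central value is used. K_D0's calibration uncertainty (±0.17×10⁻³) is stored
on `BoronConstants` for sensitivity studies but is not propagated by default:
standard practice propagates only the two measurement errors.

DIC_cf = [CO₃²⁻]_cf (1 + [H⁺]/K₂ + [H⁺]²/(K₁K₂)) and
Ω_cf = [CO₃²⁻]_cf [Ca²⁺]/K_sp, both with ambient-seawater constants —
i.e. the reconstruction deliberately does not model the fluid's distinct
ionic strength. Rayleigh fractionation and vital-effect corrections are out
of scope.

## Monte-Carlo uncertainty

δ¹¹B and B/Ca are drawn independently (no correlation is known) around the
measured values and each draw runs through the full chain. The default
distribution is Gaussian with the analytical SDs (0.17‰, 18 µmol mol⁻¹);
an interval reading ("mean ± SD" as a uniform range) is available and shrinks
propagated SDs by ~√3. The Gaussian default is what reproduces reported
proxy-study uncertainties (pH_cf SD ≈ 0.01, DIC_cf SD ≈ 110 µmol kg⁻¹ at
1000 iterations); the uniform option yields ≈ 65 µmol kg⁻¹ for DIC_cf.
Domain-violating draws (δ¹¹B at or above seawater) are rejected and
resampled with a cap of 10× the iteration count; summaries report mean, SD
(ddof = 1) and 2.5/97.5 nearest-rank percentiles. Fixed seeds give
bit-identical results.

## Calcification rates

Buoyant-weight changes convert to dry aragonite mass through
Δm_dry = Δm_buoyant / (1 − ρ_sw/ρ_arag) with ρ_arag = 2.93 g cm⁻³ and ρ_sw
from the EOS-80 one-atmosphere density polynomial (≈1.0249 g cm⁻³ at 21 °C,
S 35.5). Rates are mg CaCO₃ cm⁻² d⁻¹, normalized to tissue surface area and
calendar days (56 d assumed when dates are absent); negative rates (net
dissolution) are allowed. Species-specific weight→surface-area allometries
(SA = a W^b) are user-supplied configuration: no universal relation exists,
so absolute rates are only as good as the allometry provided.

## Abiotic-kinetics model (IpHRAC)

G = k_a(Ω_cf − 1)ⁿ with k_a = −0.0177T² + 1.47T + 14.9 and
n = 0.0628T + 0.0985 (T in °C; both positive over 15–32 °C). G is in model
rate units; `scale_to_data` provides a least-squares factor to align the
curve with measured rates. A degree-2 polynomial fit of calcification vs
Ω_cf is provided with R² and residuals; note that at Ω_cf ≈ 10–14 and rates
of 1–2 mg cm⁻² d⁻¹ the fitted quadratic coefficients are small and strongly
correlated — individual coefficients from six treatment means should not be
over-interpreted, and the package reports rather than canonicalizes them.

## Statistics

The experimental unit structure is treatment → header tank (4 per treatment,
where pH is controlled) → incubation tank (3 per header) → colony. The
two-stage analysis: (1) nested ANOVA with treatment fixed and header tank
random, using expected-mean-squares F ratios for the balanced layout — tank
MS over residual MS for the tank effect; treatment MS over tank MS while the
tank term is retained, over residual MS once dropped (both are reported,
since which denominator applies before dropping is a design choice). The
tank term is dropped when p > 0.25, the standard liberal pooling rule for
random blocking factors. (2) One-way ANOVA across treatments with Tukey HSD.
Sums of squares come from statsmodels OLS (sequential ANOVA); a constant
response short-circuits to the degenerate all-zero table rather than relying
on floating-point SS. Residual diagnostics never gate the pipeline
automatically. Under a true null the tank p-value is uniform, so the drop
rule retains the tank term in ~25% of null experiments by construction —
tests assert that rate, not an impossible near-certain drop.

## Synthetic-data generator

The generator emulates the raw colony-level data of a
2 species × 3 pH × 12 replicate experiment whose per-colony values are not
publicly deposited; treatment-level structure comes from the published
summaries:

* targets pH 8.09/7.81/7.63 with total observation jitter SD 0.05
  (header-tank offset SD 0.02 + within-tank SD 0.046), A_T ~ N(2358, 5)
  µmol kg⁻¹, T = 20.9–21.0 °C, S = 35.5;
* δ¹¹B from the species regressions on seawater pH (2.37 pH + 4.41;
  4.37 pH − 12.11) plus tank effect, colony noise and 0.17‰ analytical
  noise; B/Ca from the regressions on δ¹¹B (31.6 δ¹¹B − 124;
  25.8 δ¹¹B + 98.5) plus residual and 18 µmol mol⁻¹ analytical noise;
* calcification from the species × treatment means with colony SD = SE×√12
  (published SEs at n = 12); buoyant weights are back-computed through the
  density identity so the growth module recovers the target rates exactly;
* between-colony δ¹¹B SDs (0.50‰ and 0.85‰) are calibrated so pH_cf
  standard errors at n = 12 land on the published 0.01–0.02; the
  biological-vs-analytical variance partition is a modeling choice, as the
  true partition is not reported. Header-tank variance defaults to 10% of
  colony variance (tank effects were found negligible).

What it does **not** emulate: time-resolved pH-controller dynamics, light and
temperature covariates, non-linear pH_cf responses, day/night calcification
asymmetry, or any physiological covariance between calcification and
geochemistry. Passing parameter-recovery tests therefore demonstrates that
the pipeline is unbiased for data with this covariance structure — not that
real corals satisfy it.

## Problem sizes and determinism

Default problem sizes keep every stage at desk scale: 1000 Monte-Carlo
iterations per colony, 72 colonies per synthetic experiment, ~1000 seawater
observations, 20-seed recovery studies, and 100–400-replicate simulation
checks in the statistics tests. All RNG flows through
`numpy.random.default_rng` seeds; pipeline reruns with the same config are
byte-identical.

## Known limitations

* The proxy constants (δ¹¹B_sw, α, K_D calibration) are treated as exact
  unless explicitly perturbed; systematic proxy biases are not modelled.
* The B/Ca method inherits the inorganic-calibration assumption that boron
  partitioning in biogenic aragonite matches abiotic precipitation.
* Nested ANOVA covers the balanced case; strongly unbalanced designs should
  use a dedicated mixed-model (REML) framework instead.
* The CO₂ solver targets open-ocean-like salinities (validity ranges of the
  constant formulations); brackish or hypersaline tanks fall outside them.
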