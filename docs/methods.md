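# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hypoxphys`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
quoted from external data.

## Gas and unit conversions

Percent air saturation converts to PO₂ as
`percent/100 × 0.2095 × P_bar` (dry-gas form, the default) or with the
saturated water-vapor pressure at the water temperature subtracted from
`P_bar` first (`vapor_corrected=True`). The dry-gas default is chosen
because the canonical field conversion of 8% air saturation to
12.7 mmHg back-computes exactly under it (0.08 × 0.2095 × 760 = 12.74);
the corrected variant is provided for instruments that report
vapor-corrected saturations.

Oxygen solubility α (µmol L⁻¹ mmHg⁻¹) uses the García & Gordon (1992,
*Limnol. Oceanogr.* 37:1307) combined fit to the Benson & Krause data
(ml L⁻¹ coefficients, converted with the 22.3916 L mol⁻¹ real-gas
molar volume), divided by the saturation PO₂
0.2095 × (P_bar − p_H₂O(T)). Water-vapor pressure follows the
Benson & Krause (1984) correlation
ln p(atm) = 11.8571 − 3840.70/T − 216961/T². Validity is restricted to
0–40 °C and 0–42 psu; both correlations sit behind single functions so
they can be swapped. At 22 °C/35 psu the fit gives 222.9 µmol L⁻¹ and
α = 1.4375 µmol L⁻¹ mmHg⁻¹, pinned in the tests against hand
evaluation of the printed coefficients.

ṀO₂ unit conversion uses 32 g mol⁻¹ O₂ and 60 min h⁻¹
(1 µmol kg⁻¹ min⁻¹ = 1.92 mgO₂ kg⁻¹ h⁻¹); round trips are exact.

## Fish model and trace simulation

The simulated fish is an oxyregulator above its critical tension and a
linear conformer through the origin below it:

    ṀO₂(PO₂) = smr_true                         PO₂ ≥ pcrit_true
    ṀO₂(PO₂) = smr_true × PO₂ / pcrit_true      PO₂ < pcrit_true

The linear-through-origin conformer limb is the simplest model in which
"uptake falls below SMR" defines a unique crossing. Spontaneous
activity is a Poisson process (`activity_rate` events h⁻¹, exponential
durations of mean 1 min) during which uptake is multiplied by
`1 + activity_magnitude`; excursions are strictly non-negative so the
lowest-decile SMR estimator targets `smr_true` from below-free data.
Bursts are suppressed below the breakpoint (the fish is
oxygen-limited there). Chamber-level background respiration ramps
linearly in time between configured start and end rates, mirroring the
linear-in-time correction applied in analysis.

Closed phases integrate
dPO₂/dt = −[ṀO₂·M_f + background(t)] / [α·(V − M_f)] by explicit Euler
steps of 1 s (configurable). At these decline rates the Euler error is
orders of magnitude below measurement noise; the tests verify the
coarse integrator against the analytic conformer exponential and a
20×-finer step to within 0.2%. Flush phases relax PO₂ toward ambient
with a 0.3-min first-order time constant (no attempt to model mixing
dynamics). Gaussian noise of sd `noise_sd` is applied to the *sampled*
PO₂, not the state. Oxygen bookkeeping is conservative by
construction: the O₂ inferred from the PO₂ state change over a sealed
phase equals the time-integral of fish-plus-background consumption to
1e-6 relative (tested with bursts and background enabled). A step that
would drive PO₂ negative is clipped at zero and flagged.

Default study conditions: 91 g fish, 2.5 L chamber, 24 °C / 35 psu
water, 3 + 3 min flush/closed cycles, closed Pcrit runs terminated at
12.7 mmHg (8% air saturation). The chamber volume is a typical
respirometer-to-fish ratio (~27:1) for this body size.

## Respirometry estimators

Per closed cycle, an OLS line is fitted to the last 2 min of the PO₂
record (≥3 samples required); cycles with R² < 0.95 — or with constant
PO₂, whose R² is undefined — are flagged and excluded from SMR, never
silently dropped. ṀO₂ follows the uptake equation above with α from
the configured water conditions. Background correction subtracts the
linear-in-time interpolation between pre- and post-trial rates
(supplied in ṀO₂-equivalent units, i.e. chamber rate / fish mass);
records driven negative are flagged and de-retained. SMR is the mean of
the lowest ⌈0.10·n⌉ retained records (ceiling guarantees ≥1 record;
≥10 retained records required).

Pcrit partitions the continuous closed run into consecutive,
non-overlapping 2-min bins, each yielding an ṀO₂ against its mean PO₂.
The crossing belongs to the terminal run of below-SMR bins (robust to
isolated noisy dips). The crossing PO₂ is interpolated **on the
conformer limb**: an OLS line through the terminal below-SMR bins
(dropping the bin that straddles the breakpoint when ≥3 below-bins
exist) extrapolated up to ṀO₂ = SMR. The reason is structural: above
the breakpoint a regulator's ṀO₂ sits flat *at* SMR, so a two-point
interpolation between the bracketing bins degenerates to the last
above-bin's mean PO₂ and inherits a bias of order one bin-width; the
conformer limb carries the actual breakpoint information and the
limb-crossing is exact for a pure conformer. The two-point
interpolation remains the fallback when only one below-SMR bin exists,
and the conservative "mean PO₂ of the first below-SMR bin" variant is
always reported alongside. Runs that never drop below SMR are censored
at the minimum observed PO₂. Comparisons of ṀO₂ against SMR use a
1e-9 relative tolerance so a plateau sitting exactly at SMR is not
split by floating-point jitter.

Measured performance (test suite): zero-noise recovery of the
breakpoint is exact to <0.01 mmHg across 28–45 mmHg; at 0.5 mmHg
sampling noise the median absolute error over 100 seeded runs is
≈1.4 mmHg. Breakpoints within ~one bin of the 12.7 mmHg stop threshold
leave too little conformer limb and degrade gracefully toward the
two-point fallback.

## Hemoglobin–O₂ equilibria

Saturation is normalized between the 0% (deoxy) and 100% (oxy)
absorbance plateaus, S = (A − A₀)/(A₁₀₀ − A₀); the fit is therefore
invariant to affine rescaling of absorbance (tested). In the generator
the two reference steps are pinned to S = 0 and S = 1 exactly — at
~740 mmHg any real hemoglobin is fully saturated even though the Hill
formula is asymptotic — which anchors the normalization and makes the
zero-noise round trip exact.

The Hill fit regresses log₁₀(S/(1−S)) on log₁₀PO₂ over points with S
strictly inside a saturation window, default (0.2, 0.8): the classic
central window avoiding the curvature the two-state Hill approximation
shows at the extremes. P50 = 10^(−intercept/slope); the slope is
reported as n_H; a direct linear interpolation of the S = 0.5 crossing
is attached as a diagnostic. The window is configurable and logged: on
the sparse 15-step assay ladder (0, 0.05, …, 21, 100% O₂) the central
window can leave <3 points at acid pH where P50 is large, so the
study-scale pipeline widens it to (0.1, 0.9). Zero-noise fits are
window-invariant (the transformed model is exactly linear); with
absorbance noise at 1% of the dynamic range, P50 is recovered within
5% in >90% of 100 seeded replicates.

%O₂→PO₂ conversion for tonometry gas subtracts water-vapor pressure by
default (gas equilibrated with an aqueous sample is humidified); the
dry variant exists for cross-checks.

The Bohr coefficient is the OLS slope of log₁₀P50 on pH over all
(pH, P50) pairs — identical to Δlog₁₀P50/ΔpH for two points — with all
pairwise two-point coefficients also reported, since three-level
designs are commonly summarized per pH range.

## qPCR expression

Amplification efficiency comes from a dilution standard curve:
E = 10^(−1/m) with m the OLS slope of ct on log₁₀(input); positive
slopes are rejected. Fold changes default to the Pfaffl-style ratio

    fold = E_gene^−(ct_gene − mean ct_gene,ctrl) / E_ref^−(ct_ref − mean ct_ref,ctrl)

which corrects target and reference with their own measured
efficiencies and is exactly invariant to per-sample loading offsets
(tested); the single-efficiency form (`target_only`) and classic
2^−ΔΔct (`classic`) are available, and all three coincide at E = 2.
Relative abundance within a sample is E_anchor^ct_anchor / Eₙ^ctₙ, so
the anchor's self-abundance is 1 in every sample and a 6-cycle
separation at E = 2 is exactly 64-fold. Undetectable transcripts are
carried as missing values, listed in output and excluded from
statistics — never imputed. Group summaries are mean ± SEM.

The ct generator writes ctₙ = c_n − log_{Eₙ}(abundance × fold × load)
with the per-gene intercept c_n chosen so Eₙ^{c_n} is a shared
constant (2³⁰, i.e. ~30 cycles at E = 2); this makes zero-noise tables
invert exactly under the anchored-abundance formula while per-sample
lognormal loading offsets cancel in both estimators.

## Gill morphometrics

Total filament length reconstructs a length profile from every-10th
samples by linear interpolation across filament positions with constant
end-extrapolation, L = n_filaments × mean(profile); the plain-mean
variant is reported as a diagnostic (the two coincide for flat
profiles, and the interpolated form tracks a linear taper to <1% when
sampling covers the arch). A single sampled filament falls back to
n × length, flagged low-confidence. Lamellar frequency is
f = 2/mean(spacing) (both sides); a direct count per mm can be supplied
unchanged. A = L·f·B with B the mean bilateral lamellar area;
mass-specific area is A/body mass. Diffusion distance averages
per-image means across images (the image is the sampling unit for a
per-fish estimate), with the pooled mean emitted for comparison.

The generator draws lengths, spacings and areas with multiplicative
unit-mean noise around values whose product equals the target area
exactly; at spacing CV 0.1 the Monte-Carlo mean over 200 replicates is
within 2% of truth (the small bias is Jensen's inequality on
2/mean(spacing)).

## Statistics

Unpaired comparisons default to Welch's t (pooled-variance classic form
via `equal_var=True`); paired designs require complete pairs; one-tailed
p-values require an explicit direction. Zero-variance degeneracies are
resolved by convention and flagged: identical constant groups give
p = 1, a constant non-zero paired difference gives p = 0. Two-way ANOVA
is fixed-effects with interaction through statsmodels OLS/anova_lm;
balanced designs reproduce the classical decomposition (SS conservation
tested to 1e-9), unbalanced designs use Type-II sums of squares — the
standard choice when the interaction is not of primary interest. Both
test families hold their nominal 5% type-I error within ±2 percentage
points over 1000 null simulations. No multiple-testing correction is
applied across transcripts by default; a Benjamini–Hochberg helper
exists but is off.

## Study pipeline

`run_study` simulates the full two-treatment design (7 fish per group;
pre/post Pcrit with the per-individual SMR measured immediately prior;
P50 at three pH levels per treatment; a 7 + 7 ct table; per-fish
morphometry) and runs every estimator plus the comparison layer. All
randomness derives from one master seed via spawned seed sequences;
reports are byte-identical across repeated runs. Between-fish spread is
applied as seeded draws re-centered so group means equal the configured
truth exactly (the recovery target is then sharp). Desk-scale defaults
keep the full study under ~1 min on one CPU: 6-h SMR traces in the
study pipeline (2-h in the zero-noise recovery protocol, where SMR is
exact anyway); the 20-h trace condition is exercised directly in the
SMR-recovery acceptance test.

Generator truth values with no printed source are set to
field-realistic magnitudes and documented here: P50 at pH 7.4 of
20 mmHg (normoxia) vs 17 mmHg (hypoxia), n_H = 1.8, φ = −0.45, hypoxia
fold changes of 8× (Hbα-3.2) and 4× (Hbα-2), trace noise 0.2 mmHg,
activity bursts 12 h⁻¹ doubling SMR, between-fish CV 8%.

## What the synthetic data do not capture

The generator emulates the *structure* of the real measurements, not
their full pathology: no flush-phase mixing dynamics, temperature
drift, electrode drift or instrument artifacts; conformer behaviour is
exactly linear below the breakpoint; activity bursts are a stationary
Poisson stand-in, not a behavioural model; absorbance noise is
homoscedastic; methemoglobin formation, Root effects and NTP modulation
of P50 are out of scope. Passing recovery tests therefore demonstrates
estimator correctness under the stated model, not robustness to every
field artifact. Real-data idiosyncrasies (non-linear background growth,
partial conformity above Pcrit) should be expected to widen the error
bands reported above.
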