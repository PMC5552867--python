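# hypoxphys

Analysis toolkit for hypoxia-acclimation physiology in fish: how a
marine teleost adjusts its oxygen-transport system after weeks at low
ambient PO₂. The package covers the four quantitative layers such a
study touches, plus a synthetic-data generator that makes every stage
verifiable by parameter recovery:

* **Intermittent-flow respirometry** — oxygen uptake from closed-phase
  PO₂ declines,

  ṀO₂ = −δPO₂ · αO₂ · (V_chamber − M_f) / M_f  [µmol kg⁻¹ min⁻¹],

  with an R² ≥ 0.95 retention filter, linear-in-time background
  subtraction, standard metabolic rate (SMR) as the mean of the lowest
  10% of uptake records, and the critical oxygen tension (Pcrit) as the
  PO₂ where binned ṀO₂ drops below SMR in a continuous closed decline.
* **Hemoglobin–O₂ equilibria** — absorbance plateaus at a %O₂ gas
  ladder normalized to fractional saturation, Hill plots
  log₁₀(S/(1−S)) vs log₁₀PO₂, P50 = 10^(−intercept/slope), Hill
  coefficient n_H, and Bohr coefficients φ = Δlog₁₀P50/ΔpH across
  hemolysates at pH 7.0/7.4/7.8.
* **qPCR expression** — efficiency-corrected ΔΔCt fold changes
  (Pfaffl-style, per-primer E from dilution standard curves,
  E = 10^(−1/slope)) against an ef1α internal control, and
  within-sample relative abundance of hemoglobin subunit isoforms,
  abundanceₙ = E_anchor^ct_anchor / Eₙ^ctₙ.
* **Gill morphometrics** — Hughes surface area A = L·f·B (total
  filament length × both-sides lamellar frequency × mean bilateral
  lamellar area), mass-standardized, plus hierarchical blood-to-water
  diffusion-distance summaries.
* **Group statistics** — Welch/pooled and paired t-tests (one- and
  two-tailed) and two-way fixed-effects ANOVA with interaction
  (Type-II SS when unbalanced).

Water-side conversions (% air saturation ↔ PO₂, O₂ solubility from the
García–Gordon temperature–salinity fit) live in `hypoxphys.gas`.

## Worked example

`examples/respirometry_smr_pcrit.py` simulates a 91 g fish
(SMR 151 mgO₂ kg⁻¹ h⁻¹, Pcrit 36.2 mmHg) in a 2.5 L chamber with
spontaneous activity bursts and 0.2 mmHg sampling noise, then runs the
full analysis chain:

```
retained MO2 records : 60 of 60
SMR                  : 77.06 umol kg-1 min-1 (148.0 mgO2 kg-1 h-1; true 151.0)
Pcrit (interpolated) : 35.4 mmHg (true 36.2)
Pcrit (first bin <SMR): 33.6 mmHg
```

The SMR lands within 2% of the configured quiescent rate despite the
activity bursts (the lowest-decile estimator sees only quiet cycles),
and both Pcrit variants bracket the true breakpoint to within a
fraction of one 2-min bin. The other scripts in `examples/` walk
through the hemoglobin (P50/Bohr), qPCR, gill, and whole-study
(`run_study`) capabilities the same way.

A thin CLI mirrors the library for shell use:
`hypoxphys resp|hb|qpcr|gill|run|write-config` (see `--help`).

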