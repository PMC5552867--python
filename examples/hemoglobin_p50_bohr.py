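"""Fit Hill plots and a Bohr coefficient for one hemolysate.

Simulates absorbance-vs-%O2 equilibrium curves at pH 7.0 / 7.4 / 7.8
(the assay's 15-step gas ladder), normalizes them to saturation, fits
log10(S/(1-S)) vs log10(PO2), and regresses log10(P50) on pH.
"""

from hypoxphys import hb, synth

curves = synth.simulate_oec_plate(
    p50_at_ph74=20.0,   # mmHg
    hill_n=1.8,
    bohr_phi=-0.45,     # d log10 P50 / d pH
    noise_sd=0.004,     # ~1% of the absorbance dynamic range
    seed=3,
)

fits = []
for curve in curves:
    fit = hb.fit_curve(curve, window=(0.1, 0.9))
    fits.append((curve.ph, fit))
    print(f"pH {curve.ph:.1f}: P50 = {fit.p50:5.2f} mmHg, "
          f"n_H = {fit.slope:.2f}, r^2 = {fit.r_squared:.4f}")

bohr = hb.bohr_coefficient(fits)
print(f"Bohr coefficient phi = {bohr.phi:.3f} (true -0.450)")
print(f"pairwise: {{(7.0,7.4): {bohr.pairwise[(7.0, 7.4)]:.3f}, "
      f"(7.4,7.8): {bohr.pairwise[(7.4, 7.8)]:.3f}}}")
# P50 is the PO2 at half saturation (lower = higher O2 affinity); the
# negative phi quantifies the normal Bohr effect -- affinity falls as
# the hemolysate acidifies.
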