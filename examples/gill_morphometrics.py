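"""Hughes-method gill surface area and diffusion distance for one fish.

Simulates a first-gill-arch measurement set (every-10th filament
lengths, interlamellar spacings, bilateral lamellar areas, 15 images of
blood-to-water diffusion distance) and computes A = L * f * B.
"""

from hypoxphys import gill, synth

morph = synth.simulate_morphometry(
    true_area_per_mass=348.9,  # mm2 g-1
    mass=91.0,                 # g
    spacing_cv=0.1,
    seed=5,
)
res = gill.gill_area(morph)

print(f"total filament length L : {res.total_filament_length:.1f} mm")
print(f"lamellar frequency f    : {res.lamellar_frequency:.2f} mm-1 (both sides)")
print(f"mean bilateral area B   : {res.mean_bilateral_area:.4f} mm2")
print(f"total area A = LfB      : {res.total_area:.0f} mm2")
print(f"mass-specific area      : {res.mass_specific_area:.1f} mm2 g-1 (true 348.9)")
print(f"diffusion distance      : {res.diffusion_distance_um:.2f} "
      f"+/- {res.diffusion_sem_um:.2f} um")
# The Hughes product decomposes gill area into how much filament there
# is, how densely lamellae are packed on it, and how large each lamella
# is; mass standardization makes fish of different sizes comparable.
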