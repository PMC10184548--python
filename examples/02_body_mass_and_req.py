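"""Body mass and encephalisation quotient for the Baryonyx holotype.

From the minimum femoral circumference (350 mm) the bipedal allometry gives
body mass; combining that with the endocast volume (150.487 cm^3) at the
conventional 37% and 50% brain-fill fractions gives the reptile
encephalisation quotient (REQ), where REQ = 1 means a brain exactly as
large as expected for a reptile of that body mass.
"""

from paleoneuro import body_mass_bipedal, encephalization

mass = body_mass_bipedal(350.0)
print(f"body mass from 350 mm femoral circumference: {mass.mass_kg:.0f} kg")

for fill in (0.37, 0.50):
    res = encephalization(150.487, mass.mass_g, fill)
    print(
        f"fill {fill:.0%}: brain mass {res.MBr:5.1f} g  ->  REQ {res.REQ:.2f}"
    )
# ~2011 kg and REQ between ~1.2 and ~1.6: a brain moderately above the
# reptilian expectation, in line with other large non-coelurosaurian
# theropods.
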