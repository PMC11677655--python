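"""Classify an essential oil's headspace into olfactory families.

Loads the packaged GC-MS composition of steam-distilled marcela
(A. satureioides) essential oil and its compound property table,
predicts the equilibrium headspace by the ideal-solution (Raoult)
approximation at 25 degC, scores each compound's odor value
OV = C / ODT, and prints the normalized eight-family radar profile.
"""

from nanoaroma import load_oil_composition, load_oil_properties, radar_from_composition

composition = load_oil_composition()
registry = load_oil_properties()

report = radar_from_composition(composition, registry)

print("normalized odor value per olfactory family (sums to 1):")
for family, value in report.profile.values.items():
    bar = "#" * round(40 * value)
    print(f"  {family:9s} {value:6.4f} {bar}")
print(f"dominant family: {', '.join(report.profile.argmax_families())}")
print(f"\ncompounds scored: {[r.compound for r in report.records]}")
print(f"excluded (no threshold / trace / unregistered): {len(report.excluded)}")
# A value of e.g. 0.69 for "woody" means 69% of the total perceived
# odor intensity of the headspace falls in the woody family.
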