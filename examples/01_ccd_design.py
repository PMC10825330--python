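"""Generate the four-factor central composite circumscribed design.

Builds the 30-run design (16 factorial + 8 axial + 6 center points) for
ultrasonic power, temperature, solvent-to-solid ratio and ethanol
concentration, with the tabulated factor extremes placed at the axial
points (coded +-2).
"""

from uaextract import generate_ccd
from uaextract.fixtures import load_factors

factors = load_factors()
design = generate_ccd(factors, n_center=6)

print(f"runs: {len(design.data)}")
print(design.data["point_class"].value_counts().to_string())
print()
print(design.data.head(5).to_string(index=False))
print()
print("Each row is one extraction experiment; coded_* are dimensionless")
print("design coordinates, natural_* the machine settings to run it at.")
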