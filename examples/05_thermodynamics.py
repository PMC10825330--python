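"""Arrhenius and Van't Hoff analysis of the published kinetic parameters.

Chains the tabulated rate constants into an activation energy and the
saturation concentrations into the equilibrium constant Ke = Cs/(Cmax-Cs),
whose temperature dependence yields dH, dS and dG(T).
"""

import numpy as np

from uaextract import arrhenius_fit, celsius_to_kelvin, equilibrium_constant, gibbs, vant_hoff_fit
from uaextract.fixtures import KINETIC_PARAMS, KINETIC_TEMPERATURES_C, RESPONSE_RANGES

t_c = np.array(KINETIC_TEMPERATURES_C)
t_k = celsius_to_kelvin(t_c)

ks = [KINETIC_PARAMS["YA"][t][0] for t in t_c]
arr = arrhenius_fit(t_k, ks)
print(f"antioxidant activity: Ea = {arr.ea / 1000:.3f} kJ/mol (R2 = {arr.r2:.4f})")

cs = np.array([KINETIC_PARAMS["YP"][t][2] for t in t_c])
cmax = RESPONSE_RANGES["YP"][1]
ke = [equilibrium_constant(c, cmax) for c in cs]
vh = vant_hoff_fit(t_k, ke)
print(f"phenolics: dH = {vh.dh / 1000:.2f} kJ/mol, dS = {vh.ds:.1f} J/(mol K)")
for t in t_c:
    dg = gibbs(vh.dh, vh.ds, float(celsius_to_kelvin(t))) / 1000
    print(f"  dG({t:.0f} degC) = {dg:+.3f} kJ/mol")
print()
print("Positive dH: extraction is endothermic; negative dG that falls with")
print("temperature: spontaneous, and increasingly favourable when heated.")
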