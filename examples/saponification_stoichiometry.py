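"""How much KOH does full saponification need, and how much K does it add?

The saponification value (SV, mg KOH per g oil) fixes the stoichiometric
KOH demand; the potassium retained in the dried saponified product caps how
much substrate a fermentation can tolerate (growth of C. necator is
inhibited at about 20 g K/L).
"""

import phakinetics as pk

SV_OIL = 175.7          # mg KOH / g SCG oil
OIL_LOADING = 100.0     # g oil per L reagent (1 g per 10 mL)

molarity = pk.minimum_koh_molarity(SV_OIL, OIL_LOADING)
print(f"minimum KOH for complete saponification: {molarity:.3f} mol/L")

assay = pk.SaponificationAssay(sv_sample=93.82, sv_oil=SV_OIL)
print(f"extent at the mildest tested condition : "
      f"{pk.extent_of_saponification(assay):.1f} %")

sap = pk.get_composition("scg_saponified")
max_oil = pk.substrate_for_potassium(20.0, sap)
print(f"saponified oil reaching 20 g K/L       : {max_oil:.0f} g/L "
      "(the potassium-limited feed ceiling)")

# carbon parity with a 900 g/L sucrose fed-batch (sucrose is 44.11% C)
oil_for_sucrose_c = pk.substrate_for_carbon(900 * 0.4411, sap)
k_added = pk.potassium_loading(oil_for_sucrose_c, sap)
print(f"oil matching 900 g/L sucrose carbon    : {oil_for_sucrose_c:.0f} g/L, "
      f"adding {k_added:.1f} g K/L - far beyond the inhibitory ceiling")
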