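"""Where does growth peak, and where does it stop?

Evaluates the fitted Han-Levenspiel parameter sets for Cupriavidus necator
DSM 545 on crude and saponified spent-coffee-ground (SCG) oil, locates the
carbon concentration of maximum specific growth rate, and converts carbon
optima back to oil masses a practitioner would weigh out.
"""

import phakinetics as pk

crude_params = pk.CRUDE_SCG_ESTIMATES["han_levenspiel"]
sap_params = pk.SAPONIFIED_SCG_ESTIMATES["han_levenspiel"]
crude_oil = pk.get_composition("scg_crude")
sap_oil = pk.get_composition("scg_saponified")

peaks = {}
for label, params, comp in (("crude", crude_params, crude_oil),
                            ("saponified", sap_params, sap_oil)):
    c_peak, mu_peak = pk.find_peak(params)
    c_crit = pk.critical_concentration(params)
    call = pk.classify_inhibition(params["n"], params["m"])
    peaks[label] = c_peak
    print(f"{label} SCG oil:")
    print(f"  peak mu         = {mu_peak:.3f} 1/h at C0 = {c_peak:.2f} g C/L "
          f"({pk.substrate_for_carbon(c_peak, comp):.2f} g oil/L)")
    print(f"  growth ceases   at C0 = {c_crit:.2f} g C/L "
          f"({pk.substrate_for_carbon(c_crit, comp):.1f} g oil/L)")
    print(f"  inhibition type = {call.label} (n={params['n']}, m={params['m']})")

mid = 0.5 * (peaks["crude"] + peaks["saponified"])
print(f"\nmidpoint of the two optima: C0 = {mid:.2f} g C/L "
      "(the operating point used for blend cultivations)")
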