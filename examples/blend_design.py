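"""Design a crude/saponified oil blend for a target carbon loading.

Splits a total carbon loading between crude oil (cheap, but slow to become
bioavailable) and saponified oil (immediately consumable fatty-acid salts)
at a chosen carbon ratio, returning the oil masses to weigh in.
"""

import phakinetics as pk

spec = pk.BlendSpec(total_c0=9.57, crude_c_share=0.75)
blend = pk.design_blend(spec, n0=0.57)

print(f"target carbon loading : {blend['total_c0']} g C/L "
      f"({spec.crude_c_share:.0%} from crude oil)")
print(f"crude SCG oil         : {blend['crude_conc']:.2f} g/L")
print(f"saponified SCG oil    : {blend['saponified_conc']:.2f} g/L")
print(f"initial C/N ratio     : {blend['c_to_n']:.1f} g/g "
      "(nitrogen limitation above ~15 drives PHA accumulation)")

# sanity: the components carry exactly the requested carbon
carbon = (pk.carbon_loading(blend["crude_conc"], spec.crude_composition)
          + pk.carbon_loading(blend["saponified_conc"], spec.saponified_composition))
print(f"carbon balance check  : {carbon:.4f} g C/L")
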