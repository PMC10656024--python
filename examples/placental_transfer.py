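"""Simulate a term pregnancy and report subclass-specific IgG transfer.

The five-compartment model transports the four IgG subclasses from
maternal blood across syncytiotrophoblasts and fetal endothelial cells
into fetal blood.  Subclasses compete for the shared FcRn and FcgRIIb
pools, so transfer efficiency (the F:M ratio) differs by subclass.
"""

from placigg import default_parameters, simulate, subclass_entropy

params = default_parameters()
result = simulate(params, t_end=40.0)

print("Fetal IgG at 40 weeks (per subclass):")
for name, fetal, fm in zip(
    result.species_names, result.fetal_at_end(), result.fm_at_end()
):
    print(f"  {name}: {fetal:.3e} M   F:M = {fm:.3f}")

print(f"Total fetal IgG: {result.total_fetal()[-1]:.3e} M")
print(f"Subclass entropy: {subclass_entropy(result.fetal_at_end()):.4f}")
print()
print("The F:M ordering IgG1 > IgG3 > IgG4 > IgG2 is the transfer")
print("hierarchy most commonly reported in human cohorts; entropy below")
print("ln(4) ~ 1.386 quantifies how selective the placental sieve is.")
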