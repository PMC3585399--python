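# Conventional real single-ion hydration free energies (Schmid, Miah & Sapunov,
# Phys Chem Chem Phys 2000), the parameterisation targets of the
# Joung-Cheatham ion set used here. kcal/mol.
species,dG_hydr_kcal_mol
Li,-113.5
Na,-87.2
K,-70.5
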