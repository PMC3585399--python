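# Nonbonded parameter table: ions (Joung-Cheatham monovalent set, TIP3P variant)
# and dipolar-ligand atom types (transcribed from a standard all-atom protein
# force field; Lorentz-Berthelot combining).
# columns: name, element, charge_e, epsilon_kcal_mol, sigma_A, mass_amu
name,element,charge_e,epsilon_kcal_mol,sigma_A,mass_amu
LI,Li,1.0,0.0279896,1.826342,6.941
NA,Na,1.0,0.0874393,2.439281,22.98977
K,K,1.0,0.1936829,3.037965,39.0983
FC,C,0.50,0.110,3.563595,12.011
FO,O,-0.50,0.120,3.029056,15.9994
FH,H,0.00,0.022,2.351973,1.008
BC,C,0.51,0.110,3.563595,12.011
BO,O,-0.51,0.120,3.029056,15.9994
BH,H,0.00,0.022,2.351973,1.008
HC,C,0.23,0.055,3.875409,12.011
HO,O,-0.66,0.1521,3.153781,15.9994
HH,H,0.43,0.046,0.400013,1.008
XB,C,-0.10,0.055,3.875409,12.011
XC,C,0.62,0.070,3.563595,12.011
XO,O,-0.76,0.120,3.029056,15.9994
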