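# Harmonic bonded parameters under the 1/2*k*(x-x0)^2 convention.
# bond: ref in Angstrom, k in kcal/mol/A^2; angle: ref in degrees, k in kcal/mol/rad^2.
# columns: kind, a, b, c (blank for bonds), ref, k
kind,a,b,c,ref,k
bond,FC,FO,,1.230,1240.0
bond,FC,FH,,1.110,644.0
angle,FO,FC,FH,121.7,100.0
angle,FH,FC,FH,116.5,110.0
bond,BC,BO,,1.230,1240.0
bond,BC,BH,,1.110,644.0
angle,BO,BC,BH,121.7,100.0
angle,BH,BC,BH,116.5,110.0
bond,HC,HO,,1.420,856.0
bond,HO,HH,,0.960,1090.0
angle,HC,HO,HH,106.0,115.0
bond,XB,XC,,1.520,445.0
bond,XC,XO,,1.260,1050.0
angle,XB,XC,XO,118.0,80.0
angle,XO,XC,XO,124.0,200.0
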