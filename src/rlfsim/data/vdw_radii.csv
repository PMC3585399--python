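# Bondi van der Waals radii used for occupancy-grid volumes.
element,radius_A
H,1.20
C,1.70
O,1.52
Li,1.82
Na,2.27
K,2.75
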