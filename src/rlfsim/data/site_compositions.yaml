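# Ligand composition of the four transporter-site dipolar models.
# Labels are residue:fragment; "carboxylate" contributes two coordinating
# oxygens (bidentate).
LeuT_Na1:
  - "LEU:carboxylate"
  - "ALA22:carbonyl"
  - "ASN27:carbonyl"
  - "THR254:carbonyl"
  - "THR254:hydroxyl"
  - "ASN:carbonyl"
LeuT_Na2:
  - "GLY20:carbonyl"
  - "VAL23:carbonyl"
  - "ALA351:carbonyl"
  - "THR354:hydroxyl"
  - "SER355:hydroxyl"
Glt_Na1:
  - "GLY306:carbonyl"
  - "ASN310:carbonyl"
  - "ASN401:carbonyl"
  - "ASP405:carboxylate"
Glt_Na2:
  - "THR308:carbonyl"
  - "ILE309:carbonyl"
  - "SER349:carbonyl"
  - "ILE350:carbonyl"
  - "THR352:carbonyl"
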