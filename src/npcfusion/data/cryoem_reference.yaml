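# Reference geometry of the Nup96 SNAP-tag positions derived from the
# cryo-EM model of the human NPC (fluorophore-attachment sites of the
# benzylguanine-AF647 conjugate, expressed in the six-parameter
# eight-fold-symmetric ring model).  Units: nm and degrees.
version: 1
ring_separation_nm: 57.2
rings:
  NR:
    R_nm: 54.2
    psi_deg: 0.0
    c1z_nm: 28.6
    d_nm: 11.8
    theta_deg: 76.8
    phi_deg: -32.6
  CR:
    R_nm: 54.2
    psi_deg: 0.0
    c1z_nm: -28.6
    d_nm: 11.8
    theta_deg: 76.8
    phi_deg: 32.1
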