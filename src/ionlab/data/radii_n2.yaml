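# Per-element collision radii (Angstrom) for projection-approximation CCS
# in N2 drift gas, plus the N2 probe radius added to every atomic radius.
# These are editable configuration values for hard-sphere projections, not
# fitted ground truth; halogen values follow van-der-Waals-scale radii.
probe_radius: 1.00
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  F: 1.47
  P: 1.80
  S: 1.80
  Cl: 1.75
  Br: 1.85
  I: 1.98
  Na: 2.27
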