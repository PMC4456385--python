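# Sigmoid gain constants (c1, c2, c3) for the three MSN pools, in the two
# contexts where gains are evaluated: "learning" (cortico-striatal weight
# updates, driven by the TD error) and "selection" (direct/indirect pathway
# gating, driven by the utility-difference signal).
#
# Midpoints and slopes express each pool's functional role: the D1 gain
# rises with dopamine (value/Go), the D2 gain falls with dopamine and is
# positive for negative prediction errors (punishment/NoGo, mirroring D1),
# and the co-expressing pool's gain is a U-shape in the dopamine signal
# (risk), steep enough to be operative over the signal's working range.
learning:
  D1:  {c1: 1.0,  c2: -50.0, c3: 0.0}
  D2:  {c1: 1.0,  c2: 50.0,  c3: 0.05}
  hD1: {c1: 0.05, c2: -50.0, c3: -0.05}
  hD2: {c1: 0.05, c2: 50.0,  c3: 0.05}
selection:
  D1:  {c1: 1.0,  c2: -50.0, c3: 0.01}
  D2:  {c1: 1.0,  c2: 50.0,  c3: -0.01}
  hD1: {c1: 0.05, c2: -50.0, c3: -0.05}
  hD2: {c1: 0.05, c2: 50.0,  c3: 0.05}
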