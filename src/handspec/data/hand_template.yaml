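# Standard-proportion hand pattern (dorsal view, upright pose: fingers
# toward row 0, thumb side at the smaller column).  Coordinates are
# fractions of the target frame; finger lengths are fractions of the frame
# height, widths fractions of the frame width.  Derived from common adult
# hand anthropometry: middle finger ~0.30 of the framed hand height,
# index/ring slightly shorter, little finger ~0.22, thumb short and lateral.
relative: true
tips:
  - {row: 0.300, col: 0.220}   # V_w1 pollex
  - {row: 0.165, col: 0.375}   # V_w2 index
  - {row: 0.130, col: 0.500}   # V_w3 digitus medius
  - {row: 0.160, col: 0.625}   # V_w4 digitus annularis
  - {row: 0.230, col: 0.760}   # V_w5 digitus minimus
wrist: {row: 0.720, col: 0.500}
finger_lengths: [0.200, 0.270, 0.300, 0.275, 0.220]
finger_widths: [0.075, 0.060, 0.062, 0.058, 0.050]
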