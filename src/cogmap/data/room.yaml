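# Reference virtual-room configuration.
#
# A square room of side 2 (room units). Eight camera positions (places) sit on
# the perimeter: the four corners and the four side midpoints. Views are the
# same eight locations, used as camera targets. Eight landmarks hang on the
# walls, two per wall. Compass north is +y; bearings increase clockwise
# (N=0, E=90, S=180, W=270).
#
# The 32 snapshots are a constrained reconstruction of the published stimulus
# map (only shown graphically in the source study): the set honours the two
# printed exemplar labels (P1->V6 heads South; P6->V8 heads East), every
# place/view/heading occurs, place and view counts stay within 3-5, and the
# pairwise change statistics reproduce the reported heading/place and
# heading/view collinearity.
side_length: 2.0
fov: [74.0, 59.0]
places:
  P1: [1.0, 2.0]   # north side midpoint
  P2: [2.0, 2.0]   # north-east corner
  P3: [2.0, 1.0]   # east side midpoint
  P4: [0.0, 2.0]   # north-west corner
  P5: [0.0, 1.0]   # west side midpoint
  P6: [1.0, 0.0]   # south side midpoint
  P7: [0.0, 0.0]   # south-west corner
  P8: [2.0, 0.0]   # south-east corner
landmarks:
  L1: [0.5, 2.0]   # north wall
  L2: [1.5, 2.0]   # north wall
  L3: [2.0, 1.5]   # east wall
  L4: [2.0, 0.5]   # east wall
  L5: [1.5, 0.0]   # south wall
  L6: [0.5, 0.0]   # south wall
  L7: [0.0, 0.5]   # west wall
  L8: [0.0, 1.5]   # west wall
snapshots:
  - [P1, V2]
  - [P1, V3]
  - [P1, V4]
  - [P1, V5]
  - [P1, V6]
  - [P2, V1]
  - [P2, V4]
  - [P2, V8]
  - [P3, V2]
  - [P3, V4]
  - [P3, V6]
  - [P3, V7]
  - [P3, V8]
  - [P4, V1]
  - [P4, V2]
  - [P4, V7]
  - [P5, V1]
  - [P5, V4]
  - [P5, V6]
  - [P5, V7]
  - [P5, V8]
  - [P6, V2]
  - [P6, V3]
  - [P6, V5]
  - [P6, V7]
  - [P6, V8]
  - [P7, V4]
  - [P7, V5]
  - [P7, V8]
  - [P8, V2]
  - [P8, V3]
  - [P8, V7]
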