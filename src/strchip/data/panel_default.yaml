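# Default STR authentication panel: nine murine tetranucleotide loci plus the
# human sentinel D8S1106, distributed over four multiplex sets so that size
# windows within a set never overlap and no well carries more than three
# markers.  Predicted amplicon sizes span 130-515 bp.  Window bounds and flank
# offsets are panel design parameters (override via a custom config); each
# window is wide enough to contain every published reference allele.
#
# Ladder rungs and internal-marker sizes follow the DNA-1000 chip convention
# (sizing range 25-1000 bp, lower/upper alignment markers at 15 and 1500 bp).

ladder_sizes_bp: [25, 50, 100, 150, 200, 300, 400, 500, 700, 850, 1000]
lower_marker_bp: 15
upper_marker_bp: 1500

loci:
  - {name: "18-3",    species: mouse, repeat_unit_bp: 4, flank_offset_bp: 90,  size_range_bp: [130, 190], multiplex_set: 1}
  - {name: "4-2",     species: mouse, repeat_unit_bp: 4, flank_offset_bp: 140, size_range_bp: [196, 260], multiplex_set: 1}
  - {name: "6-7",     species: mouse, repeat_unit_bp: 4, flank_offset_bp: 210, size_range_bp: [266, 330], multiplex_set: 1}
  - {name: "9-2",     species: mouse, repeat_unit_bp: 4, flank_offset_bp: 100, size_range_bp: [148, 212], multiplex_set: 2}
  - {name: "D8S1106", species: human, repeat_unit_bp: 4, flank_offset_bp: 240, size_range_bp: [280, 340], multiplex_set: 2}
  - {name: "6-4",     species: mouse, repeat_unit_bp: 4, flank_offset_bp: 120, size_range_bp: [168, 232], multiplex_set: 3}
  - {name: "15-3",    species: mouse, repeat_unit_bp: 4, flank_offset_bp: 250, size_range_bp: [310, 370], multiplex_set: 3}
  - {name: "12-1",    species: mouse, repeat_unit_bp: 4, flank_offset_bp: 84,  size_range_bp: [136, 192], multiplex_set: 4}
  - {name: "5-5",     species: mouse, repeat_unit_bp: 4, flank_offset_bp: 180, size_range_bp: [220, 280], multiplex_set: 4}
  - {name: "X-1",     species: mouse, repeat_unit_bp: 4, flank_offset_bp: 303, size_range_bp: [355, 515], multiplex_set: 4}
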