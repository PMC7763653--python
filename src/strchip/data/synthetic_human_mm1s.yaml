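# SYNTHETIC stand-in profile for the human MM.1S myeloma line, used in
# cross-contamination simulations.  MM.1S amplifies only the human sentinel
# locus D8S1106 in this panel; its true D8S1106 genotype is not published with
# the reference profiles, so the allele pair below is an invented placeholder
# inside the panel's D8S1106 window.

"MM.1S":
  "D8S1106": [14, 17]
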