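# Published reference STR profiles (repeat counts per locus) of six primary
# murine cell lines: three HoxB8-FL hematopoietic progenitor lines (#1
# wild-type, #2 Iu-HA-Bcl6, #3 Cxcr4-WHIM) and three Kras-driven pancreatic
# ductal adenocarcinoma (mPDAC) lines.  Single values are printed as one
# allele; duplicated entries (mPDAC95 at 4-2, "19, 19") are normalised to a
# single value on ingest.

"#1_HoxB8FL":
  "18-3": [16]
  "4-2": [19]
  "6-7": [19]
  "9-2": [17]
  "15-3": [22]
  "6-4": [19]
  "12-1": [15]
  "5-5": [16]
  "X-1": [23]
"#2_HoxB8FL":
  "18-3": [15]
  "4-2": [18]
  "6-7": [15, 18]
  "9-2": [15]
  "15-3": [20]
  "6-4": [18]
  "12-1": [16]
  "5-5": [17]
  "X-1": [24]
"#3_HoxB8FL":
  "18-3": [16]
  "4-2": [19]
  "6-7": [19]
  "9-2": [15]
  "15-3": [22]
  "6-4": [19]
  "12-1": [16]
  "5-5": [17]
  "X-1": [24]
"mPDAC06":
  "18-3": [17, 18]
  "4-2": [18]
  "6-7": [20]
  "9-2": [16]
  "15-3": [20, 22]
  "6-4": [17]
  "12-1": [16, 20]
  "5-5": [14, 16]
  "X-1": [20, 24]
"mPDAC09":
  "18-3": [17, 19]
  "4-2": [17, 19]
  "6-7": [20, 23]
  "9-2": [18, 22]
  "15-3": [20]
  "6-4": [18]
  "12-1": [16]
  "5-5": [16, 17]
  "X-1": [18, 25]
"mPDAC95":
  "18-3": [17]
  "4-2": [19, 19]
  "6-7": [17]
  "9-2": [18, 20]
  "15-3": [21]
  "6-4": [19]
  "12-1": [16]
  "5-5": [16, 17]
  "X-1": [26]
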