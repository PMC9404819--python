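# Curated transcription factors with literature evidence for involvement in
# muscle metabolism and/or muscle development; matrix/TF names containing one
# of these tokens are flagged in differential-TFBS reports.
COMP1
C/EBP
MYOG
COUP
MEF2
SRF
DELTAEF1
PBX1
MYOD
E2F
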