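>cathelicidin_probe consensus of four bat cathelicidin precursors (search probe)
METQKDSLLPGCWPLLLLLLGLAVPPATAQVLSYNEAVIAAIDDFNQRSSEASLYRLLEL
DQQPPDGDDNPDTPKPVSFTVKETVCPRTTQLPPEQCEFKENGLVKQCAGTVTLAQANDS
FDIDCADIPDVGIRSGVQRIVDKIRDIGRRINDFFSNLFPRGVS
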