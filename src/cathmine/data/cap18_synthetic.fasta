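>cap18_syn1 synthetic CAP18-region exemplar (hand-built, not a database sequence)
KRIVQRIKDFLRNLVPRTES
>cap18_syn2 synthetic CAP18-region exemplar (hand-built, not a database sequence)
KRIVERIKDFLRNLVPRTES
>cap18_syn3 synthetic CAP18-region exemplar (hand-built, not a database sequence)
RRIVQRIKDFFRNLVPRTES
>cap18_syn4 synthetic CAP18-region exemplar (hand-built, not a database sequence)
KRLVQKIKDFLRNLVPRSES
>cap18_syn5 synthetic CAP18-region exemplar (hand-built, not a database sequence)
KKIVQRIKDFLRNLIPRTES
>cap18_syn6 synthetic CAP18-region exemplar (hand-built, not a database sequence)
KRIVQRLKDFLRGLVPRTES
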