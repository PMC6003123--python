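>ath-miR156a Arabidopsis thaliana miR156a mature
GCUCACUGCUCUUUCUGUCAGA
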