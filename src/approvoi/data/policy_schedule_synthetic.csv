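date,status
2021-06-24,eua
2022-12-21,approved
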