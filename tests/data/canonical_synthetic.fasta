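>SYNPROT0001 synthetic canonical protein (hand-built fixture, not a real UniProt entry)
MAAACCDDEEKGGGWWSSTTK
>SYNPROT0002 synthetic canonical protein (hand-built fixture, not a real UniProt entry)
MDEQLLNNRRSSTTVVKAAGG
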