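((parvula,kanapiae),(auraria,((kikkawai,lini),(nikananu,diplacantha))))montium;
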