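((A:1,B:1)AB:1,C:2)ROOT;
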