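id,iu_pre,iu_post1,iu_post2
Gas,32,37,36
Library,19,44,57
Loan,40,21,23
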