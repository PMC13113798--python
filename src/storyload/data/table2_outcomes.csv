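id,printed_composite,iu_gain,block,role
Airport,0.698,25,High,treated
Gas,0.55,4,High,evaluation
Tickets,0.513,30,High,treated
Fire,0.474,41,High,treated
Water,0.131,79,Medium,treated
Paint,0.091,27,Medium,treated
Garage Sale,-0.077,31,Medium,treated
Library,-0.199,38,Medium,evaluation
Loan,-0.261,-17,Low,evaluation
Sandwich,-0.304,46,Low,treated
Tightrope,-0.511,13,Low,treated
Baseball,-1.106,31,Low,treated
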