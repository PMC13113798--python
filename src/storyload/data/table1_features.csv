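id,sentence_count,word_count,avg_sentence_length,complex_ratio,estimated_ius,printed_composite,printed_block
Airport,14,220,15.71,0.50,21,0.698,High
Gas,14,217,15.50,0.43,21,0.550,High
Tickets,13,212,16.31,0.85,13,0.513,High
Fire,13,223,17.15,0.54,16,0.474,High
Water,14,220,15.71,0.36,16,0.131,Medium
Paint,14,224,16.00,0.29,16,0.091,Medium
Garage Sale,14,214,15.29,0.43,13,-0.077,Medium
Library,13,202,15.54,0.62,10,-0.199,Medium
Loan,16,200,12.50,0.25,16,-0.261,Low
Sandwich,14,202,14.43,0.50,11,-0.304,Low
Tightrope,14,217,15.50,0.14,12,-0.511,Low
Baseball,11,152,13.82,0.45,12,-1.106,Low
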