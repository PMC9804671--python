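provider_id,group_id,category,proportion,weight
A,all,poor,0.40,0.5
A,all,OK,0.10,0.5
A,all,good,0.50,0.5
B,all,poor,0.30,0.5
B,all,OK,0.30,0.5
B,all,good,0.40,0.5
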