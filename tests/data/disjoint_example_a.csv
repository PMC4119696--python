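label,value
diamond,0.5
diamond,0.8
diamond,0.6
diamond,0.5
diamond,0.4
diamond,1
circle,0.4
circle,0.6
circle,0.7
circle,0.5
circle,0.8
circle,0.6
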