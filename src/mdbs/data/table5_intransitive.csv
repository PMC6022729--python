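dimension,polarity,V,Y,Z
price,lower_better,24,16,
efficiency,higher_better,,24,32
warranty,higher_better,70,,50
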