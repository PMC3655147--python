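# config_hash=852f68bb6c79f9d4
flow_band	power_band	r	p	n
slow-2	slow-4	0.8901558752648089	0.3011906596313084	3
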