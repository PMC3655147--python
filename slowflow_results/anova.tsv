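# config_hash=852f68bb6c79f9d4
band	node	F	df1	df2	p	n_windows
slow-4	PCC	36.7599240535871	5	94	1.0496822158798956e-20	6
slow-4	mPFC	49.00533687320878	5	94	1.026305699138073e-24	6
slow-4	LMTC	74.03796813724449	5	94	4.570296394692384e-31	6
slow-4	LAG	67.14140400378255	5	94	1.669073865883873e-29	6
slow-2	PCC	12.296905367689202	5	105	2.1574238757455066e-09	6
slow-2	mPFC	17.4798147175898	5	105	1.4594844095143436e-12	6
slow-2	LMTC	3.931812416615694	5	105	0.00262338973476944	6
slow-2	LAG	2.099684800350152	5	105	0.07117123154927195	6
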