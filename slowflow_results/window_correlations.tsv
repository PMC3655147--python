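# config_hash=852f68bb6c79f9d4
window	node_i	node_j	r	n
0	PCC	mPFC	0.024233777578232252	40
0	PCC	LMTC	-0.15287829971948955	40
0	PCC	LAG	-0.32024522912727166	40
0	mPFC	LMTC	0.43181142567765896	40
0	mPFC	LAG	0.16389932939206095	40
0	LMTC	LAG	0.29953404049304344	40
1	PCC	mPFC	0.49577979927324906	40
1	PCC	LMTC	0.251937324229902	40
1	PCC	LAG	0.2231321486648346	40
1	mPFC	LMTC	0.6562694957337032	40
1	mPFC	LAG	0.7046082869041362	40
1	LMTC	LAG	0.4832679550303828	40
2	PCC	mPFC	0.6680284802172638	40
2	PCC	LMTC	0.3302894936635988	40
2	PCC	LAG	0.38473312945054733	40
2	mPFC	LMTC	0.3656808255619221	40
2	mPFC	LAG	0.47304500012672995	40
2	LMTC	LAG	0.31504458478858777	40
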