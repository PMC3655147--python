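slowflow run (config hash 852f68bb6c79f9d4, seed 5)
nodes: PCC, mPFC, LMTC, LAG
samples: 120 at 2.0 s (8 realizations)
factorization: max residual 7.83e-10, 0 failed slices, 0 floored cells, 0 clipped causality cells
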