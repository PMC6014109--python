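# Default generative configuration for the western-blot densitometry
# experiment (stratified seeds plus 24 h and 42 h of germination).  Anchors are
# relative protein levels with WT at 0 h equal to 1; the Tim17-2 values encode
# the 1.85-fold mutant-42h vs WT-24h excess seen for this FTSH4 substrate.

[design]
genotypes = ["WT", "ftsh4-1", "ftsh4-2"]
timepoints = ["0", "24", "42"]
n_replicates = 3

[signal]
band_scale = 1000.0   # arbitrary densitometry units per unit relative level
loading_scale = 1000.0
noise_cv = 0.15       # lognormal CV of band quantitation
loading_cv = 0.10     # lognormal CV of gel loading (shared by band and control)

[anchors.Tim17-2.WT]
0 = 1.0
24 = 2.0
42 = 2.4

[anchors.Tim17-2.ftsh4]
0 = 1.1
24 = 2.6
42 = 3.7

[anchors.RIESKE.WT]
0 = 0.2
24 = 5.0
42 = 0.7

[anchors.RIESKE.ftsh4]
0 = 0.2
24 = 2.5
42 = 0.7

[anchors.AOX.WT]
0 = 0.5
24 = 0.9
42 = 1.5

[anchors.AOX.ftsh4]
0 = 0.5
24 = 5.0
42 = 9.0
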