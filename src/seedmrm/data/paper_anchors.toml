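# Default generative configuration for the germination MRM experiment.
#
# Anchors are relative protein abundances per genotype and timepoint (hours of
# germination at 30 C after 48 h stratification; "DS" = dry seed, "0" = after
# stratification).  The genotype key "ftsh4" applies to any ftsh4-* allele
# unless an allele-specific table overrides it.  Values encode the published
# fold changes of the study system (e.g. the 2.6-fold WT/mutant SDH2-2 deficit
# at 24 h, the 7-fold WT RIESKE decline between 24 h and 42 h, the 10-20x
# AOX1A over-accumulation in the mutant alleles).

[design]
genotypes = ["WT", "ftsh4-1", "ftsh4-2"]
timepoints = ["DS", "0", "6", "12", "24", "42"]
n_replicates = 3
n_fractions = 12

[signal]
abundance_scale = 200000.0   # counts per unit relative abundance (natural channel)
spike_counts = 200000.0      # summed heavy-channel counts per peptide (2.5 pmol SIS equivalent)
noise_cv = 0.15              # measurement-level lognormal CV
biol_cv = 0.20               # replicate-level lognormal CV
lod_counts = 1000.0          # per-record detection floor
good_signal_counts = 10000.0 # good/low signal class threshold (summed natural)
peptide_response_sigma = 0.8 # lognormal sigma (log units) of per-peptide response
transition_profile = "dirichlet"  # "dirichlet" or "equal"
n_transitions = 5
fraction_sd = 0.8            # gel-band Gaussian sd, in fractions
interference_rate = 0.1      # probability a natural transition carries background

# Approximate subunit molecular weights (kDa) used only to rank proteins into
# SDS-PAGE gel-band centers (heaviest protein migrates nearest fraction 1).
[mw_kda]
NAD75 = 81.0
SDH1-1 = 70.0
ATP2-1 = 60.0
ATP1 = 55.0
NAD7 = 44.5
COB = 44.0
AOX2 = 38.0
AOX1A = 36.0
CLS = 33.0
SDH2-3 = 31.0
SDH2-2 = 30.5
CA2 = 30.0
COX2 = 29.5
VDAC1 = 29.0
VDAC3 = 28.5
PHB3 = 30.2
RIESKE = 26.0
COX5C-1 = 6.0

[anchors.NAD7.WT]
DS = 1.0
0 = 0.5
6 = 0.55
12 = 0.65
24 = 0.8
42 = 0.9

[anchors.NAD7.ftsh4]
DS = 1.0
0 = 0.5
6 = 0.5
12 = 0.55
24 = 0.53
42 = 0.6

[anchors.NAD75.WT]
DS = 0.25
0 = 0.25
6 = 0.3
12 = 0.5
24 = 0.8
42 = 0.85

[anchors.NAD75.ftsh4]
DS = 0.25
0 = 0.25
6 = 0.28
12 = 0.4
24 = 0.4
42 = 0.85

[anchors.CA2.WT]
DS = 0.3
0 = 0.3
6 = 0.35
12 = 0.55
24 = 0.9
42 = 1.0

[anchors.CA2.ftsh4]
DS = 0.3
0 = 0.3
6 = 0.33
12 = 0.45
24 = 0.6
42 = 1.0

[anchors.SDH1-1.WT]
DS = 0.05
0 = 0.05
6 = 0.06
12 = 0.12
24 = 0.9
42 = 0.45

[anchors.SDH1-1.ftsh4]
DS = 0.05
0 = 0.05
6 = 0.06
12 = 0.1
24 = 0.85
42 = 0.33

[anchors.SDH2-2.WT]
DS = 0.02
0 = 0.02
6 = 0.03
12 = 0.06
24 = 0.52
42 = 0.78

[anchors.SDH2-2.ftsh4]
DS = 0.02
0 = 0.02
6 = 0.03
12 = 0.05
24 = 0.2
42 = 0.5

[anchors.SDH2-3.WT]
DS = 1.6
0 = 1.0
6 = 1.2
12 = 1.5
24 = 1.2
42 = 0.6

[anchors.SDH2-3.ftsh4]
DS = 1.8
0 = 0.6
6 = 0.9
12 = 1.1
24 = 1.3
42 = 0.8

[anchors.COB.WT]
DS = 0.004
0 = 0.004
6 = 0.004
12 = 0.004
24 = 0.004
42 = 0.004

[anchors.COB.ftsh4]
DS = 0.004
0 = 0.004
6 = 0.004
12 = 0.004
24 = 0.004
42 = 0.004

[anchors.RIESKE.WT]
DS = 0.05
0 = 0.04
6 = 0.1
12 = 0.6
24 = 1.4
42 = 0.2

[anchors.RIESKE.ftsh4]
DS = 0.05
0 = 0.04
6 = 0.08
12 = 0.35
24 = 0.7
42 = 0.194

[anchors.COX2.WT]
DS = 0.15
0 = 0.15
6 = 0.16
12 = 0.3
24 = 0.6
42 = 0.55

[anchors.COX2.ftsh4]
DS = 0.15
0 = 0.15
6 = 0.16
12 = 0.2
24 = 0.28
42 = 0.33

[anchors.COX5C-1.WT]
DS = 0.2
0 = 0.2
6 = 0.25
12 = 0.4
24 = 0.6
42 = 0.7

[anchors.COX5C-1.ftsh4]
DS = 0.2
0 = 0.2
6 = 0.25
12 = 0.4
24 = 0.6
42 = 0.7

[anchors.ATP1.WT]
DS = 0.3
0 = 0.3
6 = 0.35
12 = 0.5
24 = 0.9
42 = 1.25

[anchors.ATP1.ftsh4]
DS = 0.3
0 = 0.3
6 = 0.33
12 = 0.5
24 = 0.7
42 = 0.85

[anchors.ATP2-1.WT]
DS = 0.25
0 = 0.25
6 = 0.3
12 = 0.4
24 = 0.85
42 = 1.2

[anchors.ATP2-1.ftsh4]
DS = 0.25
0 = 0.25
6 = 0.3
12 = 0.4
24 = 0.6
42 = 0.8

[anchors.AOX1A.WT]
DS = 0.05
0 = 0.05
6 = 0.06
12 = 0.07
24 = 0.09
42 = 0.15

[anchors.AOX1A.ftsh4-1]
DS = 0.05
0 = 0.05
6 = 0.1
12 = 0.25
24 = 0.5
42 = 0.9

[anchors.AOX1A.ftsh4-2]
DS = 0.05
0 = 0.05
6 = 0.12
12 = 0.35
24 = 0.8
42 = 1.9

[anchors.AOX2.WT]
DS = 0.004
0 = 0.004
6 = 0.004
12 = 0.004
24 = 0.004
42 = 0.004

[anchors.AOX2.ftsh4]
DS = 0.004
0 = 0.004
6 = 0.004
12 = 0.004
24 = 0.004
42 = 0.004

[anchors.CLS.WT]
DS = 0.004
0 = 0.004
6 = 0.004
12 = 0.004
24 = 0.004
42 = 0.004

[anchors.CLS.ftsh4]
DS = 0.004
0 = 0.004
6 = 0.004
12 = 0.004
24 = 0.004
42 = 0.004

[anchors.PHB3.WT]
DS = 0.2
0 = 0.2
6 = 0.3
12 = 0.5
24 = 0.7
42 = 0.8

[anchors.PHB3.ftsh4]
DS = 0.2
0 = 0.2
6 = 0.3
12 = 0.5
24 = 0.7
42 = 0.8

[anchors.VDAC1.WT]
DS = 0.3
0 = 0.28
6 = 0.35
12 = 0.55
24 = 0.8
42 = 0.9

[anchors.VDAC1.ftsh4]
DS = 0.3
0 = 0.28
6 = 0.35
12 = 0.55
24 = 0.8
42 = 0.9

[anchors.VDAC3.WT]
DS = 0.25
0 = 0.24
6 = 0.3
12 = 0.5
24 = 0.75
42 = 0.85

[anchors.VDAC3.ftsh4]
DS = 0.25
0 = 0.24
6 = 0.3
12 = 0.5
24 = 0.75
42 = 0.85
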