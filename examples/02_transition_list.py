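"""Compute precursor/fragment m/z values and build an SRM transition list.

Shows the light/heavy mass relationship of a stable-isotope standard (SIS):
the C-terminal label shifts the precursor and every y ion, while b ions are
shared between the channels.
"""

from seedmrm import masscalc

peptide = "AVDSLVPIGR"  # an ATP-synthase alpha-subunit panel peptide
for label in ("light", "heavy"):
    mz = masscalc.peptide_mz(peptide, charge=2, label=label)
    print(f"{peptide} 2+ {label:5s} precursor m/z = {mz:9.4f} Th")
# the difference is the Arg(13C6,15N4) label: +10.00827 Da over charge 2

light = masscalc.fragment_mzs(masscalc.LabeledPeptide(peptide, "light"))
heavy = masscalc.fragment_mzs(masscalc.LabeledPeptide(peptide, "heavy"))
print("\nfragment   light m/z   heavy m/z   shift")
for lf, hf in zip(light, heavy):
    if lf.index in (1, 5, 9):
        print(
            f"{lf.series}{lf.index:<8d} {lf.mz:9.4f}  {hf.mz:9.4f}  "
            f"{hf.mz - lf.mz:+7.4f}"
        )

table = masscalc.build_transition_table([peptide])
print(f"\ntransition list: {len(table)} rows (top-5 fragments x 2 channels)")
print(table.head(5).to_string(index=False))
# Q1/Q3 pairs like these are what a triple quadrupole monitors; CE/CV are
# per-transition instrument settings supplied by configuration.
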