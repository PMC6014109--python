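"""Design proteotypic peptide candidates from a protein sequence.

Digests a small synthetic protein in silico (trypsin, K/R cut sites with
proline suppression), scores every candidate against the panel selection
rules, and screens uniqueness against a mini proteome by exact substring
matching.
"""

from seedmrm import panel

protein = panel.TargetProtein(
    accession="At9g99990",
    name="demo inner-membrane protein",
    short_name="DEMO1",
    genome="nuclear",
    category="transport",
)
sequence = (
    "MAVDSLVPIGRKPAQLTDEEIVYISQSAKQGNNNRLLEFYERAASSGGTTPLRWNPDNPGK"
    "AVIFDRGGEFGVFLVSNGSNRPYRTTIAIDTILNQK"
)

candidates = [
    panel.PanelPeptide(protein, pep, start, end)
    for pep, start, end in panel.digest_trypsin(sequence, missed_cleavages=0)
]
print(f"tryptic digest: {len(candidates)} fragments from {len(sequence)} residues")

scores = panel.apply_rules(candidates, panel.SelectionRules())
proteome = {"At9g99990": sequence, "At8g88880": "MKAVIFDRLLSGK"}
print(f"{'peptide':24s} {'len':>3s} pass penalties          occurrences")
for s in scores:
    occ = panel.check_uniqueness(s.peptide.sequence, proteome)
    print(
        f"{s.peptide.sequence:24s} {len(s.peptide):3d} "
        f"{str(s.hard_pass):5s} {','.join(s.penalties) or '-':18s} {occ}"
    )

# A candidate with exactly one occurrence in the proteome is proteotypic;
# hard_pass=False marks fragments outside the 6-20 residue window, and
# penalties flag chemistry-prone N-termini (C/M/W/Q) or internal DP/DG/NG/QG
# motifs that are avoided when an alternative exists.
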