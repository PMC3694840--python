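"""Scan a protein sequence for [S/T]Q motifs and SCD regions.

ATM/ATR-family kinases (Tel1/Mec1 in budding yeast) phosphorylate S/T
residues followed by Q; three or more such motifs within 100 residues
form an SCD, the classical substrate signature.  The synthetic sequence
below carries two clusters, only one of which is dense enough to qualify.
"""

import meichip as m

seq = (
    "M" + "A" * 20
    + "SQ" + "A" * 15 + "TQ" + "A" * 15 + "SQ"      # 3 motifs in 40 residues -> SCD
    + "A" * 120
    + "SQ" + "A" * 150 + "TQ"                        # 2 distant motifs -> no SCD
    + "A" * 20
)

motifs, regions = m.scan_sequence(seq)
print(f"sequence length {len(seq)}, {len(motifs)} [S/T]Q motifs at {motifs}")
for r in regions:
    print(f"SCD at residues {r.start}-{r.end} "
          f"({r.n_motifs} motifs in a {r.tract_length}-residue tract)")
print("motifs outside any SCD are isolated consensus sites, not a cluster domain")
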