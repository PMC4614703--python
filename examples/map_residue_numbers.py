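"""Convert residue numbers between precursor and mature numbering schemes.

Clinical variant positions count from the start of the precursor protein
(target peptide included); structure files count from the first mature
residue.  For the packaged human→bovine correspondence the two schemes
differ by a constant 20 residues, so clinical R88G sits at structure
residue 68.  For arbitrary homolog pairs the map is built from a global
alignment instead.
"""

from flavoscore import (
    ProteinSequence,
    align_pair,
    build_residue_map,
    map_position,
    offset_residue_map,
)

# packaged constant-offset fallback: human precursor -> mature structure
rmap = offset_residue_map(20, 464)
for pos in (88, 117, 423):
    print(f"human precursor {pos:>3} -> structure residue {map_position(rmap, pos)}")

# alignment-derived map between a toy precursor and a shorter homolog
human = ProteinSequence("toy-human", "MRALLAKVDEWQGHKL")
homolog = ProteinSequence("toy-homolog", "MKVDEWQAHKL")
aln = align_pair(human, homolog)
m = build_residue_map(aln, scheme_a="toy-human", scheme_b="toy-homolog")
print(f"\ntoy alignment identity: {aln.identity_fraction:.2f}")
for pos in (5, 8, 12):
    print(f"toy-human {pos:>2} -> toy-homolog {map_position(m, pos)}")
print("Positions aligned to gaps return the string 'unmapped'.")
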