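"""Packaged reference table for the 19 clinically reported NDUFV1
missense variants: distances to the cofactors measured on the bovine
structure, clade-conservation calls, and the published score/class.

Human variants are in precursor numbering; the structure residue column is
mature numbering (every pair differs by the 20-residue target peptide).
A ``-`` in the yeast columns marks residues not conserved in the
*Y. lipolytica* homolog, which therefore could not be modelled there.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# human-precursor minus bovine-mature position, constant across all 19 rows
HUMAN_BOVINE_OFFSET = 20

# printed "4—mild" for R147W conflicts with the published <5 → none rule;
# flagged as a warning rather than treated as a scoring failure
KNOWN_CLASS_DISCREPANCIES = frozenset({"R147W"})


def load_table2() -> pd.DataFrame:
    """The packaged 19-row reference table as a DataFrame."""
    with resources.files("flavoscore.data").joinpath("table2.tsv").open() as fh:
        df = pd.read_csv(
            fh, sep="\t", dtype={"printed_score": int}, keep_default_na=False
        )
    return df


def variant_list() -> list[str]:
    return list(load_table2()["variant"])
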