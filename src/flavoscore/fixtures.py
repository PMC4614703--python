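"""Synthetic test-input generators.

Everything the test suite consumes is built here at run time: miniature
PDB structures with cofactor atoms at controlled positions, clade-annotated
MSAs whose per-column conservation sits on a chosen side of the 95%
threshold *by construction* (exact counts, never sampling, so classifier
tests cannot flake), and the packaged reference-table bundle.  None of the
generators attempts realism — folds are arbitrary point sets and MSA rows
are not evolved — they exist to give the geometry, conservation and
scoring code fully controlled inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .conservation import CLADE_ORDER, CladeTable
from .reference import load_table2, variant_list
from .sequences import AMINO_ACIDS


class FixtureError(ValueError):
    pass


# ---------------------------------------------------------------------------
# synthetic structures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueSpec:
    res_num: int
    x: float
    y: float
    z: float
    res_name: str = "ALA"


@dataclass(frozen=True)
class LigandAtomSpec:
    res_name: str  # FMN or SF4
    atom_name: str
    x: float
    y: float
    z: float
    element: str = "C"
    res_num: int = 901


@dataclass(frozen=True)
class StructureSpec:
    residues: tuple[ResidueSpec, ...]
    ligand_atoms: tuple[LigandAtomSpec, ...]
    chain: str = "A"

    def __post_init__(self) -> None:
        if not self.residues or not self.ligand_atoms:
            raise FixtureError("need at least one residue and one ligand atom")


def _pdb_atom_line(record: str, serial: int, name: str, altloc: str,
                   res_name: str, chain: str, res_num: int,
                   x: float, y: float, z: float, occ: float,
                   element: str) -> str:
    for v in (x, y, z):
        if not (-999.999 <= v <= 9999.999):
            raise FixtureError(f"coordinate {v} overflows fixed-width PDB field")
    # single-letter elements start in column 14, two-letter in column 13
    name_field = f" {name:<3}" if len(element) == 1 and len(name) <= 3 else f"{name:<4}"
    return (
        f"{record:<6}{serial:>5} {name_field}{altloc:1}{res_name:>3} "
        f"{chain:1}{res_num:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          "
        f"{element.upper():>2}"
    )


def make_synthetic_structure(
    spec: StructureSpec, altloc_residues: Sequence[int] = ()
) -> str:
    """Well-formed single-model PDB text: one Cα per residue plus HETATM
    ligand records.

    Residues listed in ``altloc_residues`` are emitted as A/B alternate
    conformers (B shifted by 1 Å in x with lower occupancy) so the
    highest-occupancy-collapse behaviour of the loader can be exercised.
    """
    lines = []
    serial = 1
    for r in spec.residues:
        if r.res_num in altloc_residues:
            lines.append(_pdb_atom_line("ATOM", serial, "CA", "A", r.res_name,
                                        spec.chain, r.res_num,
                                        r.x, r.y, r.z, 0.60, "C"))
            serial += 1
            lines.append(_pdb_atom_line("ATOM", serial, "CA", "B", r.res_name,
                                        spec.chain, r.res_num,
                                        r.x + 1.0, r.y, r.z, 0.40, "C"))
        else:
            lines.append(_pdb_atom_line("ATOM", serial, "CA", " ", r.res_name,
                                        spec.chain, r.res_num,
                                        r.x, r.y, r.z, 1.00, "C"))
        serial += 1
    lines.append("TER")
    for a in spec.ligand_atoms:
        lines.append(_pdb_atom_line("HETATM", serial, a.atom_name, " ",
                                    a.res_name, "X", a.res_num,
                                    a.x, a.y, a.z, 1.00, a.element))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def random_structure_spec(
    rng: np.random.Generator,
    n_residues: int = 20,
    n_fmn: int = 5,
    n_fes: int = 4,
    box: float = 50.0,
) -> StructureSpec:
    """Random point-cloud structure with FMN and SF4 ligand atoms."""
    def coords() -> tuple[float, float, float]:
        # round to PDB precision so file round-trips are exact
        return tuple(round(float(v), 3) for v in rng.uniform(0, box, 3))

    residues = tuple(
        ResidueSpec(i + 1, *coords()) for i in range(n_residues)
    )
    ligands = tuple(
        LigandAtomSpec("FMN", f"C{i + 1}", *coords(), res_num=901)
        for i in range(n_fmn)
    ) + tuple(
        LigandAtomSpec("SF4", f"FE{i + 1}", *coords(), element="FE", res_num=902)
        for i in range(n_fes)
    )
    return StructureSpec(residues=residues, ligand_atoms=ligands)


def spec_min_distance(spec: StructureSpec, res_num: int, res_name: str) -> float:
    """Brute-force minimum distance straight from the spec coordinates."""
    res = next(r for r in spec.residues if r.res_num == res_num)
    best = math.inf
    for a in spec.ligand_atoms:
        if a.res_name != res_name:
            continue
        d = math.dist((res.x, res.y, res.z), (a.x, a.y, a.z))
        best = min(best, d)
    if math.isinf(best):
        raise FixtureError(f"no ligand atoms named {res_name}")
    return best


# ---------------------------------------------------------------------------
# synthetic MSAs with construction-guaranteed conservation calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MsaSpec:
    """Per-clade sequence counts, a reference sequence, and one target
    conservation call per column.

    The reference row is the first chordate, so ``n_chordata`` includes it.
    """

    reference: str
    target_calls: tuple[str, ...]
    n_chordata: int = 40
    n_metazoa: int = 60  # non-chordate metazoans
    n_eukaryota: int = 50  # non-metazoan eukaryotes
    n_other: int = 50  # prokaryotes etc.
    seed: int = 0
    ref_id: str = "ref"

    def __post_init__(self) -> None:
        if min(self.n_chordata, self.n_metazoa, self.n_eukaryota, self.n_other) < 1:
            raise FixtureError("all clade counts must be positive")
        if len(self.target_calls) != len(self.reference):
            raise FixtureError("one target call per reference column required")
        bad = set(self.target_calls) - ({"none"} | set(CLADE_ORDER))
        if bad:
            raise FixtureError(f"unknown target calls {sorted(bad)}")


def _cumulative_sizes(spec: MsaSpec) -> dict[str, int]:
    c = spec.n_chordata
    m = c + spec.n_metazoa
    e = m + spec.n_eukaryota
    n = e + spec.n_other
    return {"chordata": c, "metazoa": m, "eukaryota": e, "all": n}


def _match_counts_for_call(
    spec: MsaSpec, call: str, threshold: float = 0.95
) -> dict[str, int]:
    """Matching-row count per clade *block* realizing the target call.

    Rows inside the target clade all match (fraction 1); rows outside all
    mismatch, so each broader cumulative fraction equals |target| / |broader|
    — this must be ≤ threshold, otherwise the clade is too small to keep the
    broader call below the cutoff and we error with the minimum workable
    count.  For "none" only the reference row matches.
    """
    sizes = _cumulative_sizes(spec)
    blocks = {"chordata": 0, "metazoa": 0, "eukaryota": 0, "other": 0}
    if call == "none":
        blocks["chordata"] = 1  # the reference row itself
        if 1 > threshold * sizes["chordata"]:
            raise FixtureError(
                "need at least 2 chordate rows to realize a 'none' call"
            )
        return blocks
    idx = CLADE_ORDER.index(call)
    target_size = sizes[call]
    for broader in CLADE_ORDER[idx + 1:]:
        if target_size > threshold * sizes[broader]:
            need = math.ceil(target_size / threshold - sizes[broader])
            raise FixtureError(
                f"clade {broader!r} too small to keep its fraction at or "
                f"below {threshold} for target {call!r}; add at least {need} "
                f"more sequences outside {call!r}"
            )
    block_names = ("chordata", "metazoa", "eukaryota", "other")
    block_sizes = (spec.n_chordata, spec.n_metazoa, spec.n_eukaryota, spec.n_other)
    for name, size in zip(block_names[: idx + 1], block_sizes[: idx + 1]):
        blocks[name] = size
    return blocks


def make_synthetic_msa(
    spec: MsaSpec, threshold: float = 0.95
) -> tuple[MultipleSeqAlignment, CladeTable]:
    """Deterministic MSA + clade table realizing the requested call per column."""
    rng = np.random.default_rng(spec.seed)
    alphabet = sorted(AMINO_ACIDS)
    block_names = ("chordata", "metazoa", "eukaryota", "other")
    block_sizes = (spec.n_chordata, spec.n_metazoa, spec.n_eukaryota, spec.n_other)

    ids: list[str] = []
    clade_of: dict[str, str] = {}
    for name, size in zip(block_names, block_sizes):
        for i in range(size):
            sid = spec.ref_id if (name == "chordata" and i == 0) else f"{name}_{i}"
            ids.append(sid)
            clade_of[sid] = name

    n_rows = len(ids)
    columns = np.empty((n_rows, len(spec.reference)), dtype="U1")
    for col, (ref_res, call) in enumerate(zip(spec.reference, spec.target_calls)):
        blocks = _match_counts_for_call(spec, call, threshold)
        row = 0
        for name, size in zip(block_names, block_sizes):
            n_match = blocks[name]
            for i in range(size):
                if i < n_match:
                    columns[row, col] = ref_res
                else:
                    others = [a for a in alphabet if a != ref_res]
                    columns[row, col] = others[int(rng.integers(len(others)))]
                row += 1

    records = [
        SeqRecord(Seq("".join(columns[i])), id=ids[i], description="")
        for i in range(n_rows)
    ]
    return MultipleSeqAlignment(records), CladeTable(membership=clade_of)


def write_clade_table_tsv(clades: CladeTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tclade\n")
        for sid, clade in clades.membership.items():
            fh.write(f"{sid}\t{clade}\n")


# ---------------------------------------------------------------------------
# packaged reference bundle
# ---------------------------------------------------------------------------

def make_table2_bundle() -> tuple[pd.DataFrame, list[str]]:
    """The packaged 19-row reference table plus the variant strings."""
    return load_table2(), variant_list()
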