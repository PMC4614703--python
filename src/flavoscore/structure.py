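"""Structure parsing and Cα-to-cofactor distance computation.

Distances are "center-to-center": from the Cα atom of a residue to the
nearest atom of the cofactor (FMN, or the 4Fe-4S cluster deposited as SF4).
They are kept at full precision internally; round only for display, since
the scoring bins must see the unrounded value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import gemmi
import numpy as np

FMN_RESIDUE_NAMES = frozenset({"FMN"})
FES_RESIDUE_NAMES = frozenset({"SF4"})


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    chain: str
    res_num: int
    res_name: str
    atom_name: str
    x: float
    y: float
    z: float
    element: str
    is_hetero: bool = False

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass(frozen=True)
class StructureModel:
    """Atoms of one polymer chain plus all hetero (ligand) atoms."""

    atoms: tuple[Atom, ...]
    chain: str
    source: str = ""

    def ca_atom(self, res_num: int) -> Atom:
        for a in self.atoms:
            if (
                a.chain == self.chain
                and not a.is_hetero
                and a.res_num == res_num
                and a.atom_name == "CA"
            ):
                return a
        raise StructureError(
            f"residue {res_num} of chain {self.chain} has no CA atom"
        )

    def ca_residue_numbers(self) -> list[int]:
        nums = {
            a.res_num
            for a in self.atoms
            if a.chain == self.chain and not a.is_hetero and a.atom_name == "CA"
        }
        return sorted(nums)

    def hetero_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_hetero]


@dataclass(frozen=True)
class LigandSelector:
    """Selects cofactor atoms by hetero residue name.

    ``copy_policy`` handles structures holding several copies of the same
    cofactor (the intact complex carries multiple FeS clusters): "nearest"
    keeps only the copy closest to the selected polymer chain, "all" uses
    every matching atom.  An explicit ``chain`` restriction overrides both.
    """

    residue_names: frozenset[str]
    chain: Optional[str] = None
    copy_policy: str = "nearest"

    def __post_init__(self) -> None:
        if not self.residue_names:
            raise ValueError("LigandSelector needs at least one residue name")
        if self.copy_policy not in ("nearest", "all"):
            raise ValueError(f"unknown copy_policy {self.copy_policy!r}")


FMN_SELECTOR = LigandSelector(residue_names=FMN_RESIDUE_NAMES)
FES_SELECTOR = LigandSelector(residue_names=FES_RESIDUE_NAMES)


@dataclass(frozen=True)
class DistanceRecord:
    """Minimum Cα-to-cofactor distances (Å) for one residue, mature numbering."""

    res_num: int
    d_fmn: float
    d_fes: float


def load_structure(path: Union[str, Path], chain: str) -> StructureModel:
    """Read a PDB/mmCIF file, keeping one chain plus all hetero ligand atoms.

    Alternate locations are collapsed to the highest-occupancy conformer;
    residues carrying insertion codes are rejected (the mapping machinery
    assumes plain integer numbering).
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path} contains no models")
    model = st[0]
    chains = [ch.name for ch in model]
    if chain not in chains:
        raise StructureError(
            f"chain {chain!r} not found in {path.name}; available chains: "
            f"{sorted(set(chains))}"
        )

    atoms: list[Atom] = []
    for ch in model:
        for res in ch:
            is_het = res.het_flag == "H"
            if ch.name != chain and not is_het:
                continue
            if res.seqid.icode not in (" ", "\x00", ""):
                raise StructureError(
                    f"residue {res.name} {res.seqid.num}{res.seqid.icode} in "
                    f"chain {ch.name} has an insertion code; renumber the "
                    f"structure first"
                )
            # collapse altlocs: keep highest occupancy per atom name
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ:
                    best[at.name] = at
            for name, at in best.items():
                pos = at.pos
                if not all(math.isfinite(v) for v in (pos.x, pos.y, pos.z)):
                    raise StructureError(
                        f"non-finite coordinate on atom {name} of "
                        f"{res.name} {res.seqid.num}"
                    )
                atoms.append(
                    Atom(
                        chain=ch.name,
                        res_num=res.seqid.num,
                        res_name=res.name,
                        atom_name=name,
                        x=pos.x,
                        y=pos.y,
                        z=pos.z,
                        element=at.element.name,
                        is_hetero=is_het,
                    )
                )
    return StructureModel(atoms=tuple(atoms), chain=chain, source=path.name)


def _select_ligand_atoms(s: StructureModel, sel: LigandSelector) -> list[Atom]:
    matches = [a for a in s.hetero_atoms() if a.res_name in sel.residue_names]
    if sel.chain is not None:
        matches = [a for a in matches if a.chain == sel.chain]
    if not matches:
        raise StructureError(
            f"no ligand atoms matching residue names "
            f"{sorted(sel.residue_names)} in {s.source or 'structure'}"
        )
    if sel.copy_policy == "all":
        return matches
    # group into cofactor copies and keep the copy nearest the polymer chain
    copies: dict[tuple[str, int, str], list[Atom]] = {}
    for a in matches:
        copies.setdefault((a.chain, a.res_num, a.res_name), []).append(a)
    if len(copies) == 1:
        return matches
    ca_xyz = np.array(
        [
            a.xyz
            for a in s.atoms
            if a.chain == s.chain and not a.is_hetero and a.atom_name == "CA"
        ]
    )
    if ca_xyz.size == 0:
        return matches
    best_key = min(
        copies,
        key=lambda k: min(
            float(np.min(np.linalg.norm(ca_xyz - np.array(a.xyz), axis=1)))
            for a in copies[k]
        ),
    )
    return copies[best_key]


def min_distance_to_ligand(
    s: StructureModel, residue: int, sel: LigandSelector
) -> float:
    """Minimum Euclidean distance (Å) from the residue's Cα to any selected
    cofactor atom."""
    ca = s.ca_atom(residue)
    lig = _select_ligand_atoms(s, sel)
    ca_xyz = np.array(ca.xyz)
    lig_xyz = np.array([a.xyz for a in lig])
    return float(np.min(np.linalg.norm(lig_xyz - ca_xyz, axis=1)))


def distance_profile(
    s: StructureModel,
    sel_fmn: LigandSelector = FMN_SELECTOR,
    sel_fes: LigandSelector = FES_SELECTOR,
) -> list[DistanceRecord]:
    """One :class:`DistanceRecord` per Cα-bearing residue, ascending order."""
    fmn_atoms = np.array([a.xyz for a in _select_ligand_atoms(s, sel_fmn)])
    fes_atoms = np.array([a.xyz for a in _select_ligand_atoms(s, sel_fes)])
    records = []
    for num in s.ca_residue_numbers():
        ca = np.array(s.ca_atom(num).xyz)
        records.append(
            DistanceRecord(
                res_num=num,
                d_fmn=float(np.min(np.linalg.norm(fmn_atoms - ca, axis=1))),
                d_fes=float(np.min(np.linalg.norm(fes_atoms - ca, axis=1))),
            )
        )
    return records


def write_distance_profile_tsv(
    records: Sequence[DistanceRecord], path: Union[str, Path]
) -> None:
    """TSV export rounded to 0.1 Å, the reference table's display precision."""
    with open(path, "w") as fh:
        fh.write("residue\td_fmn_A\td_fes_A\n")
        for r in records:
            fh.write(f"{r.res_num}\t{r.d_fmn:.1f}\t{r.d_fes:.1f}\n")
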