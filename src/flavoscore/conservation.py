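"""Clade-stratified conservation calls from an annotated MSA.

Each reference-sequence position is classified by the most general
taxonomic class — none < chordata < metazoa < eukaryota < all — in which
the reference residue is conserved in more than 95% of member sequences.
Clade membership is cumulative (metazoa includes the chordates, eukaryota
includes all metazoans, "all" is every row), mirroring nested taxonomic
ranks, so broadening the clade can only dilute conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from Bio import AlignIO

# narrow-to-broad; "all" means every sequence in the alignment
CLADE_ORDER = ("chordata", "metazoa", "eukaryota", "all")
CLADE_LABELS = ("chordata", "metazoa", "eukaryota", "other")
CONSERVATION_CALLS = ("none",) + CLADE_ORDER

GAP_CHARS = frozenset({"-", "."})


class MsaError(ValueError):
    pass


@dataclass(frozen=True)
class CladeTable:
    """Mapping of MSA sequence id to its clade label.

    Labels are the narrowest applicable rank: a chordate is labelled
    "chordata" (not "metazoa"); non-eukaryotes are "other".
    """

    membership: dict[str, str]

    def __post_init__(self) -> None:
        bad = {c for c in self.membership.values() if c not in CLADE_LABELS}
        if bad:
            raise ValueError(
                f"unknown clade labels {sorted(bad)}; expected one of "
                f"{CLADE_LABELS}"
            )


@dataclass(frozen=True)
class ConservationConfig:
    threshold: float = 0.95
    reference_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie strictly between 0 and 1")


@dataclass(frozen=True)
class ConservationCall:
    """Per-clade conserved fractions and the most-general-clade call.

    ``fractions`` maps clade → conserved fraction; a clade with no member
    sequences is absent (not evaluable).  ``call`` is the broadest clade
    whose fraction strictly exceeds the threshold, or "none".
    """

    position: int
    ref_residue: str
    fractions: dict[str, float]
    call: str


def read_msa(path: Union[str, Path], fmt: Optional[str] = None):
    """Read a FASTA or Stockholm MSA; all rows must have equal length."""
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix in (".sto", ".stk", ".stockholm") else "fasta"
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise MsaError(f"cannot read MSA {path}: {exc}") from exc
    return aln


def read_clade_table(path: Union[str, Path]) -> CladeTable:
    """2-column TSV (sequence id, clade label); '#' lines and a header
    row reading 'id<TAB>clade' are skipped."""
    membership: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MsaError(
                    f"{path}:{lineno}: expected 2 tab-separated columns"
                )
            sid, clade = parts[0].strip(), parts[1].strip().lower()
            if (sid, clade) == ("id", "clade"):
                continue
            if sid in membership:
                raise MsaError(f"{path}:{lineno}: duplicate id {sid!r}")
            membership[sid] = clade
    return CladeTable(membership=membership)


def check_clade_coverage(msa, clades: CladeTable) -> None:
    for rec in msa:
        if rec.id not in clades.membership:
            raise MsaError(f"MSA sequence {rec.id!r} missing from clade table")


def column_for_reference_position(msa, ref_id: str, pos: int) -> int:
    """1-based alignment column holding the reference row's pos-th residue."""
    row = None
    for rec in msa:
        if rec.id == ref_id:
            row = str(rec.seq)
            break
    if row is None:
        raise MsaError(f"reference id {ref_id!r} not in MSA")
    if pos < 1:
        raise IndexError(f"position must be >= 1, got {pos}")
    count = 0
    for col, ch in enumerate(row, start=1):
        if ch not in GAP_CHARS:
            count += 1
            if count == pos:
                return col
    raise IndexError(
        f"position {pos} beyond ungapped reference length {count}"
    )


def _cumulative_members(clades: CladeTable, ids: list[str]) -> dict[str, list[str]]:
    """ids per cumulative clade, following the nesting order."""
    by_label: dict[str, list[str]] = {lab: [] for lab in CLADE_LABELS}
    for sid in ids:
        by_label[clades.membership[sid]].append(sid)
    return {
        "chordata": by_label["chordata"],
        "metazoa": by_label["chordata"] + by_label["metazoa"],
        "eukaryota": by_label["chordata"] + by_label["metazoa"] + by_label["eukaryota"],
        "all": list(ids),
    }


def conservation_fractions(
    msa, column: int, clades: CladeTable, ref_residue: str
) -> dict[str, float]:
    """Fraction of each cumulative clade matching ``ref_residue`` at the
    1-based ``column``.  Gaps and 'X' count as mismatches; empty clades are
    omitted from the result (not evaluable)."""
    check_clade_coverage(msa, clades)
    if not 1 <= column <= msa.get_alignment_length():
        raise IndexError(f"column {column} outside alignment")
    chars = {rec.id: str(rec.seq)[column - 1].upper() for rec in msa}
    ref_residue = ref_residue.upper()
    members = _cumulative_members(clades, [rec.id for rec in msa])
    fractions: dict[str, float] = {}
    for clade, ids in members.items():
        if not ids:
            continue
        n_match = sum(
            1
            for sid in ids
            if chars[sid] == ref_residue and chars[sid] not in GAP_CHARS
            and chars[sid] != "X"
        )
        fractions[clade] = n_match / len(ids)
    return fractions


def classify_conservation(
    fractions: dict[str, float],
    cfg: ConservationConfig = ConservationConfig(),
    position: int = 0,
    ref_residue: str = "",
) -> ConservationCall:
    """Most general clade with conserved fraction strictly above threshold."""
    call = "none"
    for clade in CLADE_ORDER:  # narrow to broad; keep the broadest that passes
        if fractions.get(clade, 0.0) > cfg.threshold:
            call = clade
    return ConservationCall(
        position=position,
        ref_residue=ref_residue,
        fractions=dict(fractions),
        call=call,
    )


def call_position(
    msa,
    clades: CladeTable,
    ref_id: str,
    pos: int,
    cfg: ConservationConfig = ConservationConfig(),
) -> ConservationCall:
    """Convenience wrapper: column lookup + fractions + classification for
    one reference position (reference numbering)."""
    col = column_for_reference_position(msa, ref_id, pos)
    ref_row = next(str(r.seq) for r in msa if r.id == ref_id)
    ref_res = ref_row[col - 1].upper()
    fractions = conservation_fractions(msa, col, clades, ref_res)
    return classify_conservation(fractions, cfg, position=pos, ref_residue=ref_res)


def write_conservation_tsv(calls, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write(
            "position\tref_residue\tf_chordata\tf_metazoa\tf_eukaryota\t"
            "f_all\tcall\n"
        )
        for c in calls:
            fracs = "\t".join(
                f"{c.fractions[k]:.4f}" if k in c.fractions else "NA"
                for k in CLADE_ORDER
            )
            fh.write(f"{c.position}\t{c.ref_residue}\t{fracs}\t{c.call}\n")
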