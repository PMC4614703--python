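"""Protein sequences, pairwise alignment and residue-number mapping.

The clinical literature numbers NDUFV1 variants on the human *precursor*
sequence (mitochondrial target peptide included), while structure files
number the *mature* chain, and the yeast homolog has its own precursor
numbering.  This module reads FASTA, aligns homolog pairs globally, and
builds explicit position maps between the numbering schemes so that, e.g.,
human precursor residue 88 can be looked up as mature-structure residue 68.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Union

from Bio import Align
from Bio.Align import substitution_matrices

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_RESIDUES = AMINO_ACIDS | {"X"}

# Numbering-scheme labels used throughout the package.
HUMAN_PRECURSOR = "human-precursor"
BOVINE_MATURE = "bovine-mature-structure"
YEAST_PRECURSOR = "yeast-precursor"


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed (bad header or residue)."""


@dataclass(frozen=True)
class ProteinSequence:
    """A protein sequence with an explicit mature-start annotation.

    ``mature_start`` is the 1-based index of the first residue of the mature
    protein; 1 means the sequence carries no target peptide (or none is
    known).
    """

    id: str
    residues: str
    mature_start: int = 1

    def __post_init__(self) -> None:
        bad = set(self.residues.upper()) - VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains illegal residue characters: "
                f"{sorted(bad)}"
            )
        if self.residues and not 1 <= self.mature_start <= len(self.residues):
            raise ValueError(
                f"mature_start {self.mature_start} outside sequence "
                f"{self.id!r} of length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring settings for global pairwise alignment.

    Defaults are BLOSUM62 with affine gaps: the first position of a gap
    scores ``-gap_open`` and each further position ``-gap_extend`` (so a
    length-L gap costs ``gap_open + (L-1)*gap_extend``), in half-bit units.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0


@dataclass(frozen=True)
class PairwiseAlignment:
    id_a: str
    id_b: str
    aligned_a: str
    aligned_b: str
    score: float
    identity_fraction: float
    similarity_fraction: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class ResidueMap:
    """Ordered 1-based position correspondences between two numbering schemes.

    Positions aligned to gaps are simply absent: querying them yields the
    explicit ``"unmapped"`` marker rather than a number.
    """

    pairs: tuple[tuple[int, int], ...]
    scheme_a: str
    scheme_b: str
    _fwd: dict = field(init=False, repr=False, compare=False)
    _rev: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        last_a = last_b = 0
        for a, b in self.pairs:
            if a <= last_a or b <= last_b:
                raise ValueError("map positions must be strictly increasing")
            last_a, last_b = a, b
        object.__setattr__(self, "_fwd", {a: b for a, b in self.pairs})
        object.__setattr__(self, "_rev", {b: a for a, b in self.pairs})


UNMAPPED = "unmapped"


def read_fasta(path: Union[str, Path]) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records, order kept.

    Uses strict validation: a sequence line with characters outside the
    amino-acid alphabet (plus 'X'), or sequence data before any header,
    raises :class:`FastaParseError` naming the offending line.
    """
    path = Path(path)
    records: list[ProteinSequence] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is not None:
            records.append(ProteinSequence(id=header, residues="".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                bad = set(line.upper()) - VALID_RESIDUES
                if bad:
                    raise FastaParseError(
                        f"{path}:{lineno}: illegal residue characters "
                        f"{sorted(bad)}"
                    )
                chunks.append(line.upper())
    flush()
    return records


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def align_pair(
    a: ProteinSequence,
    b: ProteinSequence,
    params: AlignmentParams = AlignmentParams(),
) -> PairwiseAlignment:
    """Globally align two sequences and report identity/similarity.

    Identity is the fraction of columns where both rows carry the same
    residue, over columns with no gap in either row.  Similarity adds
    columns whose substitution-matrix score is positive (the usual
    "similar residue" convention).
    """
    if not a.residues or not b.residues:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(params)
    aln = aligner.align(a.residues, b.residues)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])

    matrix = aligner.substitution_matrix
    n_cols = n_ident = n_sim = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if ca == "-" or cb == "-":
            continue
        n_cols += 1
        if ca == cb:
            n_ident += 1
            n_sim += 1
        elif matrix[ca, cb] > 0:
            n_sim += 1
    return PairwiseAlignment(
        id_a=a.id,
        id_b=b.id,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identity_fraction=n_ident / n_cols if n_cols else 0.0,
        similarity_fraction=n_sim / n_cols if n_cols else 0.0,
    )


def build_residue_map(
    aln: PairwiseAlignment,
    mature_start_a: int = 1,
    mature_start_b: int = 1,
    scheme_a: str = "a",
    scheme_b: str = "b",
) -> ResidueMap:
    """Turn an alignment into a position map between two numbering schemes.

    ``mature_start_x`` shifts scheme *x* so that position 1 is the first
    mature residue (pass 1 to keep precursor numbering).  Columns with a gap
    in either row produce no pair.
    """
    pairs: list[tuple[int, int]] = []
    pos_a = pos_b = 0
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if ca != "-":
            pos_a += 1
        if cb != "-":
            pos_b += 1
        if ca != "-" and cb != "-":
            ma = pos_a - (mature_start_a - 1)
            mb = pos_b - (mature_start_b - 1)
            if ma >= 1 and mb >= 1:
                pairs.append((ma, mb))
    return ResidueMap(pairs=tuple(pairs), scheme_a=scheme_a, scheme_b=scheme_b)


def offset_residue_map(
    offset: int,
    length_a: int,
    scheme_a: str = HUMAN_PRECURSOR,
    scheme_b: str = BOVINE_MATURE,
) -> ResidueMap:
    """Constant-offset map: scheme-b position = scheme-a position - offset.

    The packaged human-precursor → bovine-mature correspondence is offset 20
    (the target-peptide length difference); all 19 reference variant pairs
    obey it, so this is the default fallback when full sequences are not
    supplied.
    """
    pairs = tuple(
        (a, a - offset) for a in range(1, length_a + 1) if a - offset >= 1
    )
    return ResidueMap(pairs=pairs, scheme_a=scheme_a, scheme_b=scheme_b)


def map_position(
    rmap: ResidueMap,
    pos: int,
    direction: Literal["a->b", "b->a"] = "a->b",
) -> Union[int, str]:
    """Convert a position between schemes; ``"unmapped"`` if aligned to a gap."""
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    table = rmap._fwd if direction == "a->b" else rmap._rev
    return table.get(pos, UNMAPPED)


def write_residue_map_tsv(rmap: ResidueMap, path: Union[str, Path]) -> None:
    """Export as 2-column TSV, header naming both schemes."""
    with open(path, "w") as fh:
        fh.write(f"{rmap.scheme_a}\t{rmap.scheme_b}\n")
        for a, b in rmap.pairs:
            fh.write(f"{a}\t{b}\n")


def write_fasta(
    seqs: Iterable[ProteinSequence], path: Union[str, Path], width: int = 60
) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")
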