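"""The binned disruptive-potential score.

A variant receives three components, each an even number of points from 0
to 8: one for the Cα distance from its residue to the flavin (FMN), one
for the distance to the 4Fe-4S cluster (closer is worse), and one for how
broad a taxonomic class conserves the reference residue (broader is
worse to mutate).  The summed total (0-24) maps to a four-level predicted
class: none / mild / impaired / strongly impaired.

Bin closures at 5/10/15/20 Å are <5, [5,10), [10,15), [15,20], >20: the
unique closure consistent with the reference data (10.0 Å scores 4 points
and 19.8 Å scores 2).  Class boundaries are ≤5 none, 6-10 mild, 11-15
impaired, ≥16 strongly impaired; with the default even-valued points the
totals 5, 11 and 15 are unreachable, so only the 16 boundary binds.
"""

from __future__ import annotations

from dataclasses import dataclass, field


# Table-2 style labels -> canonical clade vocabulary
_CONSERVATION_ALIASES = {
    "none": "none",
    "chordata": "chordata",
    "chordates": "chordata",
    "metazoa": "metazoa",
    "metazoans": "metazoa",
    "eukaryota": "eukaryota",
    "eukaryotes": "eukaryota",
    "all": "all",
    "all species": "all",
}


def canonical_conservation(label: str) -> str:
    try:
        return _CONSERVATION_ALIASES[label.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown conservation label {label!r}; expected one of "
            f"{sorted(set(_CONSERVATION_ALIASES))}"
        ) from None


def _default_distance_bins() -> tuple[tuple[float, int], ...]:
    # (upper edge, points); edges interpreted by distance_points's closure
    return ((5.0, 8), (10.0, 6), (15.0, 4), (20.0, 2), (float("inf"), 0))


def _default_conservation_points() -> dict[str, int]:
    return {"none": 0, "chordata": 2, "metazoa": 4, "eukaryota": 6, "all": 8}


def _default_class_boundaries() -> tuple[tuple[int, str], ...]:
    # (upper total, class), inclusive upper bounds, ascending
    return ((5, "none"), (10, "mild"), (15, "impaired"), (24, "strongly impaired"))


@dataclass(frozen=True)
class ScoreConfig:
    """Bins, points and class boundaries; config-driven so a recalibration
    never touches code."""

    distance_bins: tuple[tuple[float, int], ...] = field(
        default_factory=_default_distance_bins
    )
    conservation_points: dict[str, int] = field(
        default_factory=_default_conservation_points
    )
    class_boundaries: tuple[tuple[int, str], ...] = field(
        default_factory=_default_class_boundaries
    )

    def max_total(self) -> int:
        return self.class_boundaries[-1][0]


DEFAULT_CONFIG = ScoreConfig()


@dataclass(frozen=True)
class ScoreBreakdown:
    variant: str
    fmn_points: int
    fes_points: int
    conservation_points: int
    total: int
    predicted_class: str

    def __post_init__(self) -> None:
        if self.total != self.fmn_points + self.fes_points + self.conservation_points:
            raise ValueError("total must equal the sum of its components")


def distance_points(d: float, cfg: ScoreConfig = DEFAULT_CONFIG) -> int:
    """Points for one cofactor distance in Å.

    Closure: a distance exactly on an internal edge belongs to the bin
    below it (10.0 → the 10-15 Å bin), except the outermost edge where
    "more than 20 Å" is strict, so 20.0 still scores 2.
    """
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    bins = cfg.distance_bins
    for i, (edge, points) in enumerate(bins):
        last_finite = i == len(bins) - 2
        if (d < edge) if not last_finite else (d <= edge):
            return points
    return bins[-1][1]


def conservation_points(call: str, cfg: ScoreConfig = DEFAULT_CONFIG) -> int:
    """Points for a conservation call ('none' through 'all'); Table-style
    spellings like 'Metazoans' are accepted."""
    return cfg.conservation_points[canonical_conservation(call)]


def classify_score(total: int, cfg: ScoreConfig = DEFAULT_CONFIG) -> str:
    if not 0 <= total <= cfg.max_total():
        raise ValueError(f"total {total} outside [0, {cfg.max_total()}]")
    for upper, cls in cfg.class_boundaries:
        if total <= upper:
            return cls
    raise AssertionError("unreachable: boundaries cover the range")


def total_score(
    d_fmn: float,
    d_fes: float,
    call: str,
    cfg: ScoreConfig = DEFAULT_CONFIG,
    variant: str = "",
) -> ScoreBreakdown:
    """Full breakdown: distance points + conservation points, summed and
    classified."""
    p_fmn = distance_points(d_fmn, cfg)
    p_fes = distance_points(d_fes, cfg)
    p_cons = conservation_points(call, cfg)
    total = p_fmn + p_fes + p_cons
    return ScoreBreakdown(
        variant=variant,
        fmn_points=p_fmn,
        fes_points=p_fes,
        conservation_points=p_cons,
        total=total,
        predicted_class=classify_score(total, cfg),
    )
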