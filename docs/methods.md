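# Methods

## The disruptive-potential score

The score treats a missense substitution as disruptive to the extent that
its residue is (i) close to the FMN, (ii) close to the 4Fe-4S cluster N3,
and (iii) conserved across a broad sweep of the phylogeny. Each criterion
is binned into even point values 0–8 and the three are summed, so the
total lies in 0–24 and is always even. The scheme is deliberately coarse:
it encodes the observation that, for this subunit, proximity to either
cofactor and breadth of conservation track the severity of experimental
phenotypes, and it makes every point auditable. It does not model
residue chemistry, secondary structure, or interface context — a variant
on a structurally critical helix can be underscored (the published
reference set contains two such cases), and the score is a triage aid,
not a pathogenicity classifier.

### Bin and boundary closures

The published bin descriptions overlap at 5, 10, 15 and 20 Å and leave
totals 5 and 16 unassigned between classes. The closures used here —
distances `<5, [5,10), [10,15), [15,20], >20` and classes `≤5 none, 6–10
mild, 11–15 impaired, ≥16 strongly impaired` — are the unique choices
consistent with the reference data (a 10.0 Å distance scores 4 points, a
19.8 Å distance scores 2, and every 16-point variant is classed strongly
impaired). "More than 20 Å" is read strictly, so exactly 20.0 Å scores 2;
no reference row sits on that edge, so the choice is documented rather
than testable. With the default even points the totals 5, 11 and 15 are
unreachable, so only the 16 boundary binds in practice. Bins, points and
boundaries all live in `ScoreConfig`, so a recalibration never touches
code.

One reference row (R147W, 4 points) is printed with class "mild" although
the published rule assigns "none"; the validation mode applies the rule
and reports the label as a known discrepancy instead of failing.

## Distances

A residue's distance to a cofactor is the minimum Euclidean distance from
its Cα atom to any atom of the cofactor ("nearest atom", so hydrogens are
included when present). Cofactors are selected by hetero residue name
(FMN; SF4 for the 4Fe-4S cluster), matching deposited nomenclature. When
a file contains several copies of a cofactor — the intact complex holds
eight FeS clusters — the default policy keeps only the copy nearest the
selected polymer chain, preventing a neighbouring subunit's cluster from
shadowing N3; `copy_policy="all"` or an explicit chain restriction
overrides this. Alternate locations collapse to the highest-occupancy
conformer; insertion codes are rejected because the numbering maps assume
plain integers. Distances are kept at full precision internally and
rounded to 0.1 Å only for display, since binning at full precision and
rounding for output can differ at bin edges.

## Residue numbering

Clinical positions count from the precursor start (mitochondrial target
peptide included); structure files count the mature chain. All maps are
explicit `ResidueMap` objects labelled with their schemes, built either
from a global pairwise alignment or from the packaged constant-offset
fallback (human precursor − 20 = mature structure position, which holds
for every reference pair). Alignment uses BLOSUM62 with affine gaps: the
first position of a gap costs 10 and each further position 1, in half-bit
units. "Similarity" counts aligned pairs with a positive matrix score;
identity and similarity denominators exclude columns containing a gap.
Published identity figures for full-length homolog pairs are insensitive
to these parameters at the few-percent level, and recomputing them
requires downloading the real sequences, so they are exercised only
through the documented integration entry points, not the default suite.

## Conservation

Clade membership is cumulative over chordata ⊂ metazoa ⊂ eukaryota ⊂ all.
For a column, each clade's fraction is the share of member rows whose
character equals the reference residue; gaps and 'X' count as
non-conserved, and "conserved" means identical (not similarity-group —
the scheme tracks specific residues whose substitution is under
evaluation; the threshold and reference are configurable). The call is
the most general clade whose fraction strictly exceeds 0.95 ("> 95 %"),
so raising the threshold can only narrow a call. A clade with no member
sequences is reported as not evaluable rather than 0. The 200-sequence
alignment behind the packaged reference calls is not redistributable, so
the packaged conservation column is authoritative for score validation
and the MSA code path is exercised on constructed alignments.

## ThermoFMN melt curves

The assay's temperature protocol (hold at 20 °C, then +1.5 °C per 30 s
reading) defines the simulation grid, to a default 95 °C. Curves are
modelled as a four-parameter logistic
`F(T) = baseline + amplitude / (1 + exp(-(T - Tm)/width))`; for a
logistic the steepest slope falls at the midpoint, so the fitted midpoint
is the dissociation temperature, and the amplitude is proportional to
bound flavin — variant flavin content is reported as the amplitude ratio
to wild type, which is invariant to any common fluorescence scale.
Simulated noise is additive i.i.d. Gaussian per grid point, the standard
assumption for plate fluorimetry. Fitting is scipy least squares with a
deterministic start (baseline/amplitude from the curve extremes, midpoint
at the peak of a 3-point-smoothed finite-difference derivative, width
2 °C); a negative fitted width is folded into the mirror-symmetric
parameterisation. Non-convergence — flat input, midpoint outside the
observed range, or amplitude indistinguishable from the residual noise
floor — sets a flag instead of raising, so batch fits never abort.
Kinetic traces convert to specific activities by Beer–Lambert:
`slope / (ε · path · [protein])` yields µmol min⁻¹ mg⁻¹ when ε is in
mM⁻¹ cm⁻¹, the path in cm and protein in mg ml⁻¹; a sign flag handles
chromophore-consuming assays. Absolute flavin quantitation is out of
scope.

## Synthetic fixtures

The generators exist to give every consumer a fully controlled input, not
to imitate real data. Structures are arbitrary point sets written as
minimal single-model PDB text (Cα-only residues, HETATM cofactor atoms,
optional injected altlocs), with coordinates rounded to the format's
10⁻³ Å precision so file round-trips are exact; they contain no fold, no
side chains and no chemistry, so passing geometry tests demonstrates
correct distance arithmetic, not robustness to messy crystallographic
files (that robustness is delegated to gemmi). MSAs realize a requested
per-column call by exact counting — rows inside the target clade all
match, rows outside mismatch, with feasibility checked against the 0.95
threshold — so classifier tests are deterministic and cannot flake; the
default 40/60/50/50 clade sizes give a 200-sequence alignment, the scale
of the reference analysis, but the rows are not evolved sequences and say
nothing about real phylogenetic correlation. Melt curves are exact
logistics plus seeded noise. All generators are deterministic under a
fixed seed.

## Problem sizes and numerical tolerances

Geometry oracle checks use 100 random structures of up to ~50 atoms
(agreement 10⁻⁹ Å); conservation recovery uses 100 constructed columns of
a 200-row MSA; melt recovery uses 50 curves at 2 % noise for the
wild-type midpoint (mean within ±0.2 °C, the published wild-type
uncertainty) and 100 curves at 1 % noise across 40–60 °C (median error
< 0.1 °C); alignment scores are checked against an exhaustive affine-gap
DP for lengths ≤ 8. Noiseless melt fits recover parameters to 10⁻⁶.
These sizes keep the whole suite in the low seconds while leaving each
estimate's Monte-Carlo error well inside the asserted tolerance.

## Known limitations

The score is calibrated once against a 19-variant reference set from a
single subunit; applying it to other proteins requires new bins. Stop
gains and frameshifts are parsed but never scored. The conservation call
ignores conservative substitutions by default. The nearest-copy cofactor
policy can pick the wrong copy in heavily rearranged assemblies — pass an
explicit chain restriction there. The melt model assumes a single
two-state dissociation; multi-phasic curves will fit poorly and should be
caught via the residual norm.
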