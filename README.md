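# flavoscore

Structure- and conservation-based triage of missense variants in the
flavin-binding (51-kDa, NDUFV1) subunit of mitochondrial complex I.

NDUFV1 houses the FMN cofactor at which complex I oxidises NADH, and sits
next to the 4Fe-4S cluster N3. Missense variants in this subunit are a
recurrent cause of Leigh syndrome and related mitochondrial disease, but
clinical "pathogenic" labels are often weakly supported. `flavoscore`
implements a simple, auditable scoring scheme for the *disruptive
potential* of a substitution, together with everything needed to compute
its inputs:

- **Scoring** (`flavoscore.scoring`): each variant receives points for the
  Cα distance from its residue to the FMN (*d*<sub>FMN</sub>), for the
  distance to the FeS cluster (*d*<sub>FeS</sub>), and for the breadth of
  taxonomic conservation of the reference residue:

  | distance *d* (Å) | points |   | conservation | points |
  |---|---|---|---|---|
  | *d* < 5 | 8 |   | all species | 8 |
  | 5 ≤ *d* < 10 | 6 |   | eukaryota | 6 |
  | 10 ≤ *d* < 15 | 4 |   | metazoa | 4 |
  | 15 ≤ *d* ≤ 20 | 2 |   | chordata | 2 |
  | *d* > 20 | 0 |   | none | 0 |

  The three components are summed (0–24) and classified: ≤ 5 **none**,
  6–10 **mild**, 11–15 **impaired**, ≥ 16 **strongly impaired**.

- **Geometry** (`flavoscore.structure`): PDB/mmCIF parsing (via gemmi) and
  minimum Cα-to-cofactor distances, with altloc collapse and a
  nearest-copy policy for structures containing several FeS clusters.
- **Conservation** (`flavoscore.conservation`): per-column conserved
  fractions within nested clades (chordata ⊂ metazoa ⊂ eukaryota ⊂ all)
  from a clade-annotated MSA; the call is the most general clade with
  > 95 % conservation of the reference residue.
- **Numbering** (`flavoscore.sequences`): global pairwise alignment
  (BLOSUM62, affine gaps) and explicit residue maps between human
  precursor, mature structure, and homolog numbering — clinical position
  88 is mature-structure residue 68.
- **ThermoFMN analytics** (`flavoscore.melt`): simulation and
  four-parameter-logistic fitting of thermal flavin-dissociation curves
  (midpoint = dissociation temperature, amplitude ∝ bound flavin), plus
  Beer–Lambert conversion of plate-reader slopes to specific activities.
- **Packaged reference data** (`flavoscore.reference`): the 19 clinically
  reported NDUFV1 missense variants with their published distances,
  conservation calls and scores.

## Worked example

```python
>>> from flavoscore import score_variant
>>> r = score_variant("R88G")
>>> r.d_fmn, r.d_fes, r.conservation
(4.5, 21.0, 'All')
>>> r.score
ScoreBreakdown(variant='R88G', fmn_points=8, fes_points=0,
               conservation_points=8, total=16,
               predicted_class='strongly impaired')
```

R88G sits on the glycine-rich loop of the flavin site: 4.5 Å from the FMN
(8 points), far from the FeS cluster (0 points), and invariant across all
species (8 points) — 16 points, predicted strongly impaired, matching the
published call. Longer narrative walkthroughs live in `examples/`
(scoring all 19 variants, distance profiles, conservation calls, melt-curve
fitting, residue-number mapping); running
`python examples/score_reference_variants.py` prints the full 19-row table
and ends with

```
validation: 19/19 published totals reproduced
note: R147W: printed class 'mild' conflicts with the boundary rule
      (4 points -> 'none'); known discrepancy in the published table
```

A thin CLI mirrors the library: `flavoscore score --variant R88G
--use-packaged-table`, `flavoscore validate-table2`,
`flavoscore distance-profile <pdb> --chain A`, `flavoscore fit-melt
--curve trace.tsv`, `flavoscore simulate`. Scoring variants on a
user-supplied structure/MSA uses `score --structure ... --msa ...
--clades ... --reference-id ...`.

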