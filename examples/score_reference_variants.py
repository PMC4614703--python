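"""Score the 19 clinically reported NDUFV1 missense variants.

Uses the packaged reference inputs (Cα distances to FMN and to the 4Fe-4S
cluster measured on the bovine structure, plus clade-conservation calls)
and recomputes each variant's disruptive-potential total and predicted
class.  A total of >=16 points predicts a strongly impaired enzyme; <=5
predicts no effect.
"""

from flavoscore import score_variant, validate_table2, variant_list

print(f"{'variant':>8} {'d_FMN':>6} {'d_FeS':>6} {'conservation':>12} "
      f"{'total':>5}  predicted class")
for label in variant_list():
    r = score_variant(label)
    print(f"{label:>8} {r.d_fmn:6.1f} {r.d_fes:6.1f} {r.conservation:>12} "
          f"{r.score.total:5d}  {r.score.predicted_class}")

result = validate_table2()
print(f"\nvalidation: {result.n_score_matches}/{result.n_total} published "
      f"totals reproduced")
for w in result.warnings:
    print(f"note: {w}")
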