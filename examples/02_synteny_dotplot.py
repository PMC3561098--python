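"""Detect syntenic regions between the cybrid and its recipient mitotype.

Regions are local-similarity chains of at least 1 kb at >= 95% identity —
the standard criterion for mitotype comparisons; the coverage fractions say
how much of each genome the shared backbone explains.
"""

from cybridmt import detect_syntenic_regions, dotplot_points, simulate_cybrid, table_echo_config

cfg = table_echo_config(seed=1)
recipient, comparators, donor, cp, cybrid, truth = simulate_cybrid(cfg)

m = detect_syntenic_regions(cybrid, recipient, min_len=1000, min_identity=0.95)
n_opp = sum(r.orientation == "opposite" for r in m.regions)
print(f"syntenic regions : {len(m.regions)} ({n_opp} in opposite orientation)")
print(f"coverage (cybrid): {m.coverage_a:.2%}   coverage (recipient): "
      f"{m.coverage_b:.2%}")
print("first three regions (label, cybrid span, recipient span, orientation):")
for r in m.regions[:3]:
    print(f"  {r.label:<4} {r.a_iv.start}-{r.a_iv.end}  "
          f"{r.b_iv.start}-{r.b_iv.end}  {r.orientation}")
# dotplot_points(m) yields segment endpoints for plotting; opposite-
# orientation regions run anti-diagonally.
print(f"dot-plot segments: {len(dotplot_points(m))}")
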