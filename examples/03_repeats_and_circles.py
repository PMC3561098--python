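"""Find repeats and predict the multipartite structure.

A pair of large direct repeats lets the master circle recombine
intramolecularly into two subgenomic circles whose sizes sum to the master
length; short repeats (30-500 bp) are the substrate of smaller
rearrangements.
"""

from cybridmt import (
    detect_repeats, predict_subgenomic_circles, simulate_cybrid,
    table_echo_config,
)

cfg = table_echo_config(seed=1)
recipient, comparators, donor, cp, cybrid, truth = simulate_cybrid(cfg)

rs = detect_repeats(cybrid)
print(f"large repeats : {len(rs.large)}")
for p in rs.large:
    print(f"  {p.kind} pair, {p.rep_len:,} bp at {p.iv1.start:,} / "
          f"{p.iv2.start:,} (identity {p.identity:.3f})")
print(f"short repeats : {len(rs.short)} pairs, "
      f"{rs.short_fraction:.2%} of the genome")

direct = [p for p in rs.large if p.kind == "direct"]
c1, c2 = predict_subgenomic_circles(cybrid, direct[0])
print(f"subgenomic circles: {c1.size:,} bp + {c2.size:,} bp "
      f"= {c1.size + c2.size:,} bp (master {cybrid.length:,} bp)")
# Each subcircle keeps exactly one fused copy of the repeat.
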