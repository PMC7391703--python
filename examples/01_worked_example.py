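"""Score the documented hand-checkable world and print the breakdown.

The worked example is a 10-kb single-chromosome context with two RBPs,
one planted motif and a 20-variant population panel, small enough that
every component score can be derived on paper. This script scores the
two documented variants and shows that the pipeline reproduces the
hand-computed values exactly.
"""

import warnings

import rbpscore as rs

we = rs.worked_example()
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ctx = rs.build_world_context(we, we.config)

for rec, key in zip(we.variants.itertuples(), ("v1", "v2")):
    bd = rs.universal_score(rec.chrom, rec.pos0, rec.ref, rec.alt, ctx)
    print(f"{rec.chrom}:{rec.pos0 + 1} {rec.ref}>{rec.alt}  ({key})")
    for comp in ("s_popcons", "s_hub", "s_gerp", "s_structure",
                 "s_kd", "s_motif"):
        print(f"  {comp:12s} {getattr(bd, comp):.6f}   "
              f"(hand: {we.expected[key][comp]:.6f})")
    print(f"  {'universal':12s} {bd.universal:.6f}   "
          f"(hand: {we.expected[key]['universal']:.6f})")
    if bd.flags:
        print(f"  flags: {', '.join(bd.flags)}")
    print()

# the same variant with all three tissue-specific categories active
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    tc = rs.prepare_tissue(ctx, {"cond": we.de_table}, we.somatic,
                           we.prior_genes)
rec = we.variants.iloc[0]
bd = rs.full_score(rec.chrom, int(rec.pos0), rec.ref, rec.alt, ctx, tc)
print(f"with tissue inputs: tissue=+{bd.s_tissue} "
      f"({bd.provenance['tissue_categories']}), total={bd.total:.6f}")
print("Each +1 is a category-level indicator: key regulator, local "
      "somatic burden, key gene.")
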