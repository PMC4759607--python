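"""Locus lookup and consequence annotation on the bundled reference.

Positions are 1-based rCRS coordinates (m.-notation); the bundled sequence
is a synthetic stand-in laid over the real NC_012920 gene map, so locus
arithmetic (overlaps, the D-loop wrap, reading frames) behaves exactly as
on the real molecule.
"""

from mthet import load_locus_map

m = load_locus_map()

for pos in (3243, 8550, 16100, 310):
    loci = [l.name for l in m.locus_of(pos)] or ["intergenic"]
    mask = " [low-complexity mask]" if m.in_low_complexity(pos) else ""
    print(f"m.{pos}: {'/'.join(loci)}{mask}")
print("(m.3243 is the tRNA-Leu(UUR) position of the MELAS variant; m.8550 "
      "lies in the MTATP8/MTATP6 overlap and belongs to both genes; "
      "m.16100 is in the D-loop, which wraps the origin)")

pos = 6000
ref = m.ref_base(pos)
for alt in "ACGT":
    if alt == ref:
        continue
    ann = m.annotate(pos, ref, alt)
    e = ann.coding_effects[0]
    print(f"m.{pos}{ref}>{alt} ({ann.substitution_class:12s}) in MTCO1: "
          f"{e.ref_codon}->{e.alt_codon}  {e.ref_aa}->{e.alt_aa}  "
          f"{ann.consequence}")
print("(a change is nonsynonymous iff the encoded amino acid changes under "
      "the vertebrate mitochondrial code; transitions keep the purine/"
      "pyrimidine class, transversions switch it)")
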