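"""Simulate a small paired cohort and call heteroplasmies in one sample.

The generator draws a germline backbone plus low-level heteroplasmies per
tissue; the caller then recovers variants from strand-split allele counts
using the 1500x depth / 10 supporting reads / 1% VAF thresholds.
"""

from mthet import SimParams, call_sample, simulate_cohort

sim = simulate_cohort(SimParams(n_case_pairs=3, n_control_pairs=2, seed=11))
sid = sim.sample_ids[0]
counts = sim.allele_counts(sid)
calls = call_sample(counts, sim.locus_map)

print(f"sample {sid}: {len(calls)} calls from "
      f"{len(counts)} covered positions")
for c in calls[:8]:
    loci = ";".join(c.annotation.loci) or "intergenic"
    print(f"  m.{c.position}{c.ref_allele}>{c.alt_allele}  "
          f"VAF={c.vaf:.3f}  depth={c.depth}  {c.zygosity:13s} "
          f"{loci:8s} {c.annotation.consequence}")
n_het = sum(c.zygosity == "heteroplasmic" for c in calls)
print(f"{n_het} heteroplasmic (VAF in [1%, 99%)) and "
      f"{len(calls) - n_het} homoplasmic (>=99%) calls; homoplasmic calls "
      "are the inherited haplogroup backbone, heteroplasmic ones the "
      "low-level somatic/acquired fraction the study quantifies.")
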