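"""Reference-collection filter chain and codon-usage comparison.

A population collection of whole-mtDNA records is cleaned by sequential
filters (pathogenic carriers, non-human, non-European markers, truncated,
minor haplogroups); surviving records' coding variants are tabulated as
percentages of synonymous/nonsynonymous changes by codon position.
"""

from mthet import codon_usage_table, filter_reference_chain
from mthet.simulate import make_bookkeeping_fixture

records = make_bookkeeping_fixture("reference_chain")
survivors, ledger = filter_reference_chain(records)
print(f"{len(records)} records in")
for step, n in ledger.items():
    print(f"  removed {n:5d}  {step}")
print(f"{len(survivors)} records survive all five filters")

usage = codon_usage_table(
    {"reference": [v for r in survivors for v in r.variants]})["reference"]
print("\ncodon usage (% of coding variants), reference collection:")
print(usage.round(1).to_string())
print("(population variation is dominated by synonymous third-position "
      "changes; an excess of nonsynonymous first/second-position variants "
      "in a tissue cohort relative to this baseline suggests ongoing "
      "mutagenesis rather than inherited polymorphism)")
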