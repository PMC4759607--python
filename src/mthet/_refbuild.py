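"""Builder for the bundled synthetic reference sequence.

The package ships ``data/rcrs_synthetic.fa``: a SYNTHETIC stand-in for the
16,569 bp human mtDNA reference.  It pairs the real NC_012920 locus
coordinates (in ``data/loci.tsv``) with a seeded pseudo-random sequence, so
every coordinate-level behaviour (locus overlaps, D-loop wrap, reading
frames, incomplete stop codons) is exercised against the true gene
architecture while the base-level content carries no claim of biological
identity.  Analyses of real data should substitute the genuine rCRS FASTA
via :func:`mthet.mtgenome.load_locus_map`.

Construction rules:

* base composition approximates the mtDNA heavy strand (A/C-rich);
* the three low-complexity homopolymer tracts are written as poly-C runs so
  the default mask masks what it claims to mask;
* each coding locus gets an ATG start codon and stop-free internal codons in
  its own frame (light-strand MTND6 in the reverse-complement frame); codons
  shared with a previously laid overlapping gene are left untouched, so a
  mid-gene stop may appear inside an overlap, exactly as real MTATP8 ends
  inside MTATP6.
"""

from __future__ import annotations

import numpy as np

from .mtgenome import (GENOME_LENGTH, MT_CODON_TABLE,
                       DEFAULT_LOW_COMPLEXITY_INTERVALS, read_locus_table,
                       _revcomp)

BUILD_SEED = 20160212

_BASES = np.array(list("ACGT"))
_BASE_FREQS = (0.31, 0.31, 0.13, 0.25)  # heavy-strand-like A/C/G/T composition
_STOPS = set(MT_CODON_TABLE.stop_codons)  # TAA, TAG, AGA, AGG (table 2)
_NON_STOP_CODONS = sorted(
    c for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
    if c not in _STOPS)


def build_synthetic_reference(locus_table_path, seed: int = BUILD_SEED) -> str:
    """Deterministically build the synthetic reference sequence."""
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=GENOME_LENGTH, p=_BASE_FREQS)
    for a, b in DEFAULT_LOW_COMPLEXITY_INTERVALS:
        seq[a - 1:b] = "C"

    written = np.zeros(GENOME_LENGTH, dtype=bool)  # finalized coding bases
    loci = [l for l in read_locus_table(locus_table_path) if l.category == "coding"]
    for locus in sorted(loci, key=lambda l: l.start):
        span = np.arange(locus.start - 1, locus.end)  # 0-based; coding never wraps
        gene = "".join(seq[span])
        if locus.strand == "light":
            gene = _revcomp(gene)
        codons = [gene[i:i + 3] for i in range(0, len(gene) - len(gene) % 3, 3)]
        free = ~written[span] if locus.strand == "heavy" else ~written[span][::-1]
        for ci, codon in enumerate(codons):
            if not free[ci * 3:ci * 3 + 3].all():
                continue
            if ci == 0:
                codons[ci] = "ATG"
            elif codon in _STOPS:
                codons[ci] = _NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))]
        gene = "".join(codons) + gene[len(codons) * 3:]
        if locus.strand == "light":
            gene = _revcomp(gene)
        seq[span] = list(gene)
        written[span] = True
    return "".join(seq)


def write_fasta(sequence: str, path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(">rCRS_synthetic synthetic stand-in reference on the "
                 "NC_012920 coordinate system (not the real rCRS sequence)\n")
        for i in range(0, len(sequence), line_width):
            fh.write(sequence[i:i + line_width] + "\n")


if __name__ == "__main__":  # pragma: no cover
    from .mtgenome import _data_path
    sequence = build_synthetic_reference(_data_path("loci.tsv"))
    write_fasta(sequence, _data_path("rcrs_synthetic.fa"))
    print(f"wrote {len(sequence)} nt")
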