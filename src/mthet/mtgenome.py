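"""rCRS coordinate system, locus map, and per-variant consequence annotation.

Human mtDNA analysis is conventionally reported against the revised Cambridge
Reference Sequence (rCRS, NC_012920): a 16,569 bp circular molecule carrying 13
protein-coding genes, 22 tRNAs, 2 rRNAs and the non-coding displacement loop
(D-loop), which spans the origin (m.16024-m.576).  This module is the single
coordinate authority for the package: it loads the locus map, answers
position-to-locus queries (wrap-aware, returning both members of the
MTATP8/MTATP6 and MTND4L/MTND4 overlaps), applies the low-complexity mask, and
annotates single-base substitutions with their codon position, amino-acid
change and transition/transversion class under the vertebrate mitochondrial
genetic code.

Coordinates are 1-based inclusive rCRS positions throughout (matching the
field's ``m.`` notation); BED inputs are converted on read.

The bundled locus map uses the standard NC_012920 gene coordinates.  The
bundled *sequence* (``data/rcrs_synthetic.fa``) is a synthetic stand-in: a
seeded pseudo-random sequence with stop-codon-free reading frames laid over
the real locus map (see :mod:`mthet._refbuild`).  Users with the real rCRS
FASTA can pass it to :func:`load_locus_map`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

GENOME_LENGTH = 16569

#: NCBI translation table 2 (Vertebrate Mitochondrial).
MT_CODON_TABLE = CodonTable.unambiguous_dna_by_id[2]

_PURINES = frozenset("AG")
_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Default low-complexity exclusion mask: the three rCRS homopolymer tracts
#: around m.310, m.520 and m.16189 where short-read calls are unreliable.
DEFAULT_LOW_COMPLEXITY_INTERVALS = ((302, 316), (513, 526), (16181, 16194))

# The literature uses several synonymous symbol sets (MT-CO1, MTCO1, MTCOX1,
# COX1...).  Canonical symbols here are the compact MT* forms.
_ALIASES = {
    "MTCOX1": "MTCO1",
    "MTCOX2": "MTCO2",
    "MTCOX3": "MTCO3",
    "MTCYTB": "MTCYB",
    "MTCYTB6": "MTCYB",
    "MTDN4": "MTND4",
}


def canonical_locus(name: str) -> str:
    """Map any recognised locus alias (MT-CO1, MTCOX1, co1...) to its canonical symbol."""
    key = name.upper().replace("-", "").replace("_", "")
    if key in ("DLOOP", "D-LOOP", "CR", "CONTROLREGION"):
        return "DLOOP"
    if not key.startswith("MT"):
        key = "MT" + key
    return _ALIASES.get(key, key)


class CoordinateError(ValueError):
    """Position outside the rCRS coordinate range [1, 16569]."""


class ReferenceMismatchError(ValueError):
    """Stated reference allele disagrees with the bundled reference base."""


class AlleleError(ValueError):
    """Allele is not a single A/C/G/T base."""


@dataclass(frozen=True)
class MtLocus:
    """One annotated rCRS locus (gene, tRNA, rRNA or the D-loop).

    ``start``/``end`` are 1-based inclusive; ``end < start`` means the locus
    wraps the origin (only the D-loop does).  ``frame_offset`` is the codon
    phase of ``start`` in the locus's own reading frame (0 for all standard
    gene models).
    """

    name: str
    start: int
    end: int
    strand: str  # {"heavy", "light"}
    category: str  # {"coding", "tRNA", "rRNA", "DLOOP"}
    frame_offset: int = 0

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def __len__(self) -> int:
        if self.wraps:
            return GENOME_LENGTH - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end

    def positions(self):
        """Iterate the locus's rCRS positions 5'->3' on the heavy strand."""
        if self.wraps:
            yield from range(self.start, GENOME_LENGTH + 1)
            yield from range(1, self.end + 1)
        else:
            yield from range(self.start, self.end + 1)


@dataclass(frozen=True)
class CodingEffect:
    """Effect of a substitution within one coding locus."""

    locus: str
    codon_position: int  # 1..3 in the locus's own reading direction
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str

    @property
    def consequence(self) -> str:
        return "nonsynonymous" if self.ref_aa != self.alt_aa else "synonymous"


@dataclass(frozen=True)
class Annotation:
    """Full annotation of one substitution.

    ``consequence`` summarises across loci: nonsynonymous if any coding locus
    changes its amino acid, synonymous if coding but silent everywhere,
    noncoding otherwise.  Per-locus detail lives in ``coding_effects``.
    """

    position: int
    ref_allele: str
    alt_allele: str
    loci: tuple[str, ...]
    categories: tuple[str, ...]
    substitution_class: str  # {"transition", "transversion"}
    coding_effects: tuple[CodingEffect, ...] = ()

    @property
    def consequence(self) -> str:
        if not self.coding_effects:
            return "noncoding"
        if any(e.consequence == "nonsynonymous" for e in self.coding_effects):
            return "nonsynonymous"
        return "synonymous"

    @property
    def region_class(self) -> str:
        """Coarse region bucket used for burden stratification."""
        for cat in ("coding", "tRNA", "rRNA", "DLOOP"):
            if cat in self.categories:
                return cat
        return "intergenic"


def substitution_class(ref: str, alt: str) -> str:
    """Transition (purine<->purine, pyrimidine<->pyrimidine) or transversion."""
    if ref not in _BASES or alt not in _BASES:
        raise AlleleError(f"alleles must be single ACGT bases, got {ref!r}>{alt!r}")
    if ref == alt:
        raise AlleleError("ref and alt alleles are identical")
    return "transition" if (ref in _PURINES) == (alt in _PURINES) else "transversion"


def _translate(codon: str) -> str:
    return MT_CODON_TABLE.forward_table.get(codon, "*")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MtLocusMap:
    """The locus map plus reference sequence: coordinate authority for annotation.

    Parameters
    ----------
    loci:
        Ordered MtLocus collection covering the genome's annotated regions.
    sequence:
        The 16,569 nt reference sequence (heavy strand, position 1 first).
    low_complexity:
        1-based inclusive (start, end) intervals excluded from comparative
        analysis; defaults to the three rCRS homopolymer tracts.
    """

    def __init__(self, loci, sequence: str,
                 low_complexity=DEFAULT_LOW_COMPLEXITY_INTERVALS):
        self.loci: tuple[MtLocus, ...] = tuple(loci)
        if len(sequence) != GENOME_LENGTH:
            raise ValueError(
                f"reference length {len(sequence)} != rCRS length {GENOME_LENGTH}")
        self.sequence = sequence.upper()
        self.genome_length = GENOME_LENGTH
        self.low_complexity = frozenset(
            itertools.chain.from_iterable(
                range(a, b + 1) for a, b in low_complexity))
        self._by_name = {l.name: l for l in self.loci}

    # -- queries ----------------------------------------------------------
    def __getitem__(self, name: str) -> MtLocus:
        return self._by_name[canonical_locus(name)]

    def check_position(self, position: int) -> int:
        if not 1 <= position <= self.genome_length:
            raise CoordinateError(
                f"position {position} outside rCRS range [1, {self.genome_length}]")
        return position

    def locus_of(self, position: int) -> tuple[MtLocus, ...]:
        """All loci whose (possibly wrapped) interval contains ``position``.

        Returns an empty tuple for intergenic positions; positions in the
        MTATP8/MTATP6 or MTND4L/MTND4 overlaps return both genes.
        """
        self.check_position(position)
        return tuple(l for l in self.loci if l.contains(position))

    def in_low_complexity(self, position: int) -> bool:
        self.check_position(position)
        return position in self.low_complexity

    def ref_base(self, position: int) -> str:
        self.check_position(position)
        return self.sequence[position - 1]

    # -- annotation -------------------------------------------------------
    def _codon_at(self, locus: MtLocus, position: int):
        """Return (codon_positions, codon_position_1based) for the codon of
        ``position`` within ``locus``, in the locus's reading direction.
        Positions past the annotated end (incomplete stop) are None."""
        offsets = list(locus.positions())
        idx = offsets.index(position) if locus.wraps else position - locus.start
        if locus.strand == "light":
            # read 3'->5' on the heavy strand == 5'->3' on the light strand
            offsets = offsets[::-1]
            idx = len(offsets) - 1 - idx
        phase = (idx + locus.frame_offset) % 3
        codon_start = idx - phase
        codon_pos = [offsets[codon_start + k] if codon_start + k < len(offsets)
                     else None for k in range(3)]
        return codon_pos, phase + 1

    def annotate(self, position: int, ref_allele: str, alt_allele: str) -> Annotation:
        """Annotate a single-base substitution.

        The codon is reconstructed from the reference with the locus's frame;
        light-strand loci (MTND6) are translated from the reverse complement;
        incomplete stop codons are completed with A's (post-transcriptional
        polyadenylation).  Overlapping coding loci are annotated independently.
        """
        self.check_position(position)
        ref_allele, alt_allele = ref_allele.upper(), alt_allele.upper()
        for a in (ref_allele, alt_allele):
            if a not in _BASES:
                raise AlleleError(f"allele {a!r} is not a single ACGT base")
        if self.ref_base(position) != ref_allele:
            raise ReferenceMismatchError(
                f"ref allele {ref_allele} != reference base "
                f"{self.ref_base(position)} at m.{position}")
        sub_class = substitution_class(ref_allele, alt_allele)
        hits = self.locus_of(position)
        effects = []
        for locus in hits:
            if locus.category != "coding":
                continue
            codon_pos, within = self._codon_at(locus, position)
            ref_codon = alt_codon = ""
            for p in codon_pos:
                if p is None:  # incomplete stop completed by polyadenylation
                    ref_base = alt_base = "A"
                else:
                    ref_base = self.sequence[p - 1]
                    alt_base = alt_allele if p == position else ref_base
                if locus.strand == "light":
                    ref_base = ref_base.translate(_COMPLEMENT)
                    alt_base = alt_base.translate(_COMPLEMENT)
                ref_codon += ref_base
                alt_codon += alt_base
            effects.append(CodingEffect(
                locus=locus.name, codon_position=within,
                ref_codon=ref_codon, alt_codon=alt_codon,
                ref_aa=_translate(ref_codon), alt_aa=_translate(alt_codon)))
        return Annotation(
            position=position, ref_allele=ref_allele, alt_allele=alt_allele,
            loci=tuple(l.name for l in hits),
            categories=tuple(l.category for l in hits),
            substitution_class=sub_class,
            coding_effects=tuple(effects))

    def coding_positions(self) -> dict[int, tuple[str, ...]]:
        """Map of every coding position to the coding loci containing it."""
        out: dict[int, list[str]] = {}
        for locus in self.loci:
            if locus.category != "coding":
                continue
            for p in locus.positions():
                out.setdefault(p, []).append(locus.name)
        return {p: tuple(v) for p, v in out.items()}


# ---------------------------------------------------------------------------
# loading

def read_bed_mask(path) -> tuple[tuple[int, int], ...]:
    """Read a BED (0-based half-open) mask into 1-based inclusive intervals."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return tuple((int(s) + 1, int(e)) for s, e in zip(bed.start, bed.end))


def read_locus_table(path) -> tuple[MtLocus, ...]:
    tab = pd.read_csv(path, sep="\t", comment="#")
    return tuple(
        MtLocus(name=str(r.name_), start=int(r.start), end=int(r.end),
                strand=str(r.strand), category=str(r.category),
                frame_offset=int(r.frame_offset))
        for r in tab.rename(columns={"name": "name_"}).itertuples(index=False))


def _data_path(fname: str) -> Path:
    return Path(resources.files("mthet.data") / fname)


def load_locus_map(fasta=None, locus_table=None, bed_mask=None) -> MtLocusMap:
    """Load the locus map, by default from the bundled reference files.

    ``fasta`` may point at a real NC_012920 FASTA to replace the bundled
    synthetic stand-in sequence; ``bed_mask`` overrides the default
    low-complexity homopolymer mask.
    """
    fasta = fasta or _data_path("rcrs_synthetic.fa")
    locus_table = locus_table or _data_path("loci.tsv")
    record = next(SeqIO.parse(str(fasta), "fasta"))
    mask = (read_bed_mask(bed_mask) if bed_mask is not None
            else DEFAULT_LOW_COMPLEXITY_INTERVALS)
    return MtLocusMap(read_locus_table(locus_table), str(record.seq), mask)
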