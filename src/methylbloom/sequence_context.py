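"""Cytosine-context classification and strand-aware region arithmetic.

Plant genomes methylate cytosines in three sequence contexts — CG, CHG and
CHH, where H is A, C or T — and the context of a cytosine is determined
entirely by the two bases immediately 3' of it on its own strand.  This
module classifies contexts, enumerates every cytosine site on one or both
strands of a sequence (a G on the forward strand is a C on the reverse
strand, whose context is read on the reverse complement), and performs the
strand-aware region arithmetic needed to define gene bodies and promoter
windows (a fixed span immediately 5' of the start codon).

Coordinates are 0-based half-open internally; GFF3 I/O converts from the
1-based inclusive convention at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal

CG = "CG"
CHG = "CHG"
CHH = "CHH"
UNKNOWN = "UNKNOWN"

CONTEXTS = (CG, CHG, CHH)

_H = frozenset("ACT")
_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class InvalidSiteError(ValueError):
    """The queried position is not a cytosine."""


class InvalidAlphabetError(ValueError):
    """Sequence contains characters outside {A, C, G, T, N}."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """A stranded interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid region bounds [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: CDS footprint plus the start-codon anchor.

    ``region`` spans the genomic CDS footprint (first to last coding base);
    ``cds_segments`` lists the individual CDS exons in genome order, used
    when intronic cytosines must be excluded or when the spliced CDS is
    needed.  ``atg_pos`` is the 0-based position of the first base of the
    start codon: ``region.start`` on the forward strand, ``region.end - 1``
    on the reverse strand.
    """

    gene_id: str
    region: GenomicRegion
    atg_pos: int
    cds_segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        expected = self.region.start if self.region.strand == "+" else self.region.end - 1
        if self.atg_pos != expected:
            raise ValueError(
                f"{self.gene_id}: atg_pos {self.atg_pos} does not sit at the "
                f"strand-appropriate end of {self.region}"
            )
        if not self.cds_segments:
            object.__setattr__(
                self, "cds_segments", ((self.region.start, self.region.end),)
            )

    @property
    def strand(self) -> str:
        return self.region.strand


@dataclass(frozen=True)
class CytosineSite:
    """One cytosine with its strand, trinucleotide and methylation context."""

    chrom: str
    pos: int
    strand: str
    context: str
    trinucleotide: str

    def __post_init__(self) -> None:
        if self.context != UNKNOWN and not self.trinucleotide.startswith("C"):
            raise ValueError("classified site must have a C trinucleotide anchor")


def classify_context(trinucleotide: str) -> str:
    """Classify a cytosine's context from its 5'->3' trinucleotide.

    CG if the second base is G; CHG if the second base is H (A/C/T) and the
    third is G; CHH if both are H.  An N anywhere in the flank, or a flank
    truncated by the sequence end, yields UNKNOWN — N is never matched as H
    or G.

    Raises
    ------
    InvalidSiteError
        If the first base is not C.
    InvalidAlphabetError
        If any character is outside {A, C, G, T, N}.
    """
    tri = trinucleotide.upper()
    if len(tri) > 3:
        raise ValueError("trinucleotide input longer than 3 bases")
    if not set(tri) <= _ALPHABET:
        raise InvalidAlphabetError(f"non-ACGTN characters in {trinucleotide!r}")
    if not tri or tri[0] != "C":
        raise InvalidSiteError(f"site anchor must be C, got {trinucleotide!r}")
    if len(tri) < 2:
        return UNKNOWN
    b2 = tri[1]
    if b2 == "G":
        return CG
    if b2 not in _H:  # N
        return UNKNOWN
    if len(tri) < 3:
        return UNKNOWN
    b3 = tri[2]
    if b3 == "G":
        return CHG
    if b3 not in _H:
        return UNKNOWN
    return CHH


def enumerate_cytosine_sites(
    sequence: str,
    chrom: str = "seq",
    strands: Literal["+", "-", "both"] = "both",
    offset: int = 0,
) -> list[CytosineSite]:
    """Enumerate every cytosine site on the requested strand(s).

    Forward-strand sites anchor at each C; reverse-strand sites anchor at
    each G of the forward sequence, with context read on the reverse
    complement.  ``offset`` shifts reported positions (for sub-sequences cut
    from a chromosome).  Sites are ordered by position, then '+' before '-'.
    """
    seq = sequence.upper()
    if not set(seq) <= _ALPHABET:
        raise InvalidAlphabetError("sequence contains non-ACGTN characters")
    sites: list[CytosineSite] = []
    n = len(seq)
    want_fwd = strands in ("+", "both")
    want_rev = strands in ("-", "both")
    for i, base in enumerate(seq):
        if want_fwd and base == "C":
            tri = seq[i : i + 3]
            sites.append(
                CytosineSite(chrom, i + offset, "+", classify_context(tri), tri)
            )
        if want_rev and base == "G":
            tri = reverse_complement(seq[max(0, i - 2) : i + 1])
            sites.append(
                CytosineSite(chrom, i + offset, "-", classify_context(tri), tri)
            )
    sites.sort(key=lambda s: (s.pos, s.strand))
    return sites


@dataclass(frozen=True)
class PromoterWindow:
    """A promoter region plus a flag recording chromosome-edge clipping."""

    region: GenomicRegion
    clipped: bool


def promoter_region(
    gene: GeneModel, chrom_length: int, length: int = 1500
) -> PromoterWindow:
    """Window of ``length`` bp immediately 5' of the start codon.

    Forward-strand genes take ``[atg - length, atg)``; reverse-strand genes
    take ``[atg + 1, atg + 1 + length)``.  The window is clipped to
    ``[0, chrom_length)`` and clipping reported; a start codon flush with
    the chromosome edge yields a zero-length window.
    """
    if not (0 <= gene.region.start and gene.region.end <= chrom_length):
        raise ValueError(f"{gene.gene_id} lies outside [0, {chrom_length})")
    if gene.strand == "+":
        start, end = gene.atg_pos - length, gene.atg_pos
    else:
        start, end = gene.atg_pos + 1, gene.atg_pos + 1 + length
    clipped_start = max(0, start)
    clipped_end = min(chrom_length, end)
    return PromoterWindow(
        region=GenomicRegion(gene.region.chrom, clipped_start, clipped_end, gene.strand),
        clipped=(clipped_start != start or clipped_end != end),
    )


# --- FASTA / GFF3 I/O -------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered {id: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    """Write records as wrapped (60-column) FASTA."""
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_gene_models(gff_path) -> list[GeneModel]:
    """Load gene models (gene/mRNA/CDS features) from GFF3.

    The CDS footprint of the first mRNA per gene defines the coding region;
    GFF3 1-based inclusive coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        parent = mrnas[0] if mrnas else gene
        cds = list(db.children(parent, featuretype="CDS", order_by="start"))
        if not cds:
            continue
        segments = tuple((c.start - 1, c.end) for c in cds)
        start = min(s for s, _ in segments)
        end = max(e for _, e in segments)
        region = GenomicRegion(gene.seqid, start, end, gene.strand)
        atg = start if gene.strand == "+" else end - 1
        genes.append(GeneModel(gene.id, region, atg, segments))
    return genes


def spliced_cds(gene: GeneModel, chrom_seq: str) -> str:
    """Concatenated CDS sequence in translation (5'->3') order."""
    parts = [chrom_seq[s:e] for s, e in sorted(gene.cds_segments)]
    cds = "".join(parts)
    return reverse_complement(cds) if gene.strand == "-" else cds
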