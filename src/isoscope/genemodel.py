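"""Gene/transcript/exon data model with genome-backed sequence extraction.

Coordinates are 0-based half-open internally and converted to/from the GFF3
convention (1-based inclusive) only at the file boundary.  Exons of a
transcript are stored in transcript (5'-to-3') order, so for minus-strand
genes the genomic coordinates of successive exons decrease.  ``cds_start`` is
the genomic position of the first base of the initiation codon and
``cds_end`` the genomic position of the last base of the termination codon,
both in transcript orientation (for minus-strand transcripts
``cds_start > cds_end``).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio.Seq import reverse_complement

from .errors import MalformedAnnotationError, OutOfBoundsError

Genome = Mapping[str, str]

_STRANDS = ("+", "-")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on one strand of one sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


def _check_chain(exons: Sequence[GenomicInterval], what: str) -> None:
    """Validate a 5'->3' exon chain: one chrom/strand, ordered, no overlap."""
    if not exons:
        raise MalformedAnnotationError(f"{what}: empty exon chain")
    chrom, strand = exons[0].chrom, exons[0].strand
    for e in exons:
        if e.chrom != chrom or e.strand != strand:
            raise MalformedAnnotationError(f"{what}: exons on mixed chrom/strand")
    for a, b in zip(exons, exons[1:]):
        if strand == "+" and b.start < a.end:
            raise MalformedAnnotationError(f"{what}: exons unordered or overlapping")
        if strand == "-" and b.end > a.start:
            raise MalformedAnnotationError(f"{what}: exons unordered or overlapping")


@dataclass(frozen=True)
class Transcript:
    """One mRNA: an exon chain in transcript order plus optional CDS bounds."""

    id: str
    exons: tuple[GenomicInterval, ...]
    cds_start: int | None = None
    cds_end: int | None = None
    trans_spliced: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        _check_chain(self.exons, f"transcript {self.id}")
        for pos, name in ((self.cds_start, "cds_start"), (self.cds_end, "cds_end")):
            if pos is not None and not any(e.contains_point(pos) for e in self.exons):
                raise MalformedAnnotationError(
                    f"transcript {self.id}: {name}={pos} not inside any exon"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    @property
    def first_exon(self) -> GenomicInterval:
        return self.exons[0]

    @property
    def last_exon(self) -> GenomicInterval:
        return self.exons[-1]

    @property
    def tss(self) -> int:
        """Genomic position of the transcript's 5'-most base."""
        e = self.exons[0]
        return e.start if self.strand == "+" else e.end - 1

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    # -- coordinate conversion ------------------------------------------
    def to_spliced(self, pos: int) -> int:
        """Spliced (transcript) offset of genomic position ``pos``."""
        off = 0
        for e in self.exons:
            if e.contains_point(pos):
                within = pos - e.start if self.strand == "+" else e.end - 1 - pos
                return off + within
            off += len(e)
        raise OutOfBoundsError(f"position {pos} not exonic in {self.id}")

    def to_genomic(self, offset: int) -> int:
        """Genomic position of spliced offset ``offset``."""
        if offset < 0:
            raise OutOfBoundsError(f"negative spliced offset {offset}")
        for e in self.exons:
            if offset < len(e):
                return e.start + offset if self.strand == "+" else e.end - 1 - offset
            offset -= len(e)
        raise OutOfBoundsError(f"spliced offset beyond transcript {self.id}")

    @property
    def cds_spliced_start(self) -> int:
        if self.cds_start is None:
            raise MalformedAnnotationError(f"transcript {self.id} has no CDS")
        return self.to_spliced(self.cds_start)

    @property
    def cds_spliced_end(self) -> int:
        if self.cds_end is None:
            raise MalformedAnnotationError(f"transcript {self.id} has no CDS")
        return self.to_spliced(self.cds_end)

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Introns as (start, end) genomic half-open pairs, transcript order."""
        return tuple((i.start, i.end) for i in introns_of(self))


def introns_of(t: Transcript) -> list[GenomicInterval]:
    """Gaps between consecutive exons, in transcript (5'->3') order."""
    out: list[GenomicInterval] = []
    for a, b in zip(t.exons, t.exons[1:]):
        if t.strand == "+":
            out.append(GenomicInterval(t.chrom, a.end, b.start, "+"))
        else:
            out.append(GenomicInterval(t.chrom, b.end, a.start, "-"))
    return out


def donor_site(intron: GenomicInterval) -> int:
    """Boundary coordinate of the intron's 5' (donor) end, half-open terms."""
    return intron.start if intron.strand == "+" else intron.end


def acceptor_site(intron: GenomicInterval) -> int:
    """Boundary coordinate of the intron's 3' (acceptor) end."""
    return intron.end if intron.strand == "+" else intron.start


@dataclass(frozen=True)
class GeneModel:
    id: str
    transcripts: tuple[Transcript, ...]
    molecular_name: str = ""
    genetic_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if not self.transcripts:
            raise MalformedAnnotationError(f"gene {self.id}: no transcripts")
        chrom = self.transcripts[0].chrom
        strand = self.transcripts[0].strand
        for t in self.transcripts:
            if t.chrom != chrom:
                raise MalformedAnnotationError(f"gene {self.id}: mixed chromosomes")
            if t.strand != strand:
                raise MalformedAnnotationError(f"gene {self.id}: mixed strands")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        lo = min(t.span.start for t in self.transcripts)
        hi = max(t.span.end for t in self.transcripts)
        return GenomicInterval(self.chrom, lo, hi, self.strand)

    def transcript(self, tid: str) -> Transcript:
        for t in self.transcripts:
            if t.id == tid:
                return t
        raise KeyError(tid)


# ---------------------------------------------------------------------------
# sequence extraction


def spliced_sequence(t: Transcript, genome: Genome) -> str:
    """Concatenated exon sequence in transcript order (reverse-complemented
    for minus-strand transcripts)."""
    try:
        seq = genome[t.chrom]
    except KeyError as exc:
        raise OutOfBoundsError(f"sequence {t.chrom!r} not in genome") from exc
    parts = []
    for e in t.exons:
        if e.end > len(seq):
            raise OutOfBoundsError(
                f"exon [{e.start},{e.end}) beyond end of {t.chrom} (len {len(seq)})"
            )
        part = seq[e.start : e.end]
        parts.append(part if t.strand == "+" else reverse_complement(part))
    return "".join(parts)


def spliced_cds(t: Transcript, genome: Genome) -> str:
    """Spliced CDS nucleotide string, initiation through termination codon."""
    s = spliced_sequence(t, genome)
    return s[t.cds_spliced_start : t.cds_spliced_end + 1]


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O


def _attr(attrs, key: str, default: str = "") -> str:
    vals = attrs.get(key, [])
    return vals[0] if vals else default


def parse_gene_models(gff_text: str, genome: Genome | None = None) -> list[GeneModel]:
    """Parse a GFF3 string (gene/mRNA/exon/CDS hierarchy) into gene models.

    1-based inclusive file coordinates become 0-based half-open; exon chains
    of minus-strand transcripts come out in transcript order (descending
    genomic coordinates).
    """
    if not any(
        line.strip() and not line.startswith("#") for line in gff_text.splitlines()
    ):
        return []
    db = gffutils.create_db(
        gff_text,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by="start"):
        gene_iv = GenomicInterval(g.seqid, g.start - 1, g.end, g.strand)
        transcripts: list[Transcript] = []
        for m in db.children(g, featuretype="mRNA"):  # keep file order
            exons = [
                GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
                for e in db.children(m, featuretype="exon", order_by="start")
            ]
            if not exons:
                raise MalformedAnnotationError(f"mRNA {m.id}: no exons")
            for e in exons:
                if not gene_iv.contains(e):
                    raise MalformedAnnotationError(
                        f"gene {g.id}: exon [{e.start},{e.end}) outside gene span"
                    )
            if m.strand == "-":
                exons = exons[::-1]
            cds = sorted(
                (c.start - 1, c.end)
                for c in db.children(m, featuretype="CDS", order_by="start")
            )
            cds_start = cds_end = None
            if cds:
                for lo, hi in cds:
                    seg = GenomicInterval(m.seqid, lo, hi, m.strand)
                    if not any(e.contains(seg) for e in exons):
                        raise MalformedAnnotationError(
                            f"mRNA {m.id}: CDS [{lo},{hi}) not contained in exons"
                        )
                if m.strand == "+":
                    cds_start, cds_end = cds[0][0], cds[-1][1] - 1
                else:
                    cds_start, cds_end = cds[-1][1] - 1, cds[0][0]
            transcripts.append(
                Transcript(
                    id=m.id,
                    exons=tuple(exons),
                    cds_start=cds_start,
                    cds_end=cds_end,
                    trans_spliced=_attr(m.attributes, "trans_spliced") == "true",
                )
            )
        if genome is not None and g.seqid not in genome:
            raise OutOfBoundsError(f"gene {g.id}: sequence {g.seqid!r} not in genome")
        genes.append(
            GeneModel(
                id=g.id,
                transcripts=tuple(transcripts),
                molecular_name=_attr(g.attributes, "molecular_name"),
                genetic_name=_attr(g.attributes, "genetic_name"),
            )
        )
    return genes


def _cds_segments(t: Transcript) -> list[tuple[int, int]]:
    """Genomic CDS segments (ascending, half-open), clipped to exons."""
    if t.cds_start is None or t.cds_end is None:
        return []
    lo = min(t.cds_start, t.cds_end)
    hi = max(t.cds_start, t.cds_end) + 1
    segs = []
    for e in sorted(t.exons, key=lambda e: e.start):
        s, x = max(e.start, lo), min(e.end, hi)
        if s < x:
            segs.append((s, x))
    return segs


def write_gff3(genes: Iterable[GeneModel], source: str = "isoscope") -> str:
    """Serialize gene models to GFF3 text (byte-stable for a given input)."""
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for g in genes:
        span = g.span
        attrs = [f"ID={g.id}"]
        if g.molecular_name:
            attrs.append(f"molecular_name={g.molecular_name}")
        if g.genetic_name:
            attrs.append(f"genetic_name={g.genetic_name}")
        out.write(
            f"{g.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
            f"{g.strand}\t.\t{';'.join(attrs)}\n"
        )
        for t in g.transcripts:
            ts = t.span
            mattrs = f"ID={t.id};Parent={g.id}"
            if t.trans_spliced:
                mattrs += ";trans_spliced=true"
            out.write(
                f"{g.chrom}\t{source}\tmRNA\t{ts.start + 1}\t{ts.end}\t.\t"
                f"{g.strand}\t.\t{mattrs}\n"
            )
            for i, e in enumerate(sorted(t.exons, key=lambda e: e.start), 1):
                out.write(
                    f"{g.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={t.id}.exon{i};Parent={t.id}\n"
                )
            segs = _cds_segments(t)
            # GFF3 phase: bases to skip to reach the next codon start,
            # accumulated in translation order.
            order = segs if t.strand == "+" else segs[::-1]
            phases: dict[tuple[int, int], int] = {}
            done = 0
            for seg in order:
                phases[seg] = (3 - done % 3) % 3
                done += seg[1] - seg[0]
            for i, (lo, hi) in enumerate(segs, 1):
                out.write(
                    f"{g.chrom}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t{g.strand}\t"
                    f"{phases[(lo, hi)]}\tID={t.id}.cds{i};Parent={t.id}\n"
                )
    return out.getvalue()


def load_genome(path) -> dict[str, str]:
    """Read a FASTA file into a plain {name: sequence} mapping."""
    import pyfaidx

    with pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(genome: Genome, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
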