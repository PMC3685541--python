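"""Transcript-support records (EST / RT-PCR / ORFeome-clone alignments) and
evidence grading.

A record supports a transcript when its splice-junction chain matches a
consecutive run of the transcript's junctions (within a configurable
per-coordinate tolerance) and its outer blocks fall inside the flanking
exons — i.e. the record is a contiguous sub-path of the transcript's exon
chain.  Records compatible with several transcripts support all of them.

Grading follows the assessment logic used for transcription factor gene
curation: a transcript with at least ``strong_threshold`` (default 2)
independent, 5'-complete ESTs — independence proxied by distinct library
keys — grades STRONG; any lesser support (few ESTs, truncated ESTs, RT-PCR
or ORFeome clones) grades WEAK; no support grades UNSUPPORTED.  5'-truncated
cDNAs (incomplete first-strand synthesis) and intronless reads spanning
annotated introns (unarrested genomic transcription) are the two artifact
modes that are flagged rather than trusted: a truncated EST never by itself
defines a distinct transcript start, and an unspliced read supports no
spliced transcript at all.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .genemodel import GeneModel, GenomicInterval, Transcript, _check_chain


class Source(str, enum.Enum):
    EST = "EST"
    RT_PCR = "RT_PCR"
    ORFEOME_CLONE = "ORFEOME_CLONE"


class Grade(str, enum.Enum):
    STRONG = "STRONG"
    WEAK = "WEAK"
    UNSUPPORTED = "UNSUPPORTED"


class ArtifactFlag(str, enum.Enum):
    TRUNCATED_5P = "TRUNCATED_5P"
    UNSPLICED = "UNSPLICED"
    PRIMER_DERIVED = "PRIMER_DERIVED"


@dataclass(frozen=True)
class SupportRecord:
    """One pre-aligned transcript-evidence alignment as an exon chain."""

    id: str
    source: Source
    blocks: tuple[GenomicInterval, ...]  # transcript (5'->3') order
    five_prime_complete: bool = True
    primer_defined_start: bool = False
    library: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        _check_chain(self.blocks, f"record {self.id}")

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        out = []
        for a, b in zip(self.blocks, self.blocks[1:]):
            if self.strand == "+":
                out.append((a.end, b.start))
            else:
                out.append((b.end, a.start))
        return tuple(out)

    @property
    def five_prime_pos(self) -> int:
        e = self.blocks[0]
        return e.start if self.strand == "+" else e.end - 1

    @property
    def span(self) -> GenomicInterval:
        lo = min(b.start for b in self.blocks)
        hi = max(b.end for b in self.blocks)
        return GenomicInterval(self.chrom, lo, hi, self.strand)


@dataclass(frozen=True)
class EvidenceGrade:
    transcript_id: str
    grade: Grade
    n_independent: int  # distinct libraries among complete ESTs
    n_records: int
    artifact_flags: frozenset[str] = frozenset()


@dataclass
class SupportAssignment:
    by_transcript: dict[str, list[SupportRecord]]
    unassigned: list[SupportRecord] = field(default_factory=list)
    unspliced_ids: set[str] = field(default_factory=set)


def _close(a: int, b: int, tol: int) -> bool:
    return abs(a - b) <= tol


def record_supports(rec: SupportRecord, t: Transcript, tolerance: int = 0) -> bool:
    """True when ``rec`` is a contiguous sub-path of ``t``'s exon chain."""
    if rec.chrom != t.chrom or rec.strand != t.strand:
        return False
    rj, tj = rec.junctions, t.junctions
    m = len(rec.blocks)
    if m == 1:
        return any(
            e.start - tolerance <= rec.blocks[0].start
            and rec.blocks[0].end <= e.end + tolerance
            for e in t.exons
        )
    for k in range(len(tj) - len(rj) + 1):
        if all(
            _close(rj[i][0], tj[k + i][0], tolerance)
            and _close(rj[i][1], tj[k + i][1], tolerance)
            for i in range(len(rj))
        ):
            first_ok = (
                t.exons[k].start - tolerance <= rec.blocks[0].start
                and rec.blocks[0].end <= t.exons[k].end + tolerance
            )
            last_exon = t.exons[k + m - 1]
            last_ok = (
                last_exon.start - tolerance <= rec.blocks[-1].start
                and rec.blocks[-1].end <= last_exon.end + tolerance
            )
            if first_ok and last_ok:
                return True
    return False


def assign_support(
    records: Iterable[SupportRecord], gene: GeneModel, tolerance: int = 0
) -> SupportAssignment:
    """Map each record to every transcript it supports.

    Junction-bearing records compatible with no transcript come back
    unassigned, as do intronless records spanning an annotated intron (the
    latter additionally flagged UNSPLICED: they look like the primary
    unspliced transcript, not evidence for any spliced form).
    """
    assignment = SupportAssignment({t.id: [] for t in gene.transcripts})
    for rec in records:
        hit = False
        for t in gene.transcripts:
            if record_supports(rec, t, tolerance):
                assignment.by_transcript[t.id].append(rec)
                hit = True
        if not hit:
            assignment.unassigned.append(rec)
            if len(rec.blocks) == 1 and any(
                rec.span.overlaps(i)
                for t in gene.transcripts
                for i in _introns(t)
            ):
                assignment.unspliced_ids.add(rec.id)
    return assignment


def _introns(t: Transcript):
    from .genemodel import introns_of

    return introns_of(t)


def _defines_start(rec: SupportRecord, t: Transcript) -> bool:
    """A record can vouch for a transcript's 5' start only if its 5' end is
    complete and lies in the transcript's first exon."""
    return rec.five_prime_complete and t.first_exon.contains_point(rec.five_prime_pos)


def grade_evidence(
    assignment: SupportAssignment,
    gene: GeneModel,
    strong_threshold: int = 2,
) -> dict[str, EvidenceGrade]:
    """Grade each transcript's support.

    ``n_independent`` counts distinct libraries among 5'-complete EST
    records; truncated ESTs and clone/PCR products keep a transcript at WEAK
    no matter how numerous.
    """
    grades: dict[str, EvidenceGrade] = {}
    for t in gene.transcripts:
        recs = assignment.by_transcript.get(t.id, [])
        libs = {
            r.library
            for r in recs
            if r.source == Source.EST and r.five_prime_complete
        }
        n_indep = len(libs)
        flags: set[str] = set()
        start_defining = [r for r in recs if _defines_start(r, t)]
        if any(not r.five_prime_complete for r in recs) and not start_defining:
            flags.add(ArtifactFlag.TRUNCATED_5P.value)
        if start_defining and all(r.primer_defined_start for r in start_defining):
            flags.add(ArtifactFlag.PRIMER_DERIVED.value)
        if recs and all(len(r.blocks) == 1 for r in recs) and any(
            len(u.exons) > 1 for u in gene.transcripts
        ):
            flags.add(ArtifactFlag.UNSPLICED.value)
        if n_indep >= strong_threshold:
            grade = Grade.STRONG
        elif recs:
            grade = Grade.WEAK
        else:
            grade = Grade.UNSUPPORTED
        grades[t.id] = EvidenceGrade(
            transcript_id=t.id,
            grade=grade,
            n_independent=n_indep,
            n_records=len(recs),
            artifact_flags=frozenset(flags),
        )
    return grades


# ---------------------------------------------------------------------------
# TSV I/O (BED12-like block encoding, one record per row)

_COLUMNS = [
    "record_id",
    "source",
    "library",
    "chrom",
    "strand",
    "block_starts",
    "block_sizes",
    "five_prime_complete",
    "primer_defined_start",
]


def write_support_records(records: Sequence[SupportRecord], path) -> None:
    rows = []
    for r in records:
        blocks = sorted(r.blocks, key=lambda b: b.start)
        rows.append(
            {
                "record_id": r.id,
                "source": r.source.value,
                "library": r.library,
                "chrom": r.chrom,
                "strand": r.strand,
                "block_starts": ",".join(str(b.start) for b in blocks),
                "block_sizes": ",".join(str(len(b)) for b in blocks),
                "five_prime_complete": int(r.five_prime_complete),
                "primer_defined_start": int(r.primer_defined_start),
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_support_records(path) -> list[SupportRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: list[SupportRecord] = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in row.block_starts.split(",")]
        sizes = [int(x) for x in row.block_sizes.split(",")]
        blocks = [
            GenomicInterval(row.chrom, s, s + n, row.strand)
            for s, n in zip(starts, sizes)
        ]
        if row.strand == "-":
            blocks = blocks[::-1]
        out.append(
            SupportRecord(
                id=row.record_id,
                source=Source(row.source),
                blocks=tuple(blocks),
                five_prime_complete=bool(int(row.five_prime_complete)),
                primer_defined_start=bool(int(row.primer_defined_start)),
                library=row.library,
            )
        )
    return out
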