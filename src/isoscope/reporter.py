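"""In-silico recombineering: apply seamless edits to a locus, predict which
transcripts express a translational reporter, and design construct panels
that distinguish a gene's transcripts.

The model mirrors the seamless-fosmid strategy: a reporter coding sequence
is inserted immediately after an initiation codon or immediately before a
termination codon; single-base insertions placed upstream of a targeted
initiation codon shift the reading frame of — and silence the reporter for —
transcripts starting further upstream; substitutions can create in-frame
stops.  Splicing is assumed unchanged by edits unless an edit touches a
splice dinucleotide, in which case a warning is issued instead of a silent
prediction.

Expression is binary per transcript: a transcript expresses the reporter iff
translation from its annotated initiation codon reaches the reporter with no
prior stop and traverses it in the reporter's own frame 0.  Initiation
codons created by edits are ignored; each transcript keeps its annotated
start.
"""

from __future__ import annotations

import enum
import warnings as _warnings
from dataclasses import dataclass, replace
from typing import Sequence

from Bio.Seq import reverse_complement

from .errors import EditError, OutOfBoundsError, SpliceDisruptionWarning
from .genemodel import (
    GeneModel,
    Genome,
    GenomicInterval,
    Transcript,
    introns_of,
    spliced_sequence,
)
from .orf import STOP_CODONS

# default reporter payload: a short, stop-free coding cassette standing in
# for a fluorescent-protein CDS (length a multiple of 3, no frame-0 stop)
DEFAULT_REPORTER = (
    "ATGGTCAGCAAGGGCGAGGAGCTGTTCACCGGCGTCGTGCCCATCCTGGTCGAGCTGGACGGC"
    "GACGTAAACGGCCACAAGTTCAGC"[:84]
)


class EditKind(str, enum.Enum):
    REPORTER_INSERTION = "REPORTER_INSERTION"
    NT_INSERTION = "NT_INSERTION"
    SUBSTITUTION = "SUBSTITUTION"
    DELETION = "DELETION"


class Reason(str, enum.Enum):
    IN_FRAME = "IN_FRAME"
    FRAMESHIFTED_UPSTREAM = "FRAMESHIFTED_UPSTREAM"
    PREMATURE_STOP = "PREMATURE_STOP"
    REPORTER_NOT_IN_TRANSCRIPT = "REPORTER_NOT_IN_TRANSCRIPT"
    SPLICED_OUT = "SPLICED_OUT"


@dataclass(frozen=True)
class Edit:
    """One genome modification.

    ``position`` is a 0-based genomic coordinate; insertions place the
    payload *before* the base at ``position``.  Payloads are given on the
    plus strand of the genome.  ``length`` is used by deletions only.
    """

    kind: EditKind
    chrom: str
    position: int
    payload: str = ""
    length: int = 0

    def __post_init__(self) -> None:
        if self.kind == EditKind.REPORTER_INSERTION:
            if not self.payload or len(self.payload) % 3:
                raise EditError("reporter payload length must be a positive multiple of 3")
        if self.kind == EditKind.NT_INSERTION and not self.payload:
            raise EditError("NT_INSERTION needs a payload")
        if self.kind == EditKind.SUBSTITUTION and not self.payload:
            raise EditError("SUBSTITUTION needs a payload")
        if self.kind == EditKind.DELETION and self.length <= 0:
            raise EditError("DELETION needs a positive length")

    @property
    def delta(self) -> int:
        if self.kind in (EditKind.REPORTER_INSERTION, EditKind.NT_INSERTION):
            return len(self.payload)
        if self.kind == EditKind.DELETION:
            return -self.length
        return 0

    @property
    def footprint(self) -> tuple[int, int]:
        """Genomic half-open interval the edit consumes (empty for insertions)."""
        if self.kind in (EditKind.REPORTER_INSERTION, EditKind.NT_INSERTION):
            return (self.position, self.position)
        if self.kind == EditKind.SUBSTITUTION:
            return (self.position, self.position + len(self.payload))
        return (self.position, self.position + self.length)


def _check_reporter_frame0(payload: str, strand: str) -> None:
    seq = payload if strand == "+" else reverse_complement(payload)
    for i in range(0, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            raise EditError("reporter payload contains an in-frame stop codon")


@dataclass
class ReporterOutcome:
    transcript_id: str
    expresses: bool
    reason: Reason


@dataclass
class EditResult:
    gene: GeneModel
    genome: dict[str, str]
    reporter_span: GenomicInterval | None
    warnings: tuple[str, ...] = ()


def _shift_maker(edit: Edit):
    """Coordinate map from pre-edit to post-edit genomic positions."""
    lo, hi = edit.footprint
    d = edit.delta

    def shift(pos: int) -> int:
        if edit.kind in (EditKind.REPORTER_INSERTION, EditKind.NT_INSERTION):
            return pos + d if pos >= edit.position else pos
        if edit.kind == EditKind.DELETION:
            if pos >= hi:
                return pos + d
            if pos > lo:
                return lo  # clamped into the deleted window
            return pos
        return pos

    return shift


def apply_edits(
    g: GeneModel, genome: Genome, edits: Sequence[Edit]
) -> EditResult:
    """Apply non-overlapping edits; annotation 3' of each edit is shifted by
    the net length change.  Edits touching a splice dinucleotide raise a
    SpliceDisruptionWarning (splicing can no longer be assumed unchanged)."""
    if not edits:
        return EditResult(g, dict(genome), None, ())
    chrom = g.chrom
    for e in edits:
        if e.chrom != chrom:
            raise EditError(f"edit on {e.chrom}, gene on {chrom}")
        span = g.span
        if not (span.start <= e.position <= span.end):
            raise EditError(f"edit position {e.position} outside gene span")
    # overlap check (insertions at the same point also conflict)
    marks = sorted((e.footprint, e.kind) for e in edits)
    for (f1, _), (f2, _) in zip(marks, marks[1:]):
        if f2[0] < f1[1] or f1 == f2:
            raise EditError("overlapping edits")

    reporters = [e for e in edits if e.kind == EditKind.REPORTER_INSERTION]
    if len(reporters) > 1:
        raise EditError("at most one reporter insertion per construct")
    if reporters:
        _check_reporter_frame0(reporters[0].payload, g.strand)

    warn_msgs = _splice_warnings(g, edits)

    seq = genome[chrom]
    shifts = []
    for e in sorted(edits, key=lambda e: e.position, reverse=True):
        lo, hi = e.footprint
        if e.kind in (EditKind.REPORTER_INSERTION, EditKind.NT_INSERTION):
            seq = seq[:lo] + e.payload + seq[lo:]
        elif e.kind == EditKind.SUBSTITUTION:
            seq = seq[:lo] + e.payload + seq[hi:]
        else:
            seq = seq[:lo] + seq[hi:]
        shifts.append(_shift_maker(e))

    def map_pos(pos: int) -> int:
        for s in shifts:  # applied 3'-most first; all maps commute as sorted
            pos = s(pos)
        return pos

    def map_interval(iv: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(iv.chrom, map_pos(iv.start), map_pos(iv.end), iv.strand)

    new_transcripts = []
    for t in g.transcripts:
        new_transcripts.append(
            replace(
                t,
                exons=tuple(map_interval(e) for e in t.exons),
                cds_start=None if t.cds_start is None else map_pos(t.cds_start),
                cds_end=None if t.cds_end is None else map_pos(t.cds_end),
            )
        )
    new_gene = replace(g, transcripts=tuple(new_transcripts))
    new_genome = dict(genome)
    new_genome[chrom] = seq

    reporter_span = None
    if reporters:
        rep = reporters[0]
        start = map_pos(rep.position)
        # insertion itself shifted the bases at >= position; the payload sits
        # where the original position mapped to, minus its own length shift
        start -= len(rep.payload)
        reporter_span = GenomicInterval(
            chrom, start, start + len(rep.payload), g.strand
        )

    for msg in warn_msgs:
        _warnings.warn(msg, SpliceDisruptionWarning, stacklevel=2)
    return EditResult(new_gene, new_genome, reporter_span, tuple(warn_msgs))


def _splice_warnings(g: GeneModel, edits: Sequence[Edit]) -> list[str]:
    msgs = []
    dinucs = []
    for t in g.transcripts:
        for i in introns_of(t):
            dinucs.append((t.id, i.start, i.start + 2))
            dinucs.append((t.id, i.end - 2, i.end))
    for e in edits:
        lo, hi = e.footprint
        for tid, dlo, dhi in dinucs:
            splits = lo == hi and dlo < lo < dhi  # insertion inside the dinucleotide
            covers = lo < dhi and dlo < hi
            if splits or covers:
                msgs.append(
                    f"edit at {e.position} touches a splice dinucleotide of {tid}"
                )
                break
    return msgs


# ---------------------------------------------------------------------------
# expression prediction


def predict_reporter(
    g: GeneModel, genome: Genome, reporter_span: GenomicInterval
) -> list[ReporterOutcome]:
    """Per-transcript prediction of reporter translation on an edited locus.

    Reasons: SPLICED_OUT when the reporter lies in the transcript's intron;
    REPORTER_NOT_IN_TRANSCRIPT when it is outside the transcript's exons (or
    upstream of its initiation codon, where it is never translated);
    FRAMESHIFTED_UPSTREAM when the reporter is reached out of frame;
    PREMATURE_STOP when a stop intervenes; IN_FRAME otherwise.
    """
    out = []
    for t in g.transcripts:
        out.append(ReporterOutcome(t.id, *_predict_one(t, genome, reporter_span)))
    return out


def _predict_one(
    t: Transcript, genome: Genome, rep: GenomicInterval
) -> tuple[bool, Reason]:
    in_exon = any(e.contains(rep) for e in t.exons)
    if not in_exon:
        if any(i.contains(rep) for i in introns_of(t)):
            return False, Reason.SPLICED_OUT
        return False, Reason.REPORTER_NOT_IN_TRANSCRIPT
    if t.cds_start is None:
        return False, Reason.REPORTER_NOT_IN_TRANSCRIPT
    # spliced offset of the reporter's 5'-most base in transcript orientation
    five_p = rep.start if t.strand == "+" else rep.end - 1
    rep_off = t.to_spliced(five_p)
    cds_off = t.cds_spliced_start
    if rep_off < cds_off:
        return False, Reason.REPORTER_NOT_IN_TRANSCRIPT
    if (rep_off - cds_off) % 3 != 0:
        return False, Reason.FRAMESHIFTED_UPSTREAM
    # translation is modelled from the annotated initiation point; an edit
    # that rewrote the start codon itself is out of model, so the scan does
    # not re-check for ATG here
    seq = spliced_sequence(t, genome)
    stop = _first_stop(seq, cds_off)
    if stop is not None and stop < rep_off:
        return False, Reason.PREMATURE_STOP
    return True, Reason.IN_FRAME


def _first_stop(seq: str, start: int) -> int | None:
    for i in range(start, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


# ---------------------------------------------------------------------------
# construct design


@dataclass
class Construct:
    name: str
    edits: tuple[Edit, ...]
    vector: dict[str, bool]
    outcomes: tuple[ReporterOutcome, ...]


@dataclass
class DesignResult:
    constructs: list[Construct]
    inseparable: list[frozenset[str]]  # classes of transcripts no construct splits


def _after_start_position(t: Transcript) -> int | None:
    """Genomic insertion point immediately 3' of the initiation codon."""
    if t.cds_start is None:
        return None
    # require the ATG contiguous within one exon
    codon = [t.to_genomic(t.cds_spliced_start + k) for k in range(3)]
    exon = next(e for e in t.exons if e.contains_point(codon[0]))
    if not all(exon.contains_point(p) for p in codon):
        return None
    return codon[2] + 1 if t.strand == "+" else codon[2]


def _before_start_position(t: Transcript) -> int:
    return t.cds_start if t.strand == "+" else t.cds_start + 1


def _before_stop_position(t: Transcript) -> int | None:
    if t.cds_end is None:
        return None
    return t.cds_end - 2 if t.strand == "+" else t.cds_end + 3


def design_constructs(
    g: GeneModel,
    genome: Genome,
    reporter_payload: str = DEFAULT_REPORTER,
) -> DesignResult:
    """Design the standard reporter panel for a gene.

    One reporter insertion immediately after each distinct initiation codon
    (adding a single-base insertion 5' of the targeted codon when an
    upstream-starting transcript would otherwise translate the reporter in
    frame) plus one insertion immediately before each distinct termination
    codon.  For every optional exon or retained intron, one further
    construct pairs the terminal fusion with a single-base insertion into
    the middle of the optional element, disrupting the reading frame of —
    and reporter expression from — exactly the transcripts that include it.
    A single-transcript gene gets only the terminal fusion.  The
    per-construct expression-indicator vectors are computed by
    ``predict_reporter``; transcript classes that no construct separates
    (e.g. a few-base splice-site shift) are reported as inseparable.
    """
    from .mechanisms import Mechanism, detect_mechanisms
    strand = g.strand
    payload = reporter_payload if strand == "+" else reverse_complement(
        reporter_payload
    )
    constructs: list[Construct] = []

    def build(name: str, edits: list[Edit]) -> Construct:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", SpliceDisruptionWarning)
            res = apply_edits(g, genome, edits)
        outcomes = predict_reporter(res.gene, res.genome, res.reporter_span)
        return Construct(
            name=name,
            edits=tuple(edits),
            vector={o.transcript_id: o.expresses for o in outcomes},
            outcomes=tuple(outcomes),
        )

    multi = len(g.transcripts) > 1
    if multi:
        seen_starts: set[int] = set()
        for t in g.transcripts:
            p = _after_start_position(t)
            if p is None or t.cds_start in seen_starts:
                continue
            seen_starts.add(t.cds_start)
            rep_edit = Edit(EditKind.REPORTER_INSERTION, g.chrom, p, payload)
            c = build(f"start_{t.id}", [rep_edit])
            upstream_leak = any(
                c.vector[u.id]
                for u in g.transcripts
                if u.cds_start != t.cds_start
            )
            if upstream_leak:
                fs = Edit(
                    EditKind.NT_INSERTION, g.chrom, _before_start_position(t), "C"
                )
                c = build(f"start_{t.id}_fs", [rep_edit, fs])
            constructs.append(c)

    seen_stops: set[int] = set()
    for t in g.transcripts:
        p = _before_stop_position(t)
        if p is None or t.cds_end in seen_stops:
            continue
        seen_stops.add(t.cds_end)
        constructs.append(
            build(
                f"terminal_{t.id}",
                [Edit(EditKind.REPORTER_INSERTION, g.chrom, p, payload)],
            )
        )

    if multi:
        seen_elements: set[tuple[int, int]] = set()
        for call in detect_mechanisms(g):
            if call.mechanism not in (
                Mechanism.CASSETTE_EXON,
                Mechanism.RETAINED_INTRON,
            ):
                continue
            lo, hi = call.detail["start"], call.detail["end"]
            if (lo, hi) in seen_elements:
                continue
            seen_elements.add((lo, hi))
            # tag the end of the transcript that excludes the element, and
            # frameshift every transcript that includes it
            spare = (
                call.detail["skipped_by"]
                if call.mechanism == Mechanism.CASSETTE_EXON
                else call.transcripts[0]
            )
            p_stop = _before_stop_position(g.transcript(spare))
            if p_stop is None:
                continue
            constructs.append(
                build(
                    f"disrupt_{call.mechanism.value.lower()}_{lo}",
                    [
                        Edit(EditKind.REPORTER_INSERTION, g.chrom, p_stop, payload),
                        Edit(EditKind.NT_INSERTION, g.chrom, (lo + hi) // 2, "C"),
                    ],
                )
            )

    # transcripts with identical indicator rows across the whole panel are
    # inseparable by insertion constructs alone
    rows: dict[tuple[bool, ...], set[str]] = {}
    for t in g.transcripts:
        row = tuple(c.vector[t.id] for c in constructs)
        rows.setdefault(row, set()).add(t.id)
    inseparable = [frozenset(v) for v in rows.values() if len(v) > 1]
    return DesignResult(constructs, sorted(inseparable, key=sorted))


def homology_arms(
    genome: Genome,
    chrom: str,
    position: int,
    arm_length: int = 50,
    strand: str = "+",
) -> tuple[str, str]:
    """The two ``arm_length``-base sequences flanking an insertion point,
    returned 5'->3' in the given orientation (upstream arm first)."""
    seq = genome[chrom]
    if position < arm_length or position + arm_length > len(seq):
        raise OutOfBoundsError(
            f"position {position} within {arm_length} bases of a sequence end"
        )
    left = seq[position - arm_length : position]
    right = seq[position : position + arm_length]
    if strand == "+":
        return left, right
    return reverse_complement(right), reverse_complement(left)
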