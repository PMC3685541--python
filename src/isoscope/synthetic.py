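"""Synthetic multi-transcript gene loci with known mechanisms, plus EST
evidence with realistic artifact modes, so every analysis stage is testable
without any external download.

Each generated locus realises exactly one planted mechanism (or none).
Introns begin GT and end AG; every productive CDS starts ATG, ends at a
stop, and carries no internal stop in frame; 5'UTRs are kept free of ATGs
so that no accidental upstream ORF confounds the planted truth.  EST
generation emulates the two classic artifact modes seen in single-pass
cDNA data: 5'-truncated reads from incomplete first-strand synthesis, and
intronless reads corresponding to the primary unspliced transcript.
Determinism: the entire locus and its evidence are reproducible from the
spec's seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .errors import GenerationError
from .evidence import SupportRecord, Source, write_support_records
from .genemodel import (
    GeneModel,
    GenomicInterval,
    Transcript,
    spliced_sequence,
    write_fasta,
    write_gff3,
)
from .orf import STOP_CODONS, assess_nmd, translate_from

_BASES = np.array(list("ACGT"))
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS and a + b + c != "ATG"
]

MECHANISMS = (
    "NONE",
    "UNIQUE_START",
    "NESTED_START",
    "ALT_TERMINAL",
    "RETAINED_INTRON",
    "CASSETTE_EXON",
    "SPLICE_SHIFT",
)

_MAX_TRIES = 80


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Parameters of one synthetic locus; the defaults are the study
    conditions the detectors and classifier are validated under: 2-3
    transcripts per gene, compact worm-like exons (60-180 bp) and short
    GT-AG introns (48-90 bp), three independent ESTs per transcript, and no
    artifact reads unless requested."""

    mechanism: str = "NONE"
    name: str = "g0"
    n_transcripts: int = 2
    exon_count: tuple[int, int] = (4, 6)
    exon_length: tuple[int, int] = (60, 180)
    intron_length: tuple[int, int] = (48, 90)
    utr5_length: tuple[int, int] = (18, 48)
    utr3_length: tuple[int, int] = (24, 60)
    cassette_frame_preserving: bool = True
    splice_shift_offsets: tuple[int, ...] = (3, 6, 9, 12)
    expression_weights: tuple[float, ...] | None = None
    ests_per_transcript: int = 3
    n_libraries: int = 12
    p_truncated_5p: float = 0.0
    p_unspliced: float = 0.0
    padding: int = 500
    strand: str | None = None  # None: drawn at random
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not (0.0 <= self.p_truncated_5p <= 1.0 and 0.0 <= self.p_unspliced <= 1.0):
            raise ValueError("artifact rates must be in [0, 1]")
        if self.expression_weights is not None:
            if abs(sum(self.expression_weights) - 1.0) > 1e-9:
                raise ValueError("expression weights must sum to 1")


@dataclass
class GeneTruth:
    gene_id: str
    mechanism: str
    expected_category: str
    transcripts: tuple[str, ...]
    strand: str
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# low-level sequence helpers


def _rand_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _rand_utr(rng, n: int) -> str:
    """Random sequence guaranteed free of ATG (no spurious upstream starts)."""
    s = _rand_seq(rng, n)
    while "ATG" in s:
        s = s.replace("ATG", "ACG", 1)
    return s


def _rand_codons(rng, n: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), n)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _intron_seq(rng, length: int) -> str:
    if length < 6:
        raise GenerationError("intron too short for GT..AG")
    return "GT" + _rand_seq(rng, length - 4) + "AG"


def _rlen(rng, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _has_frame0_stop(seq: str) -> bool:
    return any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


class _Assembler:
    """Accumulates sequence parts left to right, tracking coordinates."""

    def __init__(self) -> None:
        self.parts: list[str] = []
        self.cursor = 0

    def add(self, seq: str) -> tuple[int, int]:
        start = self.cursor
        self.parts.append(seq)
        self.cursor += len(seq)
        return start, self.cursor

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def _mirror_interval(iv: GenomicInterval, L: int) -> GenomicInterval:
    return GenomicInterval(iv.chrom, L - iv.end, L - iv.start, "-")


def _mirror_gene(g: GeneModel, L: int) -> GeneModel:
    new_ts = []
    for t in g.transcripts:
        new_ts.append(
            replace(
                t,
                exons=tuple(_mirror_interval(e, L) for e in t.exons),
                cds_start=None if t.cds_start is None else L - 1 - t.cds_start,
                cds_end=None if t.cds_end is None else L - 1 - t.cds_end,
            )
        )
    return replace(g, transcripts=tuple(new_ts))


# ---------------------------------------------------------------------------
# mechanism-specific locus builders (all build on the plus strand)


def _coding_lengths(rng, spec, n_ex: int) -> list[int]:
    """Coding bases per exon, first and last reserving UTR room; total %3==0."""
    lens = []
    for i in range(n_ex):
        if i == 0:
            c = _rlen(rng, (30, 90))
            c -= c % 3  # keep the first exon's contribution codon-aligned
        elif i == n_ex - 1:
            c = max(21, _rlen(rng, spec.exon_length) - _rlen(rng, spec.utr3_length))
        else:
            c = _rlen(rng, spec.exon_length)
        lens.append(c)
    lens[-1] -= sum(lens) % 3
    return lens


def _build_simple(
    rng,
    spec,
    n_ex: int,
    coding: Sequence[int],
    intron_seqs=None,
    noncoding_exons: frozenset[int] = frozenset(),
):
    """One transcript: pad | exon0(utr5+cds..) | introns | exonN(cds+utr3) | pad.

    Exons listed in ``noncoding_exons`` get random content of the stated
    length instead of a slice of the codon stream (used to plant
    frame-shifting optional exons).  Returns (assembler, exon intervals,
    cds_start, cds_end, intron intervals)."""
    total = sum(c for i, c in enumerate(coding) if i not in noncoding_exons)
    cds = "ATG" + _rand_codons(rng, (total - 6) // 3) + "TAA"
    utr5 = _rand_utr(rng, _rlen(rng, spec.utr5_length))
    utr3 = _rand_seq(rng, _rlen(rng, spec.utr3_length))
    if intron_seqs is None:
        intron_seqs = [
            _intron_seq(rng, _rlen(rng, spec.intron_length)) for _ in range(n_ex - 1)
        ]
    asm = _Assembler()
    asm.add(_rand_utr(rng, spec.padding))
    exons = []
    introns = []
    pos = 0
    cds_start = cds_end = None
    for i in range(n_ex):
        if i in noncoding_exons:
            chunk = _rand_seq(rng, coding[i])
        else:
            chunk = cds[pos : pos + coding[i]]
            pos += coding[i]
        seq = chunk
        if i == 0:
            seq = utr5 + chunk
        if i == n_ex - 1:
            seq = seq + utr3
        s, e = asm.add(seq)
        exons.append((s, e))
        if i == 0:
            cds_start = s + len(utr5)
        if i == n_ex - 1:
            cds_end = e - len(utr3) - 1
        if i < n_ex - 1:
            s2, e2 = asm.add(intron_seqs[i])
            introns.append((s2, e2))
    asm.add(_rand_utr(rng, spec.padding))
    return asm, exons, cds_start, cds_end, introns


def _mk_transcript(tid, chrom, exons, cds_start, cds_end, strand="+"):
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    return Transcript(id=tid, exons=ivs, cds_start=cds_start, cds_end=cds_end)


def _clean_orf(t: Transcript, genome) -> bool:
    """Translation from the annotated start terminates exactly at cds_end."""
    seq = spliced_sequence(t, genome)
    res = translate_from(seq, t.cds_spliced_start)
    return res.stop_offset is not None and res.stop_offset + 2 == t.cds_spliced_end


def _find_stop_end(t: Transcript, genome) -> int | None:
    """Genomic position of the last base of the first in-frame stop."""
    seq = spliced_sequence(t, genome)
    res = translate_from(seq, t.cds_spliced_start)
    if res.stop_offset is None:
        return None
    return t.to_genomic(res.stop_offset + 2)


def _gen_none(rng, spec, chrom):
    n_ex = _rlen(rng, spec.exon_count)
    coding = _coding_lengths(rng, spec, n_ex)
    asm, exons, cs, ce, _ = _build_simple(rng, spec, n_ex, coding)
    t = _mk_transcript(f"{spec.name}.a", chrom, exons, cs, ce)
    return asm.sequence, [t], {}


def _gen_unique_start(rng, spec, chrom):
    n_tx = max(2, spec.n_transcripts)
    n_ex = max(3, _rlen(rng, spec.exon_count))
    coding = _coding_lengths(rng, spec, n_ex)
    shared_total = sum(coding[1:])
    # downstream (shared) coding must be codon-aligned so every alternative
    # first exon can carry a multiple-of-3 coding head
    coding[-1] -= shared_total % 3
    shared_total = sum(coding[1:])
    shared_cds = _rand_codons(rng, shared_total // 3 - 1) + "TAA"

    asm = _Assembler()
    asm.add(_rand_utr(rng, spec.padding))
    first_exons = []  # (exon interval, cds_start), transcript index k
    # unique first exons laid 5'->3'; transcript 0's first exon is the most 3'
    for k in range(n_tx - 1, -1, -1):
        utr5 = _rand_utr(rng, _rlen(rng, spec.utr5_length))
        head_len = _rlen(rng, (24, 60))
        head_len -= head_len % 3
        head = "ATG" + _rand_codons(rng, head_len // 3 - 1)
        s, e = asm.add(utr5 + head)
        first_exons.append((k, (s, e), s + len(utr5)))
        gap = _intron_seq(rng, _rlen(rng, (40, 80)))
        if k == 0:
            # final gap is the shared intron 1 ending AG before exon 2
            asm.add(gap)
        else:
            asm.add(gap[:-2] + _rand_utr(rng, 0))  # keep GT start, no AG needed
            asm.add(_rand_utr(rng, _rlen(rng, (20, 40))))
    shared_exons = []
    pos = 0
    for i in range(1, n_ex):
        chunk = shared_cds[pos : pos + coding[i]]
        pos += coding[i]
        seq = chunk if i < n_ex - 1 else chunk + _rand_seq(rng, _rlen(rng, spec.utr3_length))
        s, e = asm.add(seq)
        shared_exons.append((s, e))
        if i < n_ex - 1:
            asm.add(_intron_seq(rng, _rlen(rng, spec.intron_length)))
    cds_end = shared_exons[-1][0] + coding[-1] - 1  # last base of the shared stop
    asm.add(_rand_utr(rng, spec.padding))

    transcripts = []
    for k, exon, cs in sorted(first_exons):
        tid = f"{spec.name}.{chr(ord('a') + k)}"
        transcripts.append(
            _mk_transcript(tid, chrom, [exon] + shared_exons, cs, cds_end)
        )
    return asm.sequence, transcripts, {"n_starts": n_tx}


def _gen_nested(rng, spec, chrom):
    n_ex = max(4, _rlen(rng, spec.exon_count))
    coding = _coding_lengths(rng, spec, n_ex)
    asm, exons, cs, ce, _ = _build_simple(rng, spec, n_ex, coding)
    seq = asm.sequence
    host = _mk_transcript(f"{spec.name}.a", chrom, exons, cs, ce)
    j = int(rng.integers(1, n_ex - 1))  # host exon for the nested start
    # codon boundary inside exon j (fully coding), away from both edges
    exon_s, exon_e = exons[j]
    cds_off = host.cds_spliced_start
    lo = exon_s + 9
    hi = exon_e - 12
    if hi <= lo:
        raise GenerationError("host exon too short for a nested start")
    # candidate positions at host codon boundaries
    candidates = [
        p
        for p in range(lo, hi)
        if (host.to_spliced(p) - cds_off) % 3 == 0
    ]
    atg_pos = int(candidates[rng.integers(0, len(candidates))])
    seq = seq[:atg_pos] + "ATG" + seq[atg_pos + 3 :]
    nested_exons = [(atg_pos, exon_e)] + exons[j + 1 :]
    nested = _mk_transcript(f"{spec.name}.b", chrom, nested_exons, atg_pos, ce)
    return seq, [host, nested], {"host_exon_index": j + 1}


def _gen_alt_terminal(rng, spec, chrom):
    n_ex = max(4, _rlen(rng, spec.exon_count))
    coding = _coding_lengths(rng, spec, n_ex)
    j = int(rng.integers(1, n_ex - 2))  # internal exon that gets extended
    phase = sum(coding[: j + 1]) % 3
    stop_off = next(o for o in itertools.count(4) if (phase + o) % 3 == 0)
    ext_len = stop_off + 3 + 9  # stop plus a short 3'UTR inside the intron
    intron_seqs = []
    for i in range(n_ex - 1):
        L = _rlen(rng, spec.intron_length)
        if i == j:
            L = max(L, ext_len + 25)
            s = (
                "GT"
                + _rand_seq(rng, stop_off - 2)
                + "TAA"
                + _rand_seq(rng, L - stop_off - 3 - 2)
                + "AG"
            )
            intron_seqs.append(s)
        else:
            intron_seqs.append(_intron_seq(rng, L))
    asm, exons, cs, ce, introns = _build_simple(
        rng, spec, n_ex, coding, intron_seqs=intron_seqs
    )
    seq = asm.sequence
    full = _mk_transcript(f"{spec.name}.a", chrom, exons, cs, ce)
    short_exons = exons[:j] + [(exons[j][0], exons[j][1] + ext_len)]
    short = _mk_transcript(f"{spec.name}.b", chrom, short_exons, cs, None)
    genome = {chrom: seq}
    stop_end = _find_stop_end(replace(short, cds_end=None), genome)
    if stop_end is None or not (exons[j][1] <= stop_end < exons[j][1] + ext_len):
        raise GenerationError("no stop inside the terminal extension")
    short = replace(short, cds_end=stop_end)
    return seq, [full, short], {"extended_exon_index": j + 1}


def _gen_retained_intron(rng, spec, chrom):
    n_ex = max(3, _rlen(rng, spec.exon_count))
    coding = _coding_lengths(rng, spec, n_ex)
    i0 = int(rng.integers(0, n_ex - 1))  # retained intron index (0-based)
    for _ in range(_MAX_TRIES):
        L = _rlen(rng, spec.intron_length)
        L -= L % 3  # frame-preserving retention
        intron_seqs = [
            _intron_seq(rng, L if i == i0 else _rlen(rng, spec.intron_length))
            for i in range(n_ex - 1)
        ]
        asm, exons, cs, ce, _ = _build_simple(
            rng, spec, n_ex, coding, intron_seqs=intron_seqs
        )
        seq = asm.sequence
        splicer = _mk_transcript(f"{spec.name}.a", chrom, exons, cs, ce)
        merged = exons[:i0] + [(exons[i0][0], exons[i0 + 1][1])] + exons[i0 + 2 :]
        retainer = _mk_transcript(f"{spec.name}.b", chrom, merged, cs, ce)
        if _clean_orf(retainer, {chrom: seq}):
            return seq, [splicer, retainer], {"intron_index": i0 + 1}
    raise GenerationError("no stop-free retained intron after bounded retries")


def _gen_cassette(rng, spec, chrom):
    n_ex = max(4, _rlen(rng, spec.exon_count))
    j = int(rng.integers(1, n_ex - 2))  # cassette exon index (0-based)
    for _ in range(_MAX_TRIES):
        coding = _coding_lengths(rng, spec, n_ex)
        if spec.cassette_frame_preserving:
            coding[j] -= coding[j] % 3
            # codon-align the cassette so skipping removes whole codons
            # (the first exon's coding head is already a multiple of 3)
            shift = sum(coding[:j]) % 3
            coding[j - 1] -= shift
            coding[-1] -= sum(coding) % 3
            asm, exons, cs, ce, _ = _build_simple(rng, spec, n_ex, coding)
            seq = asm.sequence
            genome = {chrom: seq}
            includer = _mk_transcript(f"{spec.name}.a", chrom, exons, cs, ce)
            skip_exons = exons[:j] + exons[j + 1 :]
            skipper = _mk_transcript(f"{spec.name}.b", chrom, skip_exons, cs, ce)
            if _clean_orf(includer, genome) and _clean_orf(skipper, genome):
                return seq, [includer, skipper], {"exon_index": j + 1}
        else:
            # frame-shifting optional exon: the skipping transcript carries
            # the clean codon stream, the including transcript reads through
            # random exon content of length !== 0 (mod 3) and hits an early
            # stop that marks it for NMD
            if coding[j] % 3 == 0:
                coding[j] += 1
            total_others = sum(c for i, c in enumerate(coding) if i != j)
            coding[-1] -= total_others % 3
            asm, exons, cs, ce, _ = _build_simple(
                rng, spec, n_ex, coding, noncoding_exons=frozenset({j})
            )
            seq = asm.sequence
            genome = {chrom: seq}
            skip_exons = exons[:j] + exons[j + 1 :]
            skipper = _mk_transcript(f"{spec.name}.b", chrom, skip_exons, cs, ce)
            if not _clean_orf(skipper, genome):
                continue
            includer = _mk_transcript(f"{spec.name}.a", chrom, exons, cs, None)
            inc_stop = _find_stop_end(includer, genome)
            if inc_stop is None:
                continue
            includer = replace(includer, cds_end=inc_stop)
            if not assess_nmd(includer, genome).is_ptc:
                continue
            inc_len = includer.cds_spliced_end - includer.cds_spliced_start
            skp_len = skipper.cds_spliced_end - skipper.cds_spliced_start
            if inc_len >= skp_len:
                continue  # keep the clean form the longer (reference) CDS
            return seq, [includer, skipper], {"exon_index": j + 1}
    raise GenerationError("cassette-exon locus failed after bounded retries")


def _gen_splice_shift(rng, spec, chrom):
    n_ex = max(3, _rlen(rng, spec.exon_count))
    offsets = spec.splice_shift_offsets
    d = int(offsets[rng.integers(0, len(offsets))])
    frame_ok = d % 3 == 0
    if not frame_ok:
        n_ex = max(4, n_ex)
    i0 = int(rng.integers(0, max(1, n_ex - 2)))  # shifted junction (0-based)
    for _ in range(_MAX_TRIES):
        coding = _coding_lengths(rng, spec, n_ex)
        L = max(_rlen(rng, spec.intron_length), d + 30)
        # alternative acceptor d bases upstream: ...AG | d coding bases | AG
        mid = _rand_seq(rng, L - d - 6)
        ext = _rand_seq(rng, d - 2) + "AG"  # ends with the primary acceptor AG
        intron = "GT" + mid + "AG" + ext
        intron_seqs = [
            intron if i == i0 else _intron_seq(rng, _rlen(rng, spec.intron_length))
            for i in range(n_ex - 1)
        ]
        asm, exons, cs, ce, _ = _build_simple(
            rng, spec, n_ex, coding, intron_seqs=intron_seqs
        )
        seq = asm.sequence
        genome = {chrom: seq}
        primary = _mk_transcript(f"{spec.name}.a", chrom, exons, cs, ce)
        alt_exons = list(exons)
        s, e = alt_exons[i0 + 1]
        alt_exons[i0 + 1] = (s - d, e)
        alt = _mk_transcript(f"{spec.name}.b", chrom, alt_exons, cs, None)
        if frame_ok:
            alt = replace(alt, cds_end=ce)
            if _clean_orf(primary, genome) and _clean_orf(alt, genome):
                return seq, [primary, alt], {
                    "offset": d,
                    "side": "acceptor",
                    "junction_index": i0 + 1,
                }
        else:
            stop_end = _find_stop_end(alt, genome)
            if stop_end is None:
                continue
            alt = replace(alt, cds_end=stop_end)
            if not assess_nmd(alt, genome).is_ptc:
                continue
            alt_len = alt.cds_spliced_end - alt.cds_spliced_start
            prim_len = primary.cds_spliced_end - primary.cds_spliced_start
            if alt_len >= prim_len:
                continue
            return seq, [primary, alt], {
                "offset": d,
                "side": "acceptor",
                "junction_index": i0 + 1,
            }
    raise GenerationError("splice-shift locus failed after bounded retries")


_BUILDERS = {
    "NONE": _gen_none,
    "UNIQUE_START": _gen_unique_start,
    "NESTED_START": _gen_nested,
    "ALT_TERMINAL": _gen_alt_terminal,
    "RETAINED_INTRON": _gen_retained_intron,
    "CASSETTE_EXON": _gen_cassette,
    "SPLICE_SHIFT": _gen_splice_shift,
}


def _expected_category(spec: SyntheticGeneSpec, detail: dict) -> str:
    artifact_free = spec.p_truncated_5p == 0.0 and spec.p_unspliced == 0.0
    strong = artifact_free and spec.ests_per_transcript >= 2
    suffix = "STRONG" if strong else "WEAK"
    m = spec.mechanism
    if m == "NONE":
        return "NO_ALTERNATIVE"
    if m == "NESTED_START":
        return "NESTED_START"
    if m == "CASSETTE_EXON":
        if not spec.cassette_frame_preserving:
            return "DISCOUNTED"
        return f"CASSETTE_{suffix}"
    if m == "SPLICE_SHIFT":
        if detail.get("offset", 3) % 3 != 0:
            return "DISCOUNTED"
        return f"SPLICE_SHIFT_{suffix}"
    return f"{m}_{suffix}"


def generate_gene(
    spec: SyntheticGeneSpec,
) -> tuple[GeneModel, dict[str, str], GeneTruth]:
    """Build one locus realising the planted mechanism.

    Returns the gene model, its genome segment ({chrom: sequence}) and a
    truth record naming the mechanism, optional element indices and the
    category an artifact-free classification should recover.
    """
    rng = np.random.default_rng([spec.seed, 0])
    chrom = f"chr_{spec.name}"
    last_err: Exception | None = None
    for _ in range(8):
        try:
            seq, transcripts, detail = _BUILDERS[spec.mechanism](rng, spec, chrom)
            break
        except GenerationError as err:  # re-draw the whole locus
            last_err = err
    else:
        raise GenerationError(f"{spec.name}: {last_err}")
    strand = spec.strand
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    gene = GeneModel(id=spec.name, transcripts=tuple(transcripts))
    if strand == "-":
        seq = reverse_complement(seq)
        gene = _mirror_gene(gene, len(seq))
    genome = {chrom: seq}
    for t in gene.transcripts:  # generated loci must carry clean ORFs
        if t.cds_start is not None and spliced_sequence(t, genome)[
            t.cds_spliced_start : t.cds_spliced_start + 3
        ] != "ATG":
            raise GenerationError(f"{spec.name}: corrupted initiation codon")
    truth = GeneTruth(
        gene_id=spec.name,
        mechanism=spec.mechanism,
        expected_category=_expected_category(spec, detail),
        transcripts=tuple(t.id for t in gene.transcripts),
        strand=strand,
        detail=detail,
    )
    return gene, genome, truth


# ---------------------------------------------------------------------------
# EST generation


def _truncate_blocks(t: Transcript, cut: int) -> list[GenomicInterval]:
    """Blocks of a record missing the first ``cut`` spliced bases."""
    out = []
    remaining = cut
    for e in t.exons:
        if remaining >= len(e):
            remaining -= len(e)
            continue
        if remaining > 0:
            if t.strand == "+":
                e = GenomicInterval(e.chrom, e.start + remaining, e.end, e.strand)
            else:
                e = GenomicInterval(e.chrom, e.start, e.end - remaining, e.strand)
            remaining = 0
        out.append(e)
    return out


def generate_ests(
    gene: GeneModel,
    truth: GeneTruth,
    n: int,
    spec: SyntheticGeneSpec,
) -> list[SupportRecord]:
    """Draw ``n`` EST records from the locus.

    Without expression weights, transcripts are cycled so each receives an
    equal share (the designed evidence level); with weights, transcripts are
    sampled.  With probability ``p_unspliced`` a record is an intronless
    genomic-span read; with ``p_truncated_5p`` its 5' end is cut at a uniform
    spliced position.  Library keys are assigned round-robin."""
    rng = np.random.default_rng([spec.seed, 1])
    records: list[SupportRecord] = []
    txs = gene.transcripts
    for i in range(n):
        if spec.expression_weights is None:
            t = txs[i % len(txs)]
        else:
            t = txs[rng.choice(len(txs), p=np.asarray(spec.expression_weights))]
        lib = f"lib{i % spec.n_libraries}"
        u = rng.random()
        rid = f"{gene.id}_est{i}"
        if u < spec.p_unspliced:
            records.append(
                SupportRecord(
                    id=rid,
                    source=Source.EST,
                    blocks=(t.span,),
                    five_prime_complete=False,
                    library=lib,
                )
            )
        elif u < spec.p_unspliced + spec.p_truncated_5p:
            cut = int(rng.integers(1, max(2, t.spliced_length - 20)))
            records.append(
                SupportRecord(
                    id=rid,
                    source=Source.EST,
                    blocks=tuple(_truncate_blocks(t, cut)),
                    five_prime_complete=False,
                    library=lib,
                )
            )
        else:
            records.append(
                SupportRecord(
                    id=rid,
                    source=Source.EST,
                    blocks=t.exons,
                    five_prime_complete=True,
                    library=lib,
                )
            )
    return records


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    genes: list[GeneModel]
    genome: dict[str, str]
    records: list[SupportRecord]
    truth: list[GeneTruth]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": t.gene_id,
                    "mechanism": t.mechanism,
                    "expected_category": t.expected_category,
                    "strand": t.strand,
                    "n_transcripts": len(t.transcripts),
                }
                for t in self.truth
            ]
        )


def generate_cohort(
    n_genes: int,
    mixture: Mapping[str, float],
    seed: int,
    base_spec: SyntheticGeneSpec = SyntheticGeneSpec(),
    out_dir: str | Path | None = None,
) -> Cohort:
    """Generate a cohort of loci with mechanisms drawn from ``mixture``.

    Fully reproducible from ``seed``; when ``out_dir`` is given, writes
    genome.fa, annotation.gff3, evidence.tsv and truth.tsv there.
    """
    mechs = list(mixture)
    probs = np.asarray([mixture[m] for m in mechs], dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture proportions must sum to 1")
    rng = np.random.default_rng([seed, 2])
    genes, truths, records = [], [], []
    genome: dict[str, str] = {}
    for i in range(n_genes):
        mech = mechs[int(rng.choice(len(mechs), p=probs))]
        child = int(rng.integers(0, 2**31 - 1))
        spec = replace(base_spec, mechanism=mech, seed=child, name=f"g{i:04d}")
        gene, seg, truth = generate_gene(spec)
        n = spec.ests_per_transcript * len(gene.transcripts)
        recs = generate_ests(gene, truth, n, spec)
        genes.append(gene)
        truths.append(truth)
        records.extend(recs)
        genome.update(seg)
    cohort = Cohort(genes, genome, records, truths)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fa")
        (out / "annotation.gff3").write_text(write_gff3(genes))
        write_support_records(records, out / "evidence.tsv")
        cohort.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    return cohort
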