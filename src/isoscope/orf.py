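"""Translation-based checks: premature stops and NMD candidacy, upstream
ATGs in 5'UTRs, and reading-frame comparison between transcripts.

The nonsense-mediated decay (NMD) rule used is the standard metazoan
convention: a termination codon more than ``rule_distance`` (default 50)
bases upstream of the final exon-exon junction, in spliced coordinates,
marks the transcript as a premature-termination (PTC) candidate.  Only the
standard nuclear genetic code is considered.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import NotComparableError
from .genemodel import Genome, Transcript, spliced_sequence

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class TranslationResult:
    protein_length: int  # amino acids, excluding the stop
    stop_offset: int | None  # offset of the stop codon's first base, or None
    runs_off_end: bool


@dataclass(frozen=True)
class NmdAssessment:
    is_ptc: bool
    # bases from the end of the stop codon to the last junction (spliced
    # coordinates); positive when the stop is upstream of the junction.
    # None when the transcript has no junction or no stop is reached.
    distance_to_last_junction: int | None


@dataclass(frozen=True)
class UpstreamOrf:
    offset: int  # spliced offset of the upstream ATG
    in_frame_with_main: bool
    blocks_main: bool


def translate_from(seq: str, start_offset: int) -> TranslationResult:
    """Scan codons from an ATG at ``start_offset`` to the first stop.

    ``runs_off_end`` is set when the sequence ends (or leaves a partial
    codon) before any stop codon is reached.
    """
    seq = seq.upper()
    if seq[start_offset : start_offset + 3] != "ATG":
        raise ValueError(f"no ATG at offset {start_offset}")
    n_codons = (len(seq) - start_offset) // 3
    frame = seq[start_offset : start_offset + 3 * n_codons]
    protein = str(Seq(frame).translate())
    cut = protein.find("*")
    if cut == -1:
        return TranslationResult(n_codons, None, True)
    return TranslationResult(cut, start_offset + 3 * cut, False)


def assess_nmd(
    t: Transcript, genome: Genome, rule_distance: int = 50
) -> NmdAssessment:
    """PTC/NMD candidacy of a transcript's annotated reading frame.

    Depends only on spliced coordinates, never on intron lengths.  A
    single-exon transcript can never be a PTC candidate.
    """
    if len(t.exons) < 2:
        return NmdAssessment(False, None)
    seq = spliced_sequence(t, genome)
    res = translate_from(seq, t.cds_spliced_start)
    if res.stop_offset is None:
        return NmdAssessment(False, None)
    last_junction = t.spliced_length - len(t.exons[-1])
    distance = last_junction - (res.stop_offset + 3)
    return NmdAssessment(distance >= rule_distance, distance)


def scan_uorfs(t: Transcript, genome: Genome) -> list[UpstreamOrf]:
    """Report every ATG in the spliced 5'UTR.

    An upstream ATG *blocks* the main ORF when it is out of frame with the
    main initiation codon and its reading frame reaches no stop codon before
    the main start — the situation in which ribosome reinitiation at the main
    ATG is implausible.
    """
    seq = spliced_sequence(t, genome)
    main = t.cds_spliced_start
    if main <= 0:
        raise ValueError(f"transcript {t.id}: CDS starts at the transcript 5' end")
    out: list[UpstreamOrf] = []
    for u in range(main - 2):
        if seq[u : u + 3] != "ATG":
            continue
        in_frame = (main - u) % 3 == 0
        stopped = False
        for s in range(u, main, 3):
            if s + 3 <= len(seq) and seq[s : s + 3] in STOP_CODONS:
                stopped = True
                break
        out.append(UpstreamOrf(u, in_frame, not in_frame and not stopped))
    return out


def compare_terminal_frames(t1: Transcript, t2: Transcript) -> int:
    """Reading-frame phase difference over the shared final exon, mod 3.

    Both transcripts must end at the same genomic 3' boundary; the phase of
    each frame is evaluated at the final base they share and the difference
    (t1 relative to t2) returned in {0, 1, 2}.  0 means alternative splicing
    upstream preserved the terminal reading frame.
    """
    e1, e2 = t1.last_exon, t2.last_exon
    if t1.strand != t2.strand or t1.chrom != t2.chrom:
        raise NotComparableError("transcripts on different strands/sequences")
    if t1.strand == "+":
        if e1.end != e2.end:
            raise NotComparableError("final exons do not share a 3' boundary")
        pos = e1.end - 1
    else:
        if e1.start != e2.start:
            raise NotComparableError("final exons do not share a 3' boundary")
        pos = e1.start
    phases = []
    for t in (t1, t2):
        off = t.to_spliced(pos)
        cds = t.cds_spliced_start
        if off < cds:
            raise NotComparableError(
                f"transcript {t.id}: shared terminal base precedes the CDS"
            )
        phases.append((off - cds) % 3)
    return (phases[0] - phases[1]) % 3
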