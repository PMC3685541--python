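"""Shared fixtures: hand-built gene topologies mirroring the classic
alternative-transcript layouts, a deterministic random genome, and a
perturbation-based generator of random toy gene pairs for oracle checks."""

from __future__ import annotations

import numpy as np
import pytest

from isoscope.genemodel import GeneModel, GenomicInterval, Transcript

CHROM = "chrI"


def iv(start: int, end: int, strand: str = "+") -> GenomicInterval:
    return GenomicInterval(CHROM, start, end, strand)


def tx(tid: str, pairs, strand: str = "+", cds_start=None, cds_end=None) -> Transcript:
    exons = [iv(s, e, strand) for s, e in pairs]
    if strand == "-":
        exons = sorted(exons, key=lambda e: e.start, reverse=True)
    return Transcript(id=tid, exons=tuple(exons), cds_start=cds_start, cds_end=cds_end)


@pytest.fixture(scope="session")
def toy_genome():
    rng = np.random.default_rng(0)
    bases = np.array(list("ACGT"))
    return {CHROM: "".join(bases[rng.integers(0, 4, 3000)])}


@pytest.fixture
def crh2_like():
    """Three transcripts with disjoint unique first exons and a shared tail."""
    shared = [(1200, 1350), (1500, 1650)]
    return GeneModel(
        id="crh2_like",
        transcripts=(
            tx("a", [(1000, 1090)] + shared),
            tx("b", [(700, 790)] + shared),
            tx("c", [(400, 490)] + shared),
        ),
    )


@pytest.fixture
def fkh9_like():
    """All alternative transcripts nested within the longest one."""
    return GeneModel(
        id="fkh9_like",
        transcripts=(
            tx("a", [(300, 400), (500, 650), (700, 900)]),
            tx("b", [(560, 650), (700, 900)]),
            tx("c", [(760, 900)]),
        ),
    )


@pytest.fixture
def nhr104_like():
    """Foreshortened transcript whose final exon extends an internal exon
    into the intron."""
    return GeneModel(
        id="nhr104_like",
        transcripts=(
            tx("a", [(100, 200), (300, 400), (500, 600), (700, 800)]),
            tx("b", [(100, 200), (300, 430)]),
        ),
    )


@pytest.fixture
def pqn21_like():
    """Identical transcripts except one retains intron 2."""
    return GeneModel(
        id="pqn21_like",
        transcripts=(
            tx("a", [(100, 200), (300, 400), (500, 600)]),
            tx("b", [(100, 200), (300, 600)]),
        ),
    )


@pytest.fixture
def nhr117_like():
    """Optional internal exon with shared flanking junctions."""
    return GeneModel(
        id="nhr117_like",
        transcripts=(
            tx("a", [(100, 200), (300, 360), (500, 600)]),
            tx("b", [(100, 200), (500, 600)]),
        ),
    )


@pytest.fixture
def shift_like():
    """Acceptor shift of 3 bases at the single junction."""
    return GeneModel(
        id="shift_like",
        transcripts=(
            tx("a", [(100, 200), (300, 400)]),
            tx("b", [(100, 200), (297, 400)]),
        ),
    )


# ---------------------------------------------------------------------------
# random toy structures for detector-vs-oracle equivalence


def _random_chain(rng) -> list[tuple[int, int]]:
    n = int(rng.integers(1, 6))
    pos = int(rng.integers(30, 120))
    exons = []
    for _ in range(n):
        length = int(rng.integers(20, 80))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(30, 60))
    return exons


def _perturb(exons: list[tuple[int, int]], rng) -> list[tuple[int, int]]:
    exons = list(exons)
    op = rng.integers(0, 8)
    n = len(exons)
    if op == 0:
        return exons  # identical
    if op == 1 and n >= 3:  # drop an internal exon (cassette)
        del exons[int(rng.integers(1, n - 1))]
        return exons
    if op == 2 and n >= 2:  # merge adjacent exons (retained intron)
        i = int(rng.integers(0, n - 1))
        exons[i] = (exons[i][0], exons[i + 1][1])
        del exons[i + 1]
        return exons
    if op == 3 and n >= 2:  # shift a donor or acceptor
        i = int(rng.integers(0, n - 1))
        d = int(rng.integers(1, 13)) * (1 if rng.random() < 0.5 else -1)
        if rng.random() < 0.5:
            s, e = exons[i]
            if e + d - s > 5 and exons[i + 1][0] - (e + d) > 2:
                exons[i] = (s, e + d)
        else:
            s, e = exons[i + 1]
            if e - (s + d) > 5 and (s + d) - exons[i][1] > 2:
                exons[i + 1] = (s + d, e)
        return exons
    if op == 4 and n >= 2:  # 5'-truncation into an exon (nested-like)
        k = int(rng.integers(1, n))
        exons = exons[k:]
        s, e = exons[0]
        cut = int(rng.integers(0, max(1, e - s - 5)))
        exons[0] = (s + cut, e)
        return exons
    if op == 5:  # new unique first exon upstream
        s = exons[0][0]
        length = int(rng.integers(15, 40))
        gap = int(rng.integers(10, 40))
        new_start = s - gap - length
        if new_start > 2:
            exons.insert(0, (new_start, new_start + length))
        return exons
    if op == 6 and n >= 3:  # early termination extending an internal exon
        i = int(rng.integers(0, n - 2))
        gap = exons[i + 1][0] - exons[i][1]
        ext = int(rng.integers(1, max(2, gap - 1)))
        kept = exons[: i + 1]
        kept[i] = (kept[i][0], kept[i][1] + ext)
        return kept
    return _random_chain(rng)  # independent structure


def make_random_gene_pair(rng) -> GeneModel:
    strand = "+" if rng.random() < 0.5 else "-"
    e1 = _random_chain(rng)
    e2 = _perturb(e1, rng)
    return GeneModel(
        id="toy",
        transcripts=(tx("t1", e1, strand), tx("t2", e2, strand)),
    )


def mirror_gene(g: GeneModel, length: int) -> GeneModel:
    """Strand-flip a whole locus: coordinates mirrored, strand swapped."""
    flip = {"+": "-", "-": "+"}

    def m(e: GenomicInterval) -> GenomicInterval:
        return GenomicInterval(e.chrom, length - e.end, length - e.start, flip[e.strand])

    ts = []
    for t in g.transcripts:
        exons = tuple(m(e) for e in t.exons)
        ts.append(
            Transcript(
                id=t.id,
                exons=exons,
                cds_start=None if t.cds_start is None else length - 1 - t.cds_start,
                cds_end=None if t.cds_end is None else length - 1 - t.cds_end,
            )
        )
    return GeneModel(id=g.id, transcripts=tuple(ts))
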