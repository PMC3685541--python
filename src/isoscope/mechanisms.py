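"""Detect mechanisms of alternative-transcript generation from transcript
structures alone, by pairwise exon-chain comparison.

Six mechanism classes are recognised:

* ``UNIQUE_START`` — a transcript starts with a first exon overlapping no
  exon of any other transcript (a distinct promoter).
* ``NESTED_START`` — a shorter transcript's 5' end lies within an exon of a
  longer transcript and its junction chain is a suffix of the longer one's.
* ``ALT_TERMINAL`` — a transcript ends early, either by extending an
  internal exon of another transcript into that transcript's intron, or with
  a unique terminal exon 3' of the shared chain.
* ``RETAINED_INTRON`` — an intron of one transcript is fully exonic in the
  other, which is otherwise junction-identical over the shared region.
* ``CASSETTE_EXON`` — an internal exon of one transcript falls wholly within
  one intron of the other while the flanking junctions are shared.
* ``SPLICE_SHIFT`` — two transcripts use donor (or acceptor) sites a few
  bases apart at one junction while the partner site matches.

All detectors reduce multi-transcript genes to ordered pairs and then
deduplicate; they are symmetric in transcript order and invariant under a
strand flip of the whole locus.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

from .genemodel import (
    GeneModel,
    GenomicInterval,
    Transcript,
    acceptor_site,
    donor_site,
    introns_of,
)


class Mechanism(str, enum.Enum):
    UNIQUE_START = "UNIQUE_START"
    NESTED_START = "NESTED_START"
    ALT_TERMINAL = "ALT_TERMINAL"
    CASSETTE_EXON = "CASSETTE_EXON"
    RETAINED_INTRON = "RETAINED_INTRON"
    SPLICE_SHIFT = "SPLICE_SHIFT"


@dataclass
class MechanismCall:
    mechanism: Mechanism
    transcripts: tuple[str, ...]
    detail: dict[str, Any] = field(default_factory=dict)

    def key(self) -> tuple:
        """Deduplication key: mechanism, unordered transcripts, core detail."""
        detail = tuple(
            sorted((k, v) for k, v in self.detail.items() if not isinstance(v, bool))
        )
        return (self.mechanism, frozenset(self.transcripts), detail)


def _dedup(calls: list[MechanismCall]) -> list[MechanismCall]:
    seen: set[tuple] = set()
    out = []
    for c in calls:
        k = c.key()
        if k not in seen:
            seen.add(k)
            out.append(c)
    return out


def _is_5prime_of(a: int, b: int, strand: str) -> bool:
    """True when coordinate a is 5' of coordinate b in transcript orientation."""
    return a < b if strand == "+" else a > b


# ---------------------------------------------------------------------------
# nesting (shared between the nested-start and unique-start detectors)


def _nested_in(s: Transcript, t: Transcript) -> dict[str, Any] | None:
    """Detail dict when ``s`` is nested within ``t``, else None."""
    if s.id == t.id or s.tss == t.tss:
        return None
    js, jt = s.junctions, t.junctions
    k = len(js)
    if k > len(jt):
        return None
    if k and js != jt[len(jt) - k :]:
        return None
    # the exon of t in which s must begin: the one preceding the shared
    # junction suffix (t's last exon when s is single-exon)
    host_exon = t.exons[len(jt) - k]
    if not host_exon.contains_point(s.tss):
        return None
    first = s.first_exon
    if t.strand == "+":
        if first.end != host_exon.end:
            return None
    else:
        if first.start != host_exon.start:
            return None
    if s.exons[1:] != t.exons[len(jt) - k + 1 :]:
        return None
    if k == 0:
        # single-exon nested transcript must share the 3' terminus
        last_t = t.last_exon
        if t.strand == "+" and first.end != last_t.end:
            return None
        if t.strand == "-" and first.start != last_t.start:
            return None
    acc = (
        host_exon.start if t.strand == "+" else host_exon.end - 1
    )  # 5'-most base of the host exon
    return {
        "host": t.id,
        "host_exon_index": len(jt) - k + 1,
        "acceptor_coincident": s.tss == acc and host_exon != t.first_exon,
    }


def find_nested_starts(g: GeneModel) -> list[MechanismCall]:
    """Transcripts whose 5' terminus lies within an exon of a longer
    transcript and whose junctions are a suffix of the longer one's.

    When a transcript nests in several others, the call is reported against
    the host whose 5' terminus is most 5' (the longest transcript in the
    promoter sense, not by genomic span).
    """
    if len(g.transcripts) < 2:
        return []
    calls = []
    for s in g.transcripts:
        hosts = []
        for t in g.transcripts:
            d = _nested_in(s, t)
            if d is not None:
                hosts.append((t, d))
        if not hosts:
            continue
        key = (lambda td: td[0].tss) if g.strand == "+" else (lambda td: -td[0].tss)
        host, detail = min(hosts, key=key)
        calls.append(MechanismCall(Mechanism.NESTED_START, (s.id, host.id), detail))
    return _dedup(calls)


def find_unique_starts(g: GeneModel, min_overlap: int = 1) -> list[MechanismCall]:
    """Transcripts whose first exon overlaps no exon of any other transcript.

    A transcript hosting a nested transcript is excluded: its first exon is
    trivially unshared, but the gene's alternative starts are then nested
    rather than promoter-specific first exons.
    """
    if len(g.transcripts) < 2:
        return []
    calls = []
    for t in g.transcripts:
        if any(_nested_in(s, t) for s in g.transcripts):
            continue
        first = t.first_exon
        clash = any(
            first.overlap_length(e) >= min_overlap
            for u in g.transcripts
            if u.id != t.id
            for e in u.exons
        )
        if not clash:
            calls.append(
                MechanismCall(
                    Mechanism.UNIQUE_START,
                    (t.id,),
                    {"first_exon_start": first.start, "first_exon_end": first.end},
                )
            )
    return _dedup(calls)


# ---------------------------------------------------------------------------
# alternative terminal exons


def find_alt_terminals(g: GeneModel) -> list[MechanismCall]:
    if len(g.transcripts) < 2:
        return []
    calls = []
    for a in g.transcripts:
        for b in g.transcripts:
            if a.id == b.id:
                continue
            call = _alt_terminal_pair(a, b)
            if call is not None:
                calls.append(call)
    return _dedup(calls)


def _alt_terminal_pair(a: Transcript, b: Transcript) -> MechanismCall | None:
    """ALT_TERMINAL call when ``a`` terminates early relative to ``b``."""
    last = a.last_exon
    if last == b.last_exon:
        return None
    ja, jb = a.junctions, b.junctions
    strand = a.strand
    # case (a): a's final exon extends an internal exon of b into b's intron
    if len(ja) < len(jb) and ja == jb[: len(ja)]:
        e = b.exons[len(ja)]
        intron_b = introns_of(b)[len(ja)]
        same_5p = last.start == e.start if strand == "+" else last.end == e.end
        if same_5p:
            end3 = last.end - 1 if strand == "+" else last.start
            if intron_b.contains_point(end3):
                return MechanismCall(
                    Mechanism.ALT_TERMINAL,
                    (a.id, b.id),
                    {
                        "case": "extension",
                        "extended_exon_index": len(ja) + 1,
                        "nmd_hint": _inside_span(end3, b),
                    },
                )
    # case (b): a's final exon is a unique exon 3' of the shared chain
    m = len(a.exons)
    if m >= 2 and len(b.exons) >= m and a.exons[: m - 1] == b.exons[: m - 1]:
        if not any(last.overlaps(e) for e in b.exons):
            end3 = last.end - 1 if strand == "+" else last.start
            return MechanismCall(
                Mechanism.ALT_TERMINAL,
                (a.id, b.id),
                {"case": "unique_exon", "nmd_hint": _inside_span(end3, b)},
            )
    return None


def _inside_span(pos: int, t: Transcript) -> bool:
    span = t.span
    return span.start < pos < span.end - 1


# ---------------------------------------------------------------------------
# retained introns


def find_retained_introns(g: GeneModel) -> list[MechanismCall]:
    if len(g.transcripts) < 2:
        return []
    calls = []
    for a in g.transcripts:  # a splices the intron
        for b in g.transcripts:  # b retains it
            if a.id == b.id:
                continue
            region_lo = max(a.span.start, b.span.start)
            region_hi = min(a.span.end, b.span.end)
            ia = introns_of(a)
            ib = introns_of(b)

            def in_region(iv: GenomicInterval) -> bool:
                return region_lo <= iv.start and iv.end <= region_hi

            set_b = {(i.start, i.end) for i in ib if in_region(i)}
            for idx, intron in enumerate(ia, 1):
                if not any(e.contains(intron) for e in b.exons):
                    continue
                rest_a = {
                    (i.start, i.end)
                    for i in ia
                    if in_region(i) and (i.start, i.end) != (intron.start, intron.end)
                }
                if rest_a == set_b:
                    calls.append(
                        MechanismCall(
                            Mechanism.RETAINED_INTRON,
                            (a.id, b.id),
                            {
                                "intron_index": idx,
                                "start": intron.start,
                                "end": intron.end,
                                "retained_by": b.id,
                                "frame_preserved": len(intron) % 3 == 0,
                            },
                        )
                    )
    return _dedup(calls)


# ---------------------------------------------------------------------------
# cassette exons


def find_cassette_exons(g: GeneModel) -> list[MechanismCall]:
    if len(g.transcripts) < 2:
        return []
    calls = []
    for a in g.transcripts:  # a includes the exon
        for b in g.transcripts:  # b skips it
            if a.id == b.id:
                continue
            ia, ib = introns_of(a), introns_of(b)
            for j in range(1, len(a.exons) - 1):
                e = a.exons[j]
                for intron in ib:
                    if not intron.contains(e):
                        continue
                    donors_match = donor_site(ia[j - 1]) == donor_site(intron)
                    acceptors_match = acceptor_site(ia[j]) == acceptor_site(intron)
                    if donors_match and acceptors_match:
                        calls.append(
                            MechanismCall(
                                Mechanism.CASSETTE_EXON,
                                (a.id, b.id),
                                {
                                    "exon_index": j + 1,
                                    "start": e.start,
                                    "end": e.end,
                                    "skipped_by": b.id,
                                    "frame_preserved": len(e) % 3 == 0,
                                },
                            )
                        )
    return _dedup(calls)


# ---------------------------------------------------------------------------
# splice-site shifts


def find_splice_shifts(g: GeneModel) -> list[MechanismCall]:
    """Junctions where two transcripts pick alternative donor or acceptor
    sites a few bases apart while the partner site matches.

    A guard keeps this from firing on other mechanisms that also produce a
    half-matching junction pair: the exons flanking the junction on *both*
    sides must overlap between the two transcripts.  Splice-site *selection*
    presumes the same flanking exons; a cassette exon, a unique first exon
    or a unique terminal exon leaves one flank with no overlap.
    """
    if len(g.transcripts) < 2:
        return []
    calls = []
    txs = g.transcripts
    for x in range(len(txs)):
        for y in range(x + 1, len(txs)):
            a, b = txs[x], txs[y]
            ia, ib = introns_of(a), introns_of(b)
            for i, intron_a in enumerate(ia):
                for j, intron_b in enumerate(ib):
                    calls.extend(
                        _shift_calls(a, b, i, j, intron_a, intron_b, ia, ib)
                    )
    return _dedup(calls)


def _shift_calls(a, b, i, j, intron_a, intron_b, ia, ib) -> list[MechanismCall]:
    out = []
    da, db = donor_site(intron_a), donor_site(intron_b)
    aa, ab = acceptor_site(intron_a), acceptor_site(intron_b)
    flanks_ok = a.exons[i].overlaps(b.exons[j]) and a.exons[i + 1].overlaps(
        b.exons[j + 1]
    )
    if not flanks_ok:
        return out
    if da == db and aa != ab:
        out.append(
            _shift_call(a, b, "acceptor", abs(aa - ab), min(aa, ab), max(aa, ab))
        )
    if aa == ab and da != db:
        out.append(_shift_call(a, b, "donor", abs(da - db), min(da, db), max(da, db)))
    return out


def _shift_call(a, b, side: str, offset: int, lo: int, hi: int) -> MechanismCall:
    return MechanismCall(
        Mechanism.SPLICE_SHIFT,
        (a.id, b.id),
        {
            "side": side,
            "offset": offset,
            "frame_preserved": offset % 3 == 0,
            "lo": lo,
            "hi": hi,
        },
    )


# ---------------------------------------------------------------------------


def detect_mechanisms(g: GeneModel, min_overlap: int = 1) -> list[MechanismCall]:
    """Run every detector on one gene and pool the calls."""
    calls: list[MechanismCall] = []
    calls += find_unique_starts(g, min_overlap=min_overlap)
    calls += find_nested_starts(g)
    calls += find_alt_terminals(g)
    calls += find_retained_introns(g)
    calls += find_cassette_exons(g)
    calls += find_splice_shifts(g)
    return calls
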