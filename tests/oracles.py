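"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on per-base position sets and naive scans — no shared
interval arithmetic with the package — so agreement is a real check.
"""

from __future__ import annotations

_COMP = str.maketrans("ACGT", "TGCA")


def spliced_seq_oracle(t, genome) -> str:
    """Extract the spliced sequence one base at a time."""
    seq = genome[t.chrom]
    out = []
    for e in t.exons:
        positions = range(e.start, e.end)
        if t.strand == "-":
            positions = reversed(positions)
        for p in positions:
            base = seq[p]
            out.append(base.translate(_COMP) if t.strand == "-" else base)
    return "".join(out)


def codon_walk(seq: str, start: int):
    """(protein_length, stop_offset, runs_off_end) by naive codon stepping."""
    stops = {"TAA", "TAG", "TGA"}
    n = 0
    i = start
    while i + 3 <= len(seq):
        codon = seq[i : i + 3]
        if codon in stops:
            return n, i, False
        n += 1
        i += 3
    return n, None, True


# ---------------------------------------------------------------------------
# structural oracles on base-position sets


def _exon_bases(t) -> set[int]:
    return {p for e in t.exons for p in range(e.start, e.end)}


def _tx_order(t, positions):
    return sorted(positions, reverse=t.strand == "-")


def _junction_pairs(t) -> list[tuple[int, int]]:
    """Intron (start, end) pairs recomputed from sorted exon boundaries."""
    exons = sorted((e.start, e.end) for e in t.exons)
    pairs = [(a[1], b[0]) for a, b in zip(exons, exons[1:])]
    if t.strand == "-":
        pairs = pairs[::-1]
    return pairs


def _tss(t) -> int:
    bases = _exon_bases(t)
    return min(bases) if t.strand == "+" else max(bases)


def nested_oracle(s, t) -> bool:
    """s nested in t: 5' end inside an exon of t (not at t's own 5' end),
    and the remainder of s is base-identical to the 3' part of t."""
    if s.id == t.id:
        return False
    tss = _tss(s)
    if tss == _tss(t) or tss not in _exon_bases(t):
        return False
    # bases of t from tss onward (transcript direction) must equal bases of s
    if s.strand == "+":
        tail_t = {p for p in _exon_bases(t) if p >= tss}
    else:
        tail_t = {p for p in _exon_bases(t) if p <= tss}
    if tail_t != _exon_bases(s):
        return False
    # s's junctions must all be junctions of t (no retained/new junction)
    return set(_junction_pairs(s)) <= set(_junction_pairs(t))


def unique_start_oracle(g, t) -> bool:
    if len(g.transcripts) < 2:
        return False
    if any(nested_oracle(s, t) for s in g.transcripts):
        return False
    first = t.exons[0]
    fb = set(range(first.start, first.end))
    others = {
        p
        for u in g.transcripts
        if u.id != t.id
        for e in u.exons
        for p in range(e.start, e.end)
    }
    return not (fb & others)


def retained_intron_oracle(a, b, intron_index: int) -> bool:
    """Intron #index (1-based, transcript order) of a is exonic in b and the
    two are otherwise junction-identical over the shared region."""
    pairs = _junction_pairs(a)
    if not (1 <= intron_index <= len(pairs)):
        return False
    lo, hi = pairs[intron_index - 1]
    bases_b = _exon_bases(b)
    if not set(range(lo, hi)) <= bases_b:
        return False
    # retained bases must sit inside a single exon of b
    if not any(e.start <= lo and hi <= e.end for e in b.exons):
        return False
    r_lo = max(min(_exon_bases(a)), min(bases_b))
    r_hi = min(max(_exon_bases(a)), max(bases_b))

    def regional(t):
        return {
            (s, e)
            for s, e in _junction_pairs(t)
            if r_lo <= s and e <= r_hi + 1
        }

    return regional(a) - {(lo, hi)} == regional(b)


def cassette_oracle(a, b, exon_index: int) -> bool:
    """Internal exon #index (1-based, transcript order) of a lies wholly in
    one intron of b and the flanking junctions are shared."""
    if exon_index in (1, len(a.exons)):
        return False
    e = a.exons[exon_index - 1]
    bases = set(range(e.start, e.end))
    for lo, hi in _junction_pairs(b):
        if bases <= set(range(lo, hi)):
            ja = _junction_pairs(a)
            before, after = ja[exon_index - 2], ja[exon_index - 1]
            if a.strand == "+":
                donor_match = before[0] == lo
                acceptor_match = after[1] == hi
            else:
                donor_match = before[1] == hi
                acceptor_match = after[0] == lo
            if donor_match and acceptor_match:
                return True
    return False


def splice_shift_oracle(a, b) -> set[tuple[str, int]]:
    """(side, offset) pairs of genuine donor/acceptor shifts between a and b,
    requiring base-overlapping flanking exons on both sides."""
    out = set()
    ja, jb = _junction_pairs(a), _junction_pairs(b)
    ea = [set(range(e.start, e.end)) for e in a.exons]
    eb = [set(range(e.start, e.end)) for e in b.exons]
    for i, (lo_a, hi_a) in enumerate(ja):
        for j, (lo_b, hi_b) in enumerate(jb):
            if not (ea[i] & eb[j] and ea[i + 1] & eb[j + 1]):
                continue
            if a.strand == "+":
                donors = (lo_a, lo_b)
                acceptors = (hi_a, hi_b)
            else:
                donors = (hi_a, hi_b)
                acceptors = (lo_a, lo_b)
            if donors[0] == donors[1] and acceptors[0] != acceptors[1]:
                out.add(("acceptor", abs(acceptors[0] - acceptors[1])))
            if acceptors[0] == acceptors[1] and donors[0] != donors[1]:
                out.add(("donor", abs(donors[0] - donors[1])))
    return out


def alt_terminal_oracle(a, b) -> bool:
    """a ends early relative to b: either its last exon extends an internal
    exon of b into intron, or it is a unique terminal exon after a shared
    chain."""
    last = a.exons[-1]
    if last == b.exons[-1]:
        return False
    ja, jb = _junction_pairs(a), _junction_pairs(b)
    # extension case
    if len(ja) < len(jb) and ja == jb[: len(ja)]:
        e = b.exons[len(ja)]
        same_5p = last.start == e.start if a.strand == "+" else last.end == e.end
        lo, hi = jb[len(ja)]
        end3 = last.end - 1 if a.strand == "+" else last.start
        if same_5p and lo <= end3 < hi:
            return True
    # unique terminal exon case
    m = len(a.exons)
    if m >= 2 and len(b.exons) >= m and a.exons[: m - 1] == b.exons[: m - 1]:
        lb = set(range(last.start, last.end))
        if not (lb & _exon_bases(b)):
            return True
    return False


def reporter_outcome_oracle(t, genome, rep_lo: int, rep_hi: int) -> tuple[bool, str]:
    """Rebuild the edited spliced transcript base-by-base, tag reporter
    bases, and walk codons from the annotated start."""
    seq = genome[t.chrom]
    spliced = []
    positions_in_order = []
    for e in t.exons:
        positions = range(e.start, e.end)
        if t.strand == "-":
            positions = reversed(positions)
        for p in positions:
            base = seq[p]
            spliced.append(base.translate(_COMP) if t.strand == "-" else base)
            positions_in_order.append(p)
    rep_offsets = [
        i for i, p in enumerate(positions_in_order) if rep_lo <= p < rep_hi
    ]
    if len(rep_offsets) != rep_hi - rep_lo:
        # reporter absent (fully or partly) from the mature transcript
        span_lo = min(e.start for e in t.exons)
        span_hi = max(e.end for e in t.exons)
        intronic = set(range(span_lo, span_hi)) - set(positions_in_order)
        if set(range(rep_lo, rep_hi)) <= intronic:
            return False, "SPLICED_OUT"
        return False, "REPORTER_NOT_IN_TRANSCRIPT"
    if t.cds_start is None:
        return False, "REPORTER_NOT_IN_TRANSCRIPT"
    s = "".join(spliced)
    start = positions_in_order.index(t.cds_start)
    rep_start = min(rep_offsets)
    if rep_start < start:
        return False, "REPORTER_NOT_IN_TRANSCRIPT"
    if (rep_start - start) % 3 != 0:
        return False, "FRAMESHIFTED_UPSTREAM"
    _, stop, _ = codon_walk(s, start)
    if stop is not None and stop < rep_start:
        return False, "PREMATURE_STOP"
    return True, "IN_FRAME"
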