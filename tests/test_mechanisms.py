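"""Mechanism detectors: topology examples, oracle equivalence on random toy
pairs, strand-flip invariance, and planted-mechanism recovery."""

import numpy as np
import pytest

from isoscope.genemodel import GeneModel, introns_of
from isoscope.mechanisms import (
    Mechanism,
    detect_mechanisms,
    find_alt_terminals,
    find_cassette_exons,
    find_nested_starts,
    find_retained_introns,
    find_splice_shifts,
    find_unique_starts,
)
from isoscope.synthetic import SyntheticGeneSpec, generate_gene

from conftest import make_random_gene_pair, mirror_gene, tx
import oracles


class TestUniqueStarts:
    def test_three_disjoint_first_exons_give_three_calls(self, crh2_like):
        calls = find_unique_starts(crh2_like)
        assert {c.transcripts[0] for c in calls} == {"a", "b", "c"}

    def test_single_transcript_gene_is_empty(self):
        g = GeneModel(id="g", transcripts=(tx("a", [(0, 100), (200, 300)]),))
        assert find_unique_starts(g) == []

    def test_first_exon_in_intron_of_other_transcript(self):
        # transcript a starts inside intron 1 of b, just 5' of b's exon 2,
        # overlapping no b exon
        g = GeneModel(
            id="klf3_like",
            transcripts=(
                tx("a", [(280, 295), (300, 400)]),
                tx("b", [(100, 200), (300, 400)]),
            ),
        )
        assert "a" in {c.transcripts[0] for c in find_unique_starts(g)}

    def test_nested_host_not_called_unique(self, fkh9_like):
        assert find_unique_starts(fkh9_like) == []

    def test_single_base_overlap_disqualifies(self):
        g = GeneModel(
            id="g",
            transcripts=(
                tx("a", [(100, 201), (300, 400)]),
                tx("b", [(200, 250), (300, 400)]),
            ),
        )
        assert find_unique_starts(g) == []
        assert find_unique_starts(g, min_overlap=5) != []


class TestNestedStarts:
    def test_all_shorter_transcripts_nested_in_longest(self, fkh9_like):
        calls = find_nested_starts(fkh9_like)
        assert {c.transcripts[0] for c in calls} == {"b", "c"}
        assert all(c.detail["host"] == "a" for c in calls)

    def test_identical_transcripts_give_no_calls(self):
        g = GeneModel(
            id="g",
            transcripts=(
                tx("a", [(0, 100), (200, 300)]),
                tx("b", [(0, 100), (200, 300)]),
            ),
        )
        assert find_nested_starts(g) == []

    def test_toy_containment_with_shared_suffix(self):
        g = GeneModel(
            id="g",
            transcripts=(
                tx("t1", [(100, 150), (200, 300), (400, 500)]),
                tx("t2", [(250, 300), (400, 500)]),
            ),
        )
        (call,) = find_nested_starts(g)
        assert call.transcripts == ("t2", "t1")
        assert call.detail["acceptor_coincident"] is False

    def test_start_at_internal_acceptor_flagged(self):
        g = GeneModel(
            id="g",
            transcripts=(
                tx("t1", [(100, 150), (200, 300), (400, 500)]),
                tx("t2", [(200, 300), (400, 500)]),
            ),
        )
        (call,) = find_nested_starts(g)
        assert call.detail["acceptor_coincident"] is True

    def test_unique_and_nested_mutually_exclusive_per_transcript(self, fkh9_like):
        unique = {c.transcripts[0] for c in find_unique_starts(fkh9_like)}
        nested = {c.transcripts[0] for c in find_nested_starts(fkh9_like)}
        assert not unique & nested


class TestAltTerminals:
    def test_extension_into_intron(self, nhr104_like):
        (call,) = find_alt_terminals(nhr104_like)
        assert call.transcripts[0] == "b"
        assert call.detail["case"] == "extension"

    def test_shared_last_exon_gives_no_call(self, crh2_like):
        assert find_alt_terminals(crh2_like) == []

    def test_unique_terminal_exon_case(self):
        g = GeneModel(
            id="g",
            transcripts=(
                tx("a", [(100, 200), (300, 400), (500, 600)]),
                tx("b", [(100, 200), (420, 460)]),
            ),
        )
        (call,) = find_alt_terminals(g)
        assert call.transcripts[0] == "b"
        assert call.detail["case"] == "unique_exon"
        assert call.detail["nmd_hint"] is True


class TestRetainedIntrons:
    def test_retained_intron_two_of_two(self, pqn21_like):
        (call,) = find_retained_introns(pqn21_like)
        assert call.detail["intron_index"] == 2
        assert call.detail["retained_by"] == "b"
        assert call.transcripts == ("a", "b")

    def test_no_introns_anywhere_gives_no_call(self):
        g = GeneModel(
            id="g", transcripts=(tx("a", [(0, 100)]), tx("b", [(0, 150)]))
        )
        assert find_retained_introns(g) == []

    def test_intron_index_matches_transcript_order_on_minus_strand(self, pqn21_like):
        flipped = mirror_gene(pqn21_like, 1000)
        (call,) = find_retained_introns(flipped)
        # transcript-order index 2 of 2 is the genomically-lower intron now
        assert call.detail["intron_index"] == 2


class TestCassetteExons:
    def test_optional_internal_exon(self, nhr117_like):
        (call,) = find_cassette_exons(nhr117_like)
        assert call.transcripts == ("a", "b")
        assert call.detail["exon_index"] == 2
        assert call.detail["frame_preserved"] == (60 % 3 == 0)

    def test_identical_transcripts_no_call(self):
        g = GeneModel(
            id="g",
            transcripts=(
                tx("a", [(0, 100), (200, 300)]),
                tx("b", [(0, 100), (200, 300)]),
            ),
        )
        assert find_cassette_exons(g) == []

    def test_two_cassette_exons_both_found(self):
        g = GeneModel(
            id="g",
            transcripts=(
                tx("a", [(0, 90), (150, 180), (240, 330), (400, 430), (500, 590)]),
                tx("b", [(0, 90), (240, 330), (500, 590)]),
            ),
        )
        calls = find_cassette_exons(g)
        assert {c.detail["exon_index"] for c in calls} == {2, 4}


class TestSpliceShifts:
    def test_acceptor_offset_three_preserves_frame(self, shift_like):
        (call,) = find_splice_shifts(shift_like)
        assert call.detail == {
            "side": "acceptor",
            "offset": 3,
            "frame_preserved": True,
            "lo": 297,
            "hi": 300,
        }

    def test_identical_junctions_no_call(self, crh2_like):
        assert find_splice_shifts(crh2_like) == []

    def test_donor_offset_seven_breaks_frame(self):
        g = GeneModel(
            id="g",
            transcripts=(
                tx("a", [(100, 200), (300, 400)]),
                tx("b", [(100, 207), (300, 400)]),
            ),
        )
        (call,) = find_splice_shifts(g)
        assert call.detail["side"] == "donor"
        assert call.detail["offset"] == 7
        assert call.detail["frame_preserved"] is False

    def test_cassette_exon_does_not_masquerade_as_shift(self, nhr117_like):
        assert find_splice_shifts(nhr117_like) == []


# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def toy_pairs():
    rng = np.random.default_rng(2024)
    return [make_random_gene_pair(rng) for _ in range(400)]


class TestOracleEquivalence:
    """Every detector agrees with its base-set brute-force oracle on random
    toy gene pairs (including strand-flipped ones)."""

    def test_unique_starts_match_oracle(self, toy_pairs):
        for g in toy_pairs:
            got = {c.transcripts[0] for c in find_unique_starts(g)}
            want = {
                t.id for t in g.transcripts if oracles.unique_start_oracle(g, t)
            }
            assert got == want, g

    def test_nested_starts_match_oracle(self, toy_pairs):
        for g in toy_pairs:
            got = {c.transcripts[0] for c in find_nested_starts(g)}
            want = {
                s.id
                for s in g.transcripts
                if any(oracles.nested_oracle(s, t) for t in g.transcripts)
            }
            assert got == want, g

    def test_retained_introns_match_oracle(self, toy_pairs):
        for g in toy_pairs:
            got = {
                (c.transcripts[0], c.detail["start"], c.detail["end"])
                for c in find_retained_introns(g)
            }
            want = set()
            for a in g.transcripts:
                for b in g.transcripts:
                    if a.id == b.id:
                        continue
                    for idx, intron in enumerate(introns_of(a), 1):
                        if oracles.retained_intron_oracle(a, b, idx):
                            want.add((a.id, intron.start, intron.end))
            assert got == want, g

    def test_cassette_exons_match_oracle(self, toy_pairs):
        for g in toy_pairs:
            got = {
                (c.transcripts[0], c.detail["start"], c.detail["end"])
                for c in find_cassette_exons(g)
            }
            want = set()
            for a in g.transcripts:
                for b in g.transcripts:
                    if a.id == b.id:
                        continue
                    for idx in range(2, len(a.exons)):
                        if oracles.cassette_oracle(a, b, idx):
                            e = a.exons[idx - 1]
                            want.add((a.id, e.start, e.end))
            assert got == want, g

    def test_alt_terminals_match_oracle(self, toy_pairs):
        for g in toy_pairs:
            got = {c.transcripts[0] for c in find_alt_terminals(g)}
            want = {
                a.id
                for a in g.transcripts
                for b in g.transcripts
                if a.id != b.id and oracles.alt_terminal_oracle(a, b)
            }
            assert got == want, g

    def test_splice_shifts_match_oracle(self, toy_pairs):
        for g in toy_pairs:
            got = {
                (c.detail["side"], c.detail["offset"])
                for c in find_splice_shifts(g)
            }
            want = set()
            for i, a in enumerate(g.transcripts):
                for b in g.transcripts[i + 1 :]:
                    want |= oracles.splice_shift_oracle(a, b)
            assert got == want, g


class TestInvariances:
    def test_detectors_invariant_under_strand_flip(self):
        rng = np.random.default_rng(7)
        for _ in range(150):
            g = make_random_gene_pair(rng)
            flipped = mirror_gene(g, 5000)

            def summary(gene):
                return sorted(
                    (c.mechanism.value, frozenset(c.transcripts))
                    for c in detect_mechanisms(gene)
                )

            assert summary(g) == summary(flipped)

    @pytest.mark.parametrize(
        "mech",
        [
            "UNIQUE_START",
            "NESTED_START",
            "ALT_TERMINAL",
            "RETAINED_INTRON",
            "CASSETTE_EXON",
            "SPLICE_SHIFT",
        ],
    )
    def test_planted_mechanism_is_the_only_one_called(self, mech):
        for seed in range(40):
            gene, _, truth = generate_gene(
                SyntheticGeneSpec(mechanism=mech, seed=seed, name=f"p{seed}")
            )
            types = {c.mechanism.value for c in detect_mechanisms(gene)}
            assert types == {mech}, (mech, seed, types)
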