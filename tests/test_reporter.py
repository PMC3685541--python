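"""In-silico recombineering: edit application, expression prediction against
a base-by-base oracle, construct design, and homology arms."""

import warnings

import numpy as np
import pytest

from isoscope.errors import EditError, OutOfBoundsError, SpliceDisruptionWarning
from isoscope.genemodel import GenomicInterval
from isoscope.reporter import (
    Edit,
    EditKind,
    Reason,
    apply_edits,
    design_constructs,
    homology_arms,
    predict_reporter,
)
from isoscope.synthetic import MECHANISMS, SyntheticGeneSpec, generate_gene

from oracles import reporter_outcome_oracle

PAYLOAD = "GGCGGCGGCGGCGGCGGC"  # stop-free in every frame and orientation


def make_gene(mech="NONE", seed=0, **kw):
    return generate_gene(SyntheticGeneSpec(mechanism=mech, seed=seed, name="rg", **kw))


class TestApplyEdits:
    def test_empty_edit_set_is_identity(self):
        gene, genome, _ = make_gene()
        res = apply_edits(gene, genome, [])
        assert res.gene == gene and res.genome == genome

    def test_insertion_shifts_downstream_coordinates(self):
        gene, genome, _ = make_gene(strand="+")
        t = gene.transcripts[0]
        p = t.cds_start  # 1 base inserted right before the start codon
        res = apply_edits(gene, genome, [Edit(EditKind.NT_INSERTION, gene.chrom, p, "C")])
        t2 = res.gene.transcripts[0]
        assert t2.cds_start == t.cds_start + 1
        assert t2.cds_end == t.cds_end + 1
        for old, new in zip(t.exons, t2.exons):
            if old.end <= p:
                assert (new.start, new.end) == (old.start, old.end)
            elif old.start >= p:
                assert (new.start, new.end) == (old.start + 1, old.end + 1)
        # sequence outside the edit is unchanged
        assert res.genome[gene.chrom][:p] == genome[gene.chrom][:p]
        assert res.genome[gene.chrom][p] == "C"

    def test_reporter_placements_after_start_and_before_stop_both_valid(self):
        gene, genome, _ = make_gene(strand="+")
        t = gene.transcripts[0]
        for p in (t.cds_start + 3, t.cds_end - 2):
            res = apply_edits(
                gene, genome, [Edit(EditKind.REPORTER_INSERTION, gene.chrom, p, PAYLOAD)]
            )
            (o,) = predict_reporter(res.gene, res.genome, res.reporter_span)
            assert o.expresses and o.reason == Reason.IN_FRAME

    def test_overlapping_edits_rejected(self):
        gene, genome, _ = make_gene()
        p = gene.transcripts[0].cds_start
        with pytest.raises(EditError):
            apply_edits(
                gene,
                genome,
                [
                    Edit(EditKind.NT_INSERTION, gene.chrom, p, "C"),
                    Edit(EditKind.NT_INSERTION, gene.chrom, p, "G"),
                ],
            )

    def test_edit_in_splice_dinucleotide_warns(self):
        gene, genome, _ = make_gene(strand="+")
        t = gene.transcripts[0]
        intron_start = t.exons[0].end
        with pytest.warns(SpliceDisruptionWarning):
            apply_edits(
                gene,
                genome,
                [Edit(EditKind.SUBSTITUTION, gene.chrom, intron_start, "CA")],
            )

    def test_reporter_payload_with_internal_stop_rejected(self):
        gene, genome, _ = make_gene(strand="+")
        with pytest.raises(EditError):
            apply_edits(
                gene,
                genome,
                [
                    Edit(
                        EditKind.REPORTER_INSERTION,
                        gene.chrom,
                        gene.transcripts[0].cds_start + 3,
                        "GGCTAAGGC",
                    )
                ],
            )


class TestFrameArithmetic:
    def insert_and_predict(self, gene, genome, extra_payloads):
        t = gene.transcripts[0]
        rep = Edit(EditKind.REPORTER_INSERTION, gene.chrom, t.cds_end - 2, PAYLOAD)
        p_fs = t.cds_start + 30
        outcomes = {}
        for label, payload in extra_payloads.items():
            edits = [rep]
            if payload:
                edits.append(Edit(EditKind.NT_INSERTION, gene.chrom, p_fs, payload))
            res = apply_edits(gene, genome, edits)
            (o,) = predict_reporter(res.gene, res.genome, res.reporter_span)
            outcomes[label] = o.reason
        return outcomes

    def test_plus_one_breaks_and_plus_three_restores_expression(self):
        gene, genome, _ = make_gene(strand="+")
        out = self.insert_and_predict(
            gene, genome, {"none": "", "+1": "C", "+3": "CCC"}
        )
        assert out["none"] == Reason.IN_FRAME
        assert out["+1"] == Reason.FRAMESHIFTED_UPSTREAM
        assert out["+3"] == Reason.IN_FRAME

    def test_sequential_plus_one_then_plus_two_restores_frame(self):
        gene, genome, _ = make_gene(strand="+")
        t = gene.transcripts[0]
        rep = Edit(EditKind.REPORTER_INSERTION, gene.chrom, t.cds_end - 2, PAYLOAD)
        p = t.cds_start + 30
        step1 = apply_edits(gene, genome, [rep, Edit(EditKind.NT_INSERTION, gene.chrom, p, "C")])
        (o1,) = predict_reporter(step1.gene, step1.genome, step1.reporter_span)
        assert o1.reason == Reason.FRAMESHIFTED_UPSTREAM
        # second recombineering step on the already-edited locus
        step2 = apply_edits(
            step1.gene,
            step1.genome,
            [Edit(EditKind.NT_INSERTION, step1.gene.chrom, p + 2, "CC")],
        )
        rep_span = step1.reporter_span
        rep_span = GenomicInterval(
            rep_span.chrom, rep_span.start + 2, rep_span.end + 2, rep_span.strand
        )
        (o2,) = predict_reporter(step2.gene, step2.genome, rep_span)
        assert o2.reason == Reason.IN_FRAME


class TestPredictReporterAgainstOracle:
    @pytest.mark.parametrize("mech_seed", [(m, s) for m in MECHANISMS for s in range(4)])
    def test_random_gene_edit_pairs_match_codon_walk_oracle(self, mech_seed):
        mech, base_seed = mech_seed
        rng = np.random.default_rng([base_seed, MECHANISMS.index(mech)])
        gene, genome, _ = generate_gene(
            SyntheticGeneSpec(mechanism=mech, seed=base_seed, name="or")
        )
        span = gene.span
        for _ in range(8):
            p_rep = int(rng.integers(span.start, span.end + 1))
            edits = [Edit(EditKind.REPORTER_INSERTION, gene.chrom, p_rep, PAYLOAD)]
            if rng.random() < 0.5:
                p_fs = int(rng.integers(span.start, span.end + 1))
                if abs(p_fs - p_rep) > 1:
                    edits.append(
                        Edit(EditKind.NT_INSERTION, gene.chrom, p_fs, "C")
                    )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", SpliceDisruptionWarning)
                res = apply_edits(gene, genome, edits)
            got = predict_reporter(res.gene, res.genome, res.reporter_span)
            for o in got:
                t = res.gene.transcript(o.transcript_id)
                want_expresses, want_reason = reporter_outcome_oracle(
                    t, res.genome, res.reporter_span.start, res.reporter_span.end
                )
                assert (o.expresses, o.reason.value) == (
                    want_expresses,
                    want_reason,
                ), (mech, base_seed, o.transcript_id, edits)


class TestDesign:
    def test_single_transcript_gene_gets_one_terminal_construct(self):
        gene, genome, _ = make_gene()
        d = design_constructs(gene, genome)
        assert len(d.constructs) == 1
        assert d.constructs[0].name.startswith("terminal")

    def test_three_unique_starts_give_four_separating_constructs(self):
        gene, genome, _ = make_gene(mech="UNIQUE_START", n_transcripts=3, seed=5)
        d = design_constructs(gene, genome)
        assert len(d.constructs) == 4
        starts = [c for c in d.constructs if c.name.startswith("start")]
        assert len(starts) == 3
        # each start fusion tags exactly its own transcript
        for c in starts:
            assert sum(c.vector.values()) == 1
        assert d.inseparable == []

    def test_nested_start_fusion_carries_frameshift_disambiguation(self):
        for strand in "+-":
            gene, genome, _ = make_gene(mech="NESTED_START", seed=3, strand=strand)
            d = design_constructs(gene, genome)
            nested_id = gene.transcripts[1].id
            (c,) = [c for c in d.constructs if c.name == f"start_{nested_id}_fs"]
            assert len(c.edits) == 2
            assert c.vector == {gene.transcripts[0].id: False, nested_id: True}

    @pytest.mark.parametrize("mech", ["CASSETTE_EXON", "RETAINED_INTRON"])
    def test_optional_element_disruption_separates_include_and_skip_forms(
        self, mech
    ):
        for seed in range(5):
            gene, genome, truth = generate_gene(
                SyntheticGeneSpec(mechanism=mech, seed=seed, name="oe")
            )
            d = design_constructs(gene, genome)
            disrupt = [c for c in d.constructs if c.name.startswith("disrupt")]
            assert disrupt, (mech, seed)
            # the insertion silences exactly the element-containing form
            includer = gene.transcripts[0].id if mech == "CASSETTE_EXON" else gene.transcripts[1].id
            other = ({t.id for t in gene.transcripts} - {includer}).pop()
            assert disrupt[0].vector[includer] is False
            assert disrupt[0].vector[other] is True
            assert d.inseparable == []

    def test_small_splice_shift_reported_inseparable(self):
        gene, genome, _ = make_gene(mech="SPLICE_SHIFT", seed=2)
        d = design_constructs(gene, genome)
        assert d.inseparable == [frozenset(t.id for t in gene.transcripts)]

    def test_terminal_fusion_equals_union_of_start_fusions(self):
        """The terminal fusion's expressing set must equal the union over
        start-tagged fusions, on genes without shared-start ambiguity."""
        for mech in ("UNIQUE_START", "NESTED_START", "NONE"):
            for seed in range(6):
                gene, genome, _ = make_gene(mech=mech, seed=seed)
                d = design_constructs(gene, genome)
                terminals = [c for c in d.constructs if c.name.startswith("terminal")]
                starts = [c for c in d.constructs if c.name.startswith("start")]
                if not starts:
                    continue
                union = set()
                for c in starts:
                    union |= {t for t, v in c.vector.items() if v}
                expressed_terminal = {
                    t for c in terminals for t, v in c.vector.items() if v
                }
                assert union == expressed_terminal, (mech, seed)


class TestHomologyArms:
    def test_flanks_at_stated_length(self):
        genome = {"c": "A" * 50 + "C" * 50 + "G" * 50}
        left, right = homology_arms(genome, "c", 100, 50)
        assert left == "C" * 50 and right == "G" * 50

    def test_default_length_is_fifty(self):
        gene, genome, _ = make_gene()
        left, right = homology_arms(genome, gene.chrom, gene.span.start)
        assert len(left) == len(right) == 50

    def test_arms_relocate_the_position_uniquely(self):
        gene, genome, _ = make_gene(seed=9)
        seq = genome[gene.chrom]
        pos = gene.transcripts[0].cds_start + 3
        left, right = homology_arms(genome, gene.chrom, pos)
        probe = left + right
        assert seq.count(probe) == 1
        assert seq.find(probe) + 50 == pos

    def test_minus_strand_arms_are_orientation_correct(self):
        from Bio.Seq import reverse_complement

        gene, genome, _ = make_gene(strand="-")
        pos = gene.span.start + 120
        up, down = homology_arms(genome, gene.chrom, pos, 50, "-")
        seq = genome[gene.chrom]
        assert up == reverse_complement(seq[pos : pos + 50])
        assert down == reverse_complement(seq[pos - 50 : pos])

    def test_too_close_to_contig_end_raises(self):
        with pytest.raises(OutOfBoundsError):
            homology_arms({"c": "ACGT" * 30}, "c", 10, 50)
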