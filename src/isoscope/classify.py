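"""Combine mechanism calls, evidence grades and ORF checks into a per-gene
category, apply discount rules, and summarize cohorts.

Category assignment order (first match wins):

1. ``NO_ALTERNATIVE`` — only one structurally distinct transcript.
2. ``SAME_PROTEIN`` — all transcripts yield an identical spliced CDS.
3. ``DISCOUNTED`` — every alternative transcript is removed by a discount
   rule (blocking upstream ATG, wrong terminal frame on a single record,
   support that is only the unspliced primary transcript, or a
   premature-termination codon marking the alternative for NMD).
4. A single-mechanism category with a strong/weak evidence split (nested
   starts carry no split), or ``MULTIPLE_STRONG``/``MULTIPLE_WEAK`` when
   two or more mechanism *types* survive discounting.  Unique and nested
   starts count as one "alternative starts" type for this purpose: a gene
   is filed under nested starts only when nesting is the sole start
   mechanism.

A mechanism is STRONG only when every alternative transcript it involves
grades STRONG; repeated calls of one type (e.g. five unique starts) stay a
single category.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evidence import (
    EvidenceGrade,
    Grade,
    SupportAssignment,
    SupportRecord,
    assign_support,
    grade_evidence,
)
from .errors import NotComparableError
from .genemodel import GeneModel, Genome, Transcript, introns_of, spliced_cds
from .mechanisms import Mechanism, MechanismCall, detect_mechanisms
from .orf import assess_nmd, compare_terminal_frames, scan_uorfs


class Category(str, enum.Enum):
    NO_ALTERNATIVE = "NO_ALTERNATIVE"
    SAME_PROTEIN = "SAME_PROTEIN"
    UNIQUE_START_STRONG = "UNIQUE_START_STRONG"
    UNIQUE_START_WEAK = "UNIQUE_START_WEAK"
    NESTED_START = "NESTED_START"
    ALT_TERMINAL_STRONG = "ALT_TERMINAL_STRONG"
    ALT_TERMINAL_WEAK = "ALT_TERMINAL_WEAK"
    CASSETTE_STRONG = "CASSETTE_STRONG"
    CASSETTE_WEAK = "CASSETTE_WEAK"
    RETAINED_INTRON_STRONG = "RETAINED_INTRON_STRONG"
    RETAINED_INTRON_WEAK = "RETAINED_INTRON_WEAK"
    SPLICE_SHIFT_STRONG = "SPLICE_SHIFT_STRONG"
    SPLICE_SHIFT_WEAK = "SPLICE_SHIFT_WEAK"
    MULTIPLE_STRONG = "MULTIPLE_STRONG"
    MULTIPLE_WEAK = "MULTIPLE_WEAK"
    DISCOUNTED = "DISCOUNTED"


class DiscountReason(str, enum.Enum):
    BLOCKING_UORF = "BLOCKING_UORF"
    WRONG_FRAME = "WRONG_FRAME"
    UNSPLICED_PRIMARY = "UNSPLICED_PRIMARY"
    NO_PRODUCTIVE_ALTERNATIVE = "NO_PRODUCTIVE_ALTERNATIVE"


_MECH_CATEGORY = {
    Mechanism.UNIQUE_START: ("UNIQUE_START_STRONG", "UNIQUE_START_WEAK"),
    Mechanism.ALT_TERMINAL: ("ALT_TERMINAL_STRONG", "ALT_TERMINAL_WEAK"),
    Mechanism.CASSETTE_EXON: ("CASSETTE_STRONG", "CASSETTE_WEAK"),
    Mechanism.RETAINED_INTRON: ("RETAINED_INTRON_STRONG", "RETAINED_INTRON_WEAK"),
    Mechanism.SPLICE_SHIFT: ("SPLICE_SHIFT_STRONG", "SPLICE_SHIFT_WEAK"),
}


@dataclass(frozen=True)
class ClassifyConfig:
    strong_threshold: int = 2
    junction_tolerance: int = 0
    nmd_distance: int = 50
    min_overlap: int = 1


@dataclass
class ClassificationResult:
    gene_id: str
    category: Category
    mechanisms: tuple[MechanismCall, ...] = ()
    discount_reasons: frozenset[str] = frozenset()
    grades: dict[str, EvidenceGrade] = field(default_factory=dict)
    reference_transcript: str = ""
    warnings: tuple[str, ...] = ()


def encode_same_protein(g: GeneModel, genome: Genome) -> bool:
    """True iff all transcripts yield an identical spliced CDS sequence."""
    if len(g.transcripts) < 2:
        return True
    cds = {spliced_cds(t, genome) for t in g.transcripts if t.cds_start is not None}
    return len(cds) == 1 and all(t.cds_start is not None for t in g.transcripts)


def _distinct_transcripts(g: GeneModel) -> list[Transcript]:
    seen = set()
    out = []
    for t in g.transcripts:
        key = (t.exons, t.cds_start, t.cds_end)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def _reference_transcript(
    transcripts: Sequence[Transcript], grades: Mapping[str, EvidenceGrade]
) -> Transcript:
    """The best-evidenced transcript (ties: longer CDS, then id)."""

    def score(t: Transcript):
        gr = grades.get(t.id)
        cds_len = 0
        if t.cds_start is not None and t.cds_end is not None:
            cds_len = t.cds_spliced_end - t.cds_spliced_start
        return (
            -(gr.n_independent if gr else 0),
            -(gr.n_records if gr else 0),
            -cds_len,
            t.id,  # deterministic tie-break
        )

    return min(transcripts, key=score)


def apply_discount_rules(
    g: GeneModel,
    genome: Genome,
    reference: Transcript,
    alternatives: Sequence[Transcript],
    assignment: SupportAssignment,
    config: ClassifyConfig = ClassifyConfig(),
) -> dict[str, set[DiscountReason]]:
    """Collect discount reasons for each alternative transcript."""
    reasons: dict[str, set[DiscountReason]] = {}
    ref_introns = introns_of(reference)
    for t in alternatives:
        r: set[DiscountReason] = set()
        recs = assignment.by_transcript.get(t.id, [])
        if t.cds_start is not None:
            if t.cds_spliced_start > 0 and any(
                u.blocks_main for u in scan_uorfs(t, genome)
            ):
                r.add(DiscountReason.BLOCKING_UORF)
            try:
                if (
                    compare_terminal_frames(t, reference) != 0
                    and len(recs) <= 1
                ):
                    r.add(DiscountReason.WRONG_FRAME)
            except NotComparableError:
                pass
            if assess_nmd(t, genome, config.nmd_distance).is_ptc:
                r.add(DiscountReason.NO_PRODUCTIVE_ALTERNATIVE)
        if (
            recs
            and all(len(rec.blocks) == 1 for rec in recs)
            and ref_introns
            and any(
                any(e.contains(i) for e in t.exons) for i in ref_introns
            )
        ):
            r.add(DiscountReason.UNSPLICED_PRIMARY)
        reasons[t.id] = r
    return reasons


def classify_gene(
    g: GeneModel,
    records: Iterable[SupportRecord],
    genome: Genome,
    config: ClassifyConfig = ClassifyConfig(),
) -> ClassificationResult:
    distinct = _distinct_transcripts(g)
    if len(distinct) == 1:
        return ClassificationResult(g.id, Category.NO_ALTERNATIVE)
    if encode_same_protein(g, genome):
        return ClassificationResult(g.id, Category.SAME_PROTEIN)

    assignment = assign_support(records, g, tolerance=config.junction_tolerance)
    grades = grade_evidence(assignment, g, strong_threshold=config.strong_threshold)
    calls = detect_mechanisms(g, min_overlap=config.min_overlap)
    reference = _reference_transcript(distinct, grades)
    alternatives = [t for t in distinct if t.id != reference.id]
    discounts = apply_discount_rules(
        g, genome, reference, alternatives, assignment, config
    )
    discounted_ids = {tid for tid, rs in discounts.items() if rs}
    all_reasons = frozenset(
        r.value for rs in discounts.values() for r in rs
    )

    if alternatives and all(t.id in discounted_ids for t in alternatives):
        return ClassificationResult(
            g.id,
            Category.DISCOUNTED,
            mechanisms=tuple(calls),
            discount_reasons=all_reasons,
            grades=grades,
            reference_transcript=reference.id,
        )

    surviving = [c for c in calls if _call_survives(c, reference.id, discounted_ids)]
    warnings: tuple[str, ...] = ()
    if not surviving:
        # structurally distinct transcripts, but no recognised mechanism:
        # report as no alternative with a warning rather than inventing one
        return ClassificationResult(
            g.id,
            Category.NO_ALTERNATIVE,
            grades=grades,
            reference_transcript=reference.id,
            warnings=("distinct transcripts but no mechanism detected",),
        )

    types = {c.mechanism for c in surviving}
    start_types = types & {Mechanism.UNIQUE_START, Mechanism.NESTED_START}
    other_types = types - start_types
    n_effective = len(other_types) + (1 if start_types else 0)

    def mech_grade(mech_set: set[Mechanism]) -> Grade:
        involved = {
            tid
            for c in surviving
            if c.mechanism in mech_set
            for tid in c.transcripts
            if tid != reference.id and tid not in discounted_ids
        }
        if not involved:  # only the reference is involved (e.g. unique starts)
            involved = {
                tid
                for c in surviving
                if c.mechanism in mech_set
                for tid in c.transcripts
            }
        gs = [grades[tid].grade for tid in involved if tid in grades]
        strong = bool(gs) and all(x == Grade.STRONG for x in gs)
        return Grade.STRONG if strong else Grade.WEAK

    if n_effective >= 2:
        per_type = [mech_grade({m}) for m in other_types]
        if start_types:
            per_type.append(mech_grade(start_types))
        category = (
            Category.MULTIPLE_STRONG
            if all(x == Grade.STRONG for x in per_type)
            else Category.MULTIPLE_WEAK
        )
    elif start_types:
        if start_types == {Mechanism.NESTED_START}:
            category = Category.NESTED_START
        else:
            strong, weak = _MECH_CATEGORY[Mechanism.UNIQUE_START]
            category = Category(
                strong if mech_grade(start_types) == Grade.STRONG else weak
            )
    else:
        (mech,) = other_types
        strong, weak = _MECH_CATEGORY[mech]
        category = Category(strong if mech_grade({mech}) == Grade.STRONG else weak)

    return ClassificationResult(
        g.id,
        category,
        mechanisms=tuple(surviving),
        discount_reasons=all_reasons,
        grades=grades,
        reference_transcript=reference.id,
        warnings=warnings,
    )


def _call_survives(
    call: MechanismCall, reference_id: str, discounted: set[str]
) -> bool:
    non_ref = [tid for tid in call.transcripts if tid != reference_id]
    if not non_ref:
        return True
    return any(tid not in discounted for tid in non_ref)


# ---------------------------------------------------------------------------
# cohort summaries


def summarize_cohort(results: Iterable[ClassificationResult]) -> pd.Series:
    """Counts per category over a cohort; categories partition the cohort."""
    counts = {c.value: 0 for c in Category}
    n = 0
    for r in results:
        counts[r.category.value] += 1
        n += 1
    s = pd.Series(counts, name="n_genes")
    s.index.name = "category"
    assert int(s.sum()) == n
    return s


def aggregate_summary(counts: Mapping[str, int]) -> dict[str, int]:
    """Roll category counts up into mechanism-family aggregates."""

    def total(*names: str) -> int:
        return sum(int(counts.get(n, 0)) for n in names)

    agg = {
        "alternative_transcript_starts": total(
            "UNIQUE_START_STRONG", "UNIQUE_START_WEAK", "NESTED_START"
        ),
        "alternative_transcript_ends": total(
            "ALT_TERMINAL_STRONG", "ALT_TERMINAL_WEAK"
        ),
        "alternative_splicing": total(
            "CASSETTE_STRONG",
            "CASSETTE_WEAK",
            "RETAINED_INTRON_STRONG",
            "RETAINED_INTRON_WEAK",
            "SPLICE_SHIFT_STRONG",
            "SPLICE_SHIFT_WEAK",
        ),
        "multiple_mechanisms": total("MULTIPLE_STRONG", "MULTIPLE_WEAK"),
        "discounted": total("DISCOUNTED"),
        "same_protein": total("SAME_PROTEIN"),
        "no_alternative": total("NO_ALTERNATIVE"),
    }
    agg["total"] = sum(int(v) for v in counts.values())
    return agg


def results_to_frame(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "category": r.category.value,
                "mechanisms": ";".join(
                    sorted({c.mechanism.value for c in r.mechanisms})
                ),
                "discount_reasons": ";".join(sorted(r.discount_reasons)),
                "reference_transcript": r.reference_transcript,
                "warnings": ";".join(r.warnings),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "category",
            "mechanisms",
            "discount_reasons",
            "reference_transcript",
            "warnings",
        ],
    )
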