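"""Packaged reference tables from the *C. elegans* transcription-factor
isoform survey, and the aggregations over them.

Two tables ship with the package:

* ``isoform_category_counts.tsv`` — the cohort-level category counts for the
  938 candidate transcription factor genes (how many genes fall into each
  alternative-isoform category, by mechanism and evidence strength).
* ``assayed_genes.tsv`` — the 29 genes selected for reporter-fusion assays,
  with their isoform annotation labels and evidence assessments.

These are curation results over a genome-annotation snapshot and are not
recomputable from scratch here; they serve as fixed inputs whose internal
arithmetic (family aggregates, partition identities) the package recomputes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

# row labels in the category-count table
TOTAL = "Total considered"
NO_EVIDENCE = "No evidence for alternative transcripts"
SAME_PROTEIN = "Alternative transcripts encode same protein"
ANNOTATED_DISTINCT = "Alternative transcripts annotated to encode different isoforms"
DISCOUNTED = "Alternative transcript evidence considered invalid"

_START_ROWS = (
    "Alternative unique starting exon - strong evidence",
    "Alternative unique starting exon - weak evidence",
    "Nested alternative starts",
)
_END_ROWS = (
    "Alternative terminal exon - strong evidence",
    "Alternative terminal exon - weak evidence",
)
_SPLICING_ROWS = (
    "Non-constitutive internal exon - strong evidence",
    "Non-constitutive internal exon - weak evidence",
    "Non-constitutive internal intron - strong evidence",
    "Non-constitutive internal intron - weak evidence",
    "Alternative splice site selection - strong evidence",
    "Alternative splice site selection - weak evidence",
)
_MULTIPLE_ROWS = (
    "Alternative transcripts by multiple mechanisms - strong evidence",
    "Alternative transcripts by multiple mechanisms - weak evidence",
)


def _read(name: str) -> pd.DataFrame:
    with resources.files("isoscope").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t", keep_default_na=False)


def load_isoform_category_counts() -> pd.DataFrame:
    return _read("isoform_category_counts.tsv")


def load_assayed_genes() -> pd.DataFrame:
    return _read("assayed_genes.tsv")


def reference_aggregates(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Mechanism-family aggregates recomputed from the category-count table.

    Returns the number of genes with alternative transcript starts, ends,
    splicing, multiple mechanisms, the discounted count, the number of genes
    annotated with distinct isoforms (recomputed as the sum of the mechanism
    rows), and the total cohort size (recomputed as no-evidence +
    same-protein + annotated-distinct).
    """
    if df is None:
        df = load_isoform_category_counts()
    counts = dict(zip(df["category"], df["n_genes"].astype(int)))

    def total(rows) -> int:
        return sum(counts[r] for r in rows)

    mechanism_rows_sum = (
        total(_START_ROWS)
        + total(_END_ROWS)
        + total(_SPLICING_ROWS)
        + total(_MULTIPLE_ROWS)
        + counts[DISCOUNTED]
    )
    return {
        "alternative_transcript_starts": total(_START_ROWS),
        "alternative_transcript_ends": total(_END_ROWS),
        "alternative_splicing": total(_SPLICING_ROWS),
        "multiple_mechanisms": total(_MULTIPLE_ROWS),
        "discounted": counts[DISCOUNTED],
        "annotated_distinct_isoforms": mechanism_rows_sum,
        "total_considered": counts[NO_EVIDENCE]
        + counts[SAME_PROTEIN]
        + mechanism_rows_sum,
    }


def assayed_gene_counts(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Study-design counts recomputed from the assayed-gene table."""
    if df is None:
        df = load_assayed_genes()
    ann = df["annotation"]
    return {
        "assayed_genes": len(df),
        "assayed_alternative_promoters": int((ann == "Alternative promoters").sum()),
        "assayed_optional_exon": int((ann == "Exon +/-").sum()),
        "assayed_optional_intron": int((ann == "Intron +/-").sum()),
        "assayed_complex": int(ann.str.startswith("Complex").sum()),
        "assayed_well_supported": int((df["assessment"] == "Well-supported").sum()),
    }
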