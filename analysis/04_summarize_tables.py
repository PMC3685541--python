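"""Aggregate the packaged reference tables.

Recomputes the mechanism-family aggregates from the packaged cohort
category-count table (genes with alternative transcript starts, ends,
splicing, multiple mechanisms, and discounted annotations) and the
study-design counts from the assayed-gene table, and writes both to
results/reference_summary.tsv.  These aggregates are the arithmetic
backbone of the cohort survey: the category rows must sum to the number of
genes annotated with distinct isoforms, and that number plus the
no-evidence and same-protein genes must reproduce the full cohort size.
"""

from pathlib import Path

import pandas as pd

from isoscope.tables import assayed_gene_counts, reference_aggregates

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    agg = dict(reference_aggregates())
    agg.update(assayed_gene_counts())
    s = pd.Series(agg, name="n_genes").rename_axis("quantity")
    RESULTS.mkdir(exist_ok=True)
    s.to_csv(RESULTS / "reference_summary.tsv", sep="\t")
    print(s.to_string())


if __name__ == "__main__":
    main()
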