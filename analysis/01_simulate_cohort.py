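"""Simulate the study cohorts.

Generates two synthetic cohorts under scratch/ (bulky raw FASTA/GFF3/TSV
data; the small summary tables land under results/):

* ``cohort_clean`` — 140 multi-transcript loci, mechanisms mixed uniformly
  across the six structural classes plus single-transcript genes, three
  independent ESTs per transcript and no artifact reads.  This is the
  evidence level under which a curator would call support "strong".
* ``cohort_artifact`` — the same mechanism mixture but with EST artifact
  modes switched on (70% 5'-truncated reads, 30% unspliced genomic reads),
  emulating incomplete first-strand cDNA synthesis and unarrested
  transcriptional read-through.

Each cohort is a FASTA genome, a GFF3 annotation, an evidence TSV and a
truth table, all reproducible from the seed.
"""

from pathlib import Path

from isoscope.synthetic import MECHANISMS, SyntheticGeneSpec, generate_cohort

SCRATCH = Path(__file__).resolve().parent.parent / "scratch"
SEED = 20130415
N_GENES = 140
MIX = {m: 1.0 / len(MECHANISMS) for m in MECHANISMS}


def main() -> None:
    clean = generate_cohort(N_GENES, MIX, SEED, out_dir=SCRATCH / "cohort_clean")
    artifact_spec = SyntheticGeneSpec(p_truncated_5p=0.7, p_unspliced=0.3)
    noisy = generate_cohort(
        N_GENES, MIX, SEED + 1, base_spec=artifact_spec,
        out_dir=SCRATCH / "cohort_artifact",
    )
    for name, cohort in [("clean", clean), ("artifact", noisy)]:
        mechs = cohort.truth_frame()["mechanism"].value_counts().to_dict()
        print(f"cohort_{name}: {len(cohort.genes)} genes, "
              f"{len(cohort.records)} EST records, mechanisms {mechs}")


if __name__ == "__main__":
    main()
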