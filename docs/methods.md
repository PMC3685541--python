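# Methods

## Coordinate model

All internal coordinates are 0-based, half-open; GFF3's 1-based inclusive
convention is converted exactly once, at the file boundary, and the
writer/parser pair round-trips byte-for-byte.  A transcript stores its
exons in transcript (5'→3') order, so minus-strand chains have descending
genomic coordinates; `cds_start`/`cds_end` are the genomic positions of
the first base of the initiation codon and the last base of the
termination codon in transcript orientation.  All transcripts of one gene
must share a strand — antisense neighbours are separate genes, and a mixed
gene is a hard annotation error.  Trans-splicing is represented only as a
boolean flag on the transcript; leader sequence is not modelled.

## Mechanism detectors

Multi-transcript genes are reduced to ordered transcript pairs; calls are
deduplicated and all detectors are invariant under a strand flip of the
locus (verified by property test).

* **Unique start** — transcript *t* qualifies when its first exon overlaps
  no exon of any other transcript by at least `min_overlap` bases
  (default 1).  A transcript that *hosts* a nested transcript is excluded:
  its first exon is trivially unshared, but the gene's alternative starts
  are then nested rather than promoter-specific first exons.
* **Nested start** — *s* nests in *t* when its 5' terminus lies within an
  exon of *t* (but not at *t*'s own 5' terminus) and everything from that
  point on is structurally identical to *t*.  When several hosts exist
  the call is reported against the transcript whose 5' terminus is most 5'
  — "longest" in the promoter sense, not by genomic span.  Whether the
  nested 5' end coincides with a splice-acceptor position (the
  trans-splice reading) is recorded as an `acceptor_coincident` flag but
  deliberately not acted upon.
* **Alternative terminal** — either the foreshortened transcript's final
  exon shares its 5' boundary with an internal exon of the longer
  transcript and extends 3' into that transcript's intron, or it is a
  unique exon 3' of a shared chain.  The detail records which case, plus
  an advisory NMD hint when the terminal exon is internal to the partner's
  extent.
* **Retained intron** — an intron of one transcript is wholly contained
  in a single exon of the other, and the two are otherwise
  junction-identical over the genomic region they share.  The detail
  carries the 1-based intron index in transcript order.
* **Cassette exon** — an internal exon of one transcript lies wholly
  within one intron of the other while both flanking junctions (donor of
  the upstream intron, acceptor of the downstream one) are shared.
* **Splice-site shift** — two introns share one boundary (donor or
  acceptor) and differ at the other by offset *d* > 0, with
  `frame_preserved = (d mod 3 == 0)`.  A guard requires the exons
  flanking the junction on *both* sides to overlap between the two
  transcripts: splice-site selection presumes the same flanking exons,
  and this is what keeps cassette exons, unique first exons and unique
  terminal exons — all of which produce a half-matching junction pair —
  from masquerading as shifts.

Every detector is checked against an independent brute-force oracle that
works on per-base position sets rather than interval arithmetic, over a
thousand randomly perturbed toy gene pairs.

## Evidence model

A support record (EST, RT-PCR product, or ORFeome clone) is an aligned
exon chain.  It supports a transcript iff its junctions match a
consecutive run of the transcript's junctions — each coordinate within
`junction_tolerance` bases (default 0; synthetic data is exact, real
alignments are noisy, so this is a config knob) — and its outer blocks lie
inside the flanking exons.  Records compatible with several transcripts
support all of them; junction-bearing records compatible with none are
returned unassigned, and intronless records spanning an annotated intron
are additionally flagged `UNSPLICED` (they look like the primary unspliced
transcript).

Grading: `n_independent` counts distinct library keys among **5'-complete**
EST records; `STRONG` requires `n_independent ≥ strong_threshold`
(default 2 — "multiple independent" is not quantified anywhere
authoritative, so two distinct libraries is the package's operational
definition, and the threshold is configurable).  Any lesser support —
fewer ESTs, truncated ESTs, clone or PCR products — is `WEAK`; no support
is `UNSUPPORTED`.  Two deliberate asymmetries encode the artifact logic:
a 5'-truncated cDNA (incomplete first-strand synthesis) never counts as
independent support and never defines a transcript start, and a
primer-encoded clone start sets a `PRIMER_DERIVED` flag because the primer
presupposes the start it claims to demonstrate.  Library-key independence
is a proxy; no stronger independence criterion is defined for single-pass
cDNA data.

## Translation checks and discount rules

Translation uses the standard nuclear code only (no selenocysteine
recoding).  NMD candidacy follows the standard metazoan convention: a stop
whose end lies ≥ `nmd_distance` bases (default 50) upstream of the last
exon–exon junction in spliced coordinates; the rule depends only on
spliced coordinates and is invariant to intron length, and single-exon
transcripts are never candidates.  An upstream ATG *blocks* the main ORF
when it is out of frame with the main start and its frame reaches no stop
before the main start — the case where reinitiation is implausible.  This
is one defensible formalisation of "most unlikely to be translated", and
results carry it as an explicit reason rather than silently.

Per alternative transcript (everything except the reference — the
transcript with most independent support, ties broken by record count,
then CDS length, then identifier), the discount rules are:

* `BLOCKING_UORF` — a blocking upstream ATG in its 5'UTR;
* `WRONG_FRAME` — its terminal reading frame differs from the reference's
  over a shared final exon *and* it rests on at most one record;
* `UNSPLICED_PRIMARY` — all of its support is intronless while it covers
  reference introns exonically (the annotation is the primary unspliced
  transcript);
* `NO_PRODUCTIVE_ALTERNATIVE` — its own reading frame is an NMD candidate.

A gene whose alternatives are all discounted is `DISCOUNTED`.  Otherwise
the surviving mechanism *types* decide the category; unique and nested
starts are treated as one "alternative starts" family when deciding
whether a gene is `MULTIPLE` (both are promoter mechanisms; a gene is
filed under nested starts only when nesting is the sole start mechanism,
matching the "nested transcripts only" reading).  A mechanism is strong
only when every alternative transcript it involves grades STRONG — the
minimum-grade rule; the source assessments never state how mixed grades
were resolved, so this conservative choice is the package's own.  Genes
whose transcripts differ structurally but trigger no detector are reported
as `NO_ALTERNATIVE` with an explicit warning rather than being forced into
a category.

## Reporter model

Edits are applied to the genome sequence with exact propagation of all
annotation coordinates (everything 3' of an insertion shifts by the
payload length; deletions clamp interior coordinates).  Splicing is
assumed unchanged unless an edit touches a splice dinucleotide, in which
case a `SpliceDisruptionWarning` is raised instead of a silent prediction
— edits squeezed between a splice acceptor and a directly juxtaposed
initiation codon are exactly the situation where that assumption fails.

Expression is binary per transcript: `IN_FRAME` iff translation from the
transcript's annotated initiation codon reaches the reporter with no prior
stop and traverses it in the reporter's frame 0.  The annotated initiation
point is taken as given — ATGs created (or, pathologically, destroyed) by
edits are out of model.  A reporter upstream of a transcript's initiation
codon is reported as `REPORTER_NOT_IN_TRANSCRIPT`, the same reason as a
reporter outside its exons, since it is equally untranslated.  Expression
levels ("weaker" patterns) are out of model entirely.

The designed panel is the standard tagging strategy, not a minimum set
cover: one reporter insertion immediately after each distinct initiation
codon — with a single-base insertion immediately 5' of the targeted codon
whenever an upstream-starting transcript would otherwise read the reporter
in frame — one insertion immediately before each distinct termination
codon, and, for each detected optional exon or retained intron, a terminal
fusion combined with a single base inserted into the middle of the
optional element (disrupting exactly the element-containing transcripts).
A three-promoter gene therefore yields four constructs even though two
would formally separate the transcripts; the panel mirrors what one would
actually build and keeps the terminal fusion as the summation control
(terminal expression = union of the start fusions, a property tested on
unambiguous loci).  Transcript classes with identical indicator vectors
across the whole panel are reported inseparable — notably few-base
splice-site shifts, where no insertion construct can distinguish the
forms.  Homology arms default to 50 nt per side.

## Synthetic data

The generator's defaults are the validation conditions: 2–3 transcripts
per gene, 4–6 exons of 60–180 bp, GT–AG introns of 48–90 bp, 18–48 bp
5'UTRs kept free of ATG (so no accidental upstream ORF confounds the
planted truth), 24–60 bp 3'UTRs, 500 bp of flanking sequence (so 50-nt
homology arms always resolve), three ESTs per transcript drawn from a
round-robin over 12 library keys, and no artifacts.  Without expression
weights, transcripts are cycled so each receives exactly its designed
share of ESTs — the point of the defaults is a *guaranteed* evidence
level, with weighted sampling available when sampling noise is wanted.
Strand is drawn at random per locus, which keeps minus-strand code paths
permanently exercised.

Every planted locus is rejected-and-regenerated (bounded retries) until
all productive transcripts carry clean ORFs: CDS starts ATG, ends at a
stop, no internal in-frame stop — including through retained introns and
acceptor extensions, whose sequences are re-drawn until stop-free.
Frame-shifting variants are planted deliberately: a cassette exon of
length ≢ 0 (mod 3) holds random content so that the *including* transcript
frameshifts into an early stop and becomes an NMD candidate, and
splice-shift offsets outside {3, 6, 9, 12} do the same to the shifted
form.  Alternative acceptors are written with their own AG dinucleotide
inside the intron, so both splice forms are canonical.

What the generator does **not** emulate: realistic nucleotide composition,
splice-site strength, sequencing error, expression-level variation between
tissues, overlapping genes, or alignment noise (records are exact chains;
the junction tolerance exists for real data but is untested against a real
aligner).  Passing tests therefore demonstrate the correctness of the
logic under clean structural conditions, not performance on noisy
genome-wide alignments.

## Packaged reference tables

Two small TSVs ship with the package: the cohort-level category counts for
the 938 candidate transcription factor genes, and the 29 genes selected
for reporter assays with their annotation labels.  They are curation
results over an external annotation snapshot and are not recomputable
here; what the package recomputes — in `isoscope.tables`, the analysis
scripts and the acceptance script — is their internal arithmetic: the
mechanism-family aggregates (50 genes with alternative starts, 23 with
alternative ends, 35 with alternative splicing, 34 multiple, 55
discounted), the partition identity summing the mechanism rows to the 197
annotated multi-isoform genes, the 938-gene total, and the study-design
counts (18 + 2 + 3 + 6 = 29 assayed genes).

## Problem sizes and determinism

Cohort-scale checks use 200 generated loci per mechanism for category
recovery, 1,000 random toy pairs for detector–oracle equivalence and 500
edited loci for the reporter oracle; at roughly a millisecond per locus
the full suite runs in a few seconds.  All randomness flows through
NumPy `default_rng` seeded from explicit integers (spec seeds, or the
acceptance script's `--seed` via independent child streams), so every
cohort, file and result is bit-reproducible.
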