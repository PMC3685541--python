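"""Exception and warning types shared across the package."""


class IsoscopeError(Exception):
    """Base class for package errors."""


class MalformedAnnotationError(IsoscopeError, ValueError):
    """Annotation violates the gene/mRNA/exon/CDS contract (e.g. exon outside
    the gene span, CDS not contained in exons, mixed strands in one gene)."""


class OutOfBoundsError(IsoscopeError, ValueError):
    """A coordinate falls outside the named sequence."""


class NotComparableError(IsoscopeError, ValueError):
    """Two transcripts lack the shared structure an operation requires."""


class GenerationError(IsoscopeError, RuntimeError):
    """The synthetic-locus generator could not satisfy its constraints within
    the bounded number of retries."""


class EditError(IsoscopeError, ValueError):
    """An in-silico edit set is invalid (overlapping edits, bad payload)."""


class SpliceDisruptionWarning(UserWarning):
    """An edit touches a splice dinucleotide; splicing of the edited locus can
    no longer be assumed unchanged, so downstream predictions are suspect."""
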