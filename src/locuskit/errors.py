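"""Exception hierarchy for locuskit.

Every failure mode the pipeline distinguishes gets its own class so callers
(and the CLI) can react to the *kind* of problem, not a message string.
"""


class LocusKitError(Exception):
    """Base class for all locuskit errors."""


class MissingGeneError(LocusKitError):
    """Requested gene id not present in the annotation."""


class MixedStrandError(LocusKitError):
    """Exons of one gene annotated on both strands."""


class CdsFrameError(LocusKitError):
    """Translated CDS length is not a multiple of three."""


class WindowBoundsError(LocusKitError):
    """Requested window extends beyond the chromosome; never silently clipped."""


class SequenceAlphabetError(LocusKitError):
    """Sequence contains a character outside {A, C, G, T, N}."""


class OutsideRegionError(LocusKitError):
    """A variant position falls outside the region an operation requires."""


class MalformedInputError(LocusKitError):
    """Unparseable input file (VCF line, matrix block, map row ...)."""


class NoGenotypesError(LocusKitError):
    """An operation needing called genotypes found none."""


class UnsupportedVariantError(LocusKitError):
    """Variant class not handled by the requested operation (e.g. indel codon)."""


class AlleleMismatchError(LocusKitError):
    """VCF REF allele disagrees with the reference sequence under the window."""


class MatrixFormatError(LocusKitError):
    """Ragged or otherwise invalid position-frequency matrix."""


class SpikeError(LocusKitError):
    """Synthetic scenario asks for an unrealizable spike configuration."""
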