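"""Exception hierarchy for polyase.

All library errors derive from :class:`PolyaseError` so callers can catch
one base class at pipeline boundaries.
"""


class PolyaseError(Exception):
    """Base class for all polyase errors."""


class ReferenceMismatchError(PolyaseError, ValueError):
    """The stated reference allele does not match the sequence at that offset."""


class FlankBoundsError(PolyaseError, ValueError):
    """A sequence does not extend far enough around the variant."""


class DesignInfeasibleError(PolyaseError, ValueError):
    """No allele satisfying the design constraints exists."""


class CoordinateError(PolyaseError, ValueError):
    """A genomic position falls outside the expected feature (e.g. not exonic)."""


class NoJunctionError(PolyaseError, ValueError):
    """A transcript has no exon-exon junction (single-exon)."""


class SchemaError(PolyaseError, ValueError):
    """A table is missing required columns."""


class FastqParseError(PolyaseError, ValueError):
    """A FASTQ record could not be parsed."""


class UndefinedRateError(PolyaseError, ZeroDivisionError):
    """A rate is undefined because the denominator (coverage) is zero."""


class UndefinedAfcError(PolyaseError, ValueError):
    """aFC is undefined because an allele count is zero and pseudocount is 0."""


class DegenerateNullError(PolyaseError, ValueError):
    """The empirical control null has zero spread or too few variants."""


class ParameterError(PolyaseError, ValueError):
    """A simulation or configuration parameter is outside its valid range."""
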