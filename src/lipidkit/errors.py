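"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`LipidkitError` so callers can
distinguish pipeline failures from programming errors.
"""


class LipidkitError(Exception):
    """Base class for all package errors."""


# --- nomenclature ---------------------------------------------------------

class LipidNameError(LipidkitError):
    """A shorthand lipid name could not be interpreted."""


class UnknownClassError(LipidNameError):
    """Class token absent from the registry."""


class MalformedChainError(LipidNameError):
    """Chain token does not match the C:D[;On] pattern."""


class ChainCountMismatchError(LipidNameError):
    """Molecular-species name with the wrong number of chains for its class."""


class SumCompositionError(LipidkitError):
    """Operation requires molecular-species resolution but the species is
    annotated only at sum-composition level."""


# --- quantification -------------------------------------------------------

class MissingInternalStandardError(LipidkitError):
    """A lipid class in the feature table has no internal-standard mapping."""


class ZeroInternalStandardAreaError(LipidkitError):
    """An internal standard has zero area in a sample (acquisition failure)."""


class AllMissingSpeciesError(LipidkitError):
    """A species has no positive measurement in any sample."""


# --- statistics -----------------------------------------------------------

class DegenerateVarianceError(LipidkitError):
    """Both groups have zero variance; the test statistic is undefined."""


class ConstantVectorError(LipidkitError):
    """Correlation requested against a constant vector."""


class TooFewSamplesError(LipidkitError):
    """Not enough samples for the requested operation."""


# --- multivariate ---------------------------------------------------------

class ZeroMedianError(LipidkitError):
    """A sample column has median zero; median normalisation is undefined."""


class RankDeficientError(LipidkitError):
    """More components requested than the matrix rank supports."""


# --- networks -------------------------------------------------------------

class EdgeClassAbsentError(LipidkitError):
    """A catalogued edge references a class absent from the data."""


class ClassAbsentError(LipidkitError):
    """Requested lipid class not present in the matrix."""


class UnknownEdgeError(LipidkitError):
    """A planted edge references classes or chains outside the design."""


# --- synthetic / IO -------------------------------------------------------

class InvalidDesignError(LipidkitError):
    """Synthetic design violates its invariants."""


class TableFormatError(LipidkitError):
    """Input table malformed (duplicates, missing columns, bad values)."""


class SampleMetadataMismatchError(LipidkitError):
    """Feature-table samples and metadata do not line up."""
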