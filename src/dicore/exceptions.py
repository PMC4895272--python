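"""Exception hierarchy for input validation and pipeline errors."""


class DicoreError(Exception):
    """Base class for all package errors."""


class MissingFileError(DicoreError, FileNotFoundError):
    """Input file does not exist."""


class DuplicateIDError(DicoreError, ValueError):
    """A feature or sample ID occurs more than once."""


class NonNumericError(DicoreError, ValueError):
    """Expression body contains a non-numeric or missing cell."""


class RaggedRowError(DicoreError, ValueError):
    """A data row has a different number of fields than the header."""


class InsufficientOverlapError(DicoreError, ValueError):
    """Fewer than three sample IDs are shared between the two matrices."""


class ReferenceParseError(DicoreError, ValueError):
    """Malformed line in a reference interaction table."""


class ParameterError(DicoreError, ValueError):
    """A parameter is outside its admissible range."""


class MembershipError(DicoreError, KeyError):
    """A group member is not present in the collaboration matrix."""


class GroupSizeError(DicoreError, ValueError):
    """A group is too small for canonical correlation analysis."""


class SingularCovarianceError(DicoreError, ValueError):
    """Classical CCA covariance is singular; a regularized method is required."""


class ScenarioError(DicoreError, ValueError):
    """Infeasible synthetic-data scenario."""
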