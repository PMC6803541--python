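"""Exception hierarchy shared across the pipeline stages.

Error classes map onto the CLI exit codes: schema problems (malformed
input files), domain problems (values outside the model's assumptions),
and resource problems (computations that would exceed configured bounds).
"""


class OiassocError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(OiassocError):
    """An input file is missing a required column or is malformed."""

    exit_code = 2


class VocabularyError(OiassocError):
    """A phenotype label is not part of the controlled vocabulary."""

    exit_code = 3


class HGVSParseError(OiassocError):
    """A protein-level HGVS string could not be interpreted."""

    exit_code = 3


class CoordinateError(OiassocError):
    """A residue position does not map into the reference sequence."""

    exit_code = 3


class DomainError(OiassocError):
    """A value violates a documented precondition."""

    exit_code = 3


class EnumerationBoundError(OiassocError):
    """An exact-test enumeration would exceed the configured table total."""

    exit_code = 4


class SpecError(OiassocError):
    """A synthetic-data specification is internally inconsistent."""

    exit_code = 3
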