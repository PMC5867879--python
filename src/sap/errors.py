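"""Exception hierarchy shared across the package.

``SAPError`` is the base for every data/validation failure the pipeline can
raise; the CLI maps it to exit code 2, keeping exit code 1 for usage errors.
"""


class SAPError(Exception):
    """Base class for all data and validation errors."""


class FastaParseError(SAPError):
    """A FASTA file could not be parsed into records."""


class ValidationError(SAPError):
    """Input violated a domain invariant (alphabet, ids, labels, shapes)."""


class AlphabetError(ValidationError):
    """A sequence contains a character outside the 20 standard residues."""


class DuplicateIdError(ValidationError):
    """Two records in one dataset share an identifier."""


class TooShortError(ValidationError):
    """A peptide is too short for the requested feature block."""


class UndefinedMetricError(SAPError):
    """A confusion-matrix metric is undefined for the given counts."""


class InconsistentRatesError(SAPError):
    """Printed rates admit no integer confusion counts at their precision."""
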