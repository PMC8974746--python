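"""Exception hierarchy.

Parse and I/O problems (bad input files) are kept distinct from validation
and configuration problems (bad values, bad rule sets) so the command-line
layer can map them to stable exit codes.
"""


class AllerScreenError(Exception):
    """Base class for all toolkit errors."""


class ParseError(AllerScreenError, ValueError):
    """Malformed input file (FASTA, flat file)."""


class SchemaError(AllerScreenError, ValueError):
    """Delimited table does not match the expected column schema."""


class ConfigError(AllerScreenError, ValueError):
    """Invalid configuration: rule set, matrix name, thresholds."""


class ValidationError(AllerScreenError, ValueError):
    """A domain object violates an invariant (record, entry, decision)."""


class AlignmentError(AllerScreenError, ValueError):
    """Invalid alignment request (empty sequence, residue not in matrix)."""


class ReleaseConflictError(AllerScreenError, ValueError):
    """Accession collision while building a release without update mode."""
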