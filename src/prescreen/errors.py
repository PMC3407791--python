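"""Exception hierarchy.

Every user-facing failure raises a subclass of :class:`PrescreenError` with a
message that names the offending field, row or file — never a bare stack
trace. The CLI maps these to exit code 1; anything else is an internal error
(exit code 2).
"""


class PrescreenError(Exception):
    """Base class for all errors raised on invalid user input or data."""


class ExtractFormatError(PrescreenError):
    """A warehouse extract file is missing, malformed or violates the schema."""


class ReferentialIntegrityError(ExtractFormatError):
    """A child row references a patient_id absent from patients.csv."""


class PatientNotFoundError(PrescreenError):
    """A requested patient_id does not exist in the extract."""


class ChecklistSchemaError(PrescreenError):
    """An eligibility checklist document does not conform to the schema."""


class ConfigurationError(PrescreenError):
    """A criterion or config refers to an unknown attribute, vocabulary, etc."""


class InputError(PrescreenError):
    """Invalid value passed to an analysis operation."""
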