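"""Exception hierarchy shared across the package."""


class DigenetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(DigenetError):
    """A text input file could not be parsed (names the offending line)."""


class ValidationError(DigenetError):
    """Inputs are syntactically fine but violate a documented contract."""


class FormatError(DigenetError):
    """A structured artifact (TSV pattern list) has the wrong layout."""


class SimulationError(DigenetError):
    """A simulation configuration cannot produce the requested cohort."""


class VariantLookupError(DigenetError, KeyError):
    """A variant id is not present in the dataset at hand."""
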