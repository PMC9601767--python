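"""Exception hierarchy shared across the package."""


class AfDisorderError(Exception):
    """Base class for all package-specific errors."""


class InputError(AfDisorderError):
    """Unreadable, malformed or out-of-range user input."""


class FormatError(InputError):
    """A file does not conform to the expected dialect."""


class EmptyModelError(InputError):
    """A structure file contains no protein residues."""


class ConsistencyError(AfDisorderError):
    """Lengths or identifiers of paired inputs do not match."""


class ConfigurationError(AfDisorderError):
    """An invalid method constant (threshold, radius, table...)."""


class DegenerateInputError(AfDisorderError):
    """A metric is undefined on this input (e.g. single-class labels)."""


class EmptyEvaluationError(AfDisorderError):
    """No prediction/reference pair could be matched."""


class ConstructionError(AfDisorderError):
    """Synthetic geometry could not be built without atom clashes."""
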