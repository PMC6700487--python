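"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: input/format/parameter problems exit
with 2, a missing folding engine with 3.
"""


class MirhairpinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MirhairpinError):
    """A file exists but its contents violate the expected format."""


class ParameterError(MirhairpinError):
    """A configuration value or function argument is out of range."""


class InputError(MirhairpinError):
    """A sequence or in-memory input violates a precondition."""


class BackendUnavailableError(MirhairpinError):
    """The requested external folding engine cannot be loaded."""
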