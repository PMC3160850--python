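"""Exception hierarchy.

InputError / ParseError map to CLI exit code 1, anything else to 2.
"""


class FragPickError(Exception):
    """Base class for all package errors."""


class ParseError(FragPickError):
    """A file does not follow its documented dialect."""


class InputError(FragPickError):
    """Inconsistent or missing user input (length mismatches, bad values)."""


class ConfigurationError(FragPickError):
    """The scoring/collector configuration cannot be satisfied at startup."""
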