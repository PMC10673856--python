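"""Exception types shared across the pipeline."""


class EditscanError(Exception):
    """Base class for all editscan errors."""


class ConfigurationError(EditscanError, ValueError):
    """A spec/threshold object violates its own invariants."""


class InputError(EditscanError, ValueError):
    """Malformed input data (bad alphabet, out-of-bounds edit, missing field)."""


class DegenerateInputError(EditscanError, ValueError):
    """Structurally valid input on which the computation is undefined
    (e.g. an all-zero control trace window, an empty allele table)."""
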