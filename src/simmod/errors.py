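"""Exception hierarchy."""


class SimModError(Exception):
    """Base class for all errors raised by this package."""


class InputError(SimModError):
    """Malformed or inconsistent user input (files, counts, parameters)."""
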