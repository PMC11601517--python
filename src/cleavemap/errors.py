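"""Exception hierarchy."""


class CleavemapError(Exception):
    """Base class for all package errors."""


class DataError(CleavemapError):
    """Malformed or out-of-contract input data."""
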