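"""Exception hierarchy shared across the package."""


class NoncodeError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NoncodeError):
    """Invalid input data (sequences, labels, tables, probabilities)."""


class BundleError(NoncodeError):
    """Model-bundle persistence problems (corruption, version mismatch)."""
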