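"""Package-wide exception types."""


class InvalidParameterError(ValueError):
    """A parameter is outside its allowed domain (non-positive rescale factor,
    even window size, unknown encoding name, ...)."""


class ResourceLimitError(RuntimeError):
    """An operation would allocate a density pattern larger than the configured
    matrix-side cap."""
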