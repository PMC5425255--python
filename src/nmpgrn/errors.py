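"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid user-supplied configuration (program sizes, proportions, ...)."""


class LayerError(ValueError):
    """An operation received an ExpressionMatrix in the wrong layer."""


class EmptyResultError(RuntimeError):
    """A filter removed everything; callers must be told explicitly."""
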