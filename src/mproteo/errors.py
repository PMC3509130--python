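"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A parameter or config file is invalid; the message names the field."""


class DataError(ValueError):
    """An input record or table violates a precondition."""


class ConvergenceError(RuntimeError):
    """An iterative procedure failed to converge within its iteration budget."""
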