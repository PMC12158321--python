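"""Exception types shared across the package."""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class InvalidStateError(RuntimeError):
    """An object is in a state in which the requested operation is undefined."""
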