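"""Exception types shared across the package."""


class FormatError(ValueError):
    """A file violates the expected on-disk format (missing column, ragged
    alignment, non-numeric cell under strict parsing, ...)."""


class ContractError(ValueError):
    """An in-memory call violates an operation's precondition (wt == mut,
    dimension mismatch, single-class input, out-of-range position, ...)."""
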