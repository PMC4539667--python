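"""Exception types shared across the package."""


class FastaParseError(ValueError):
    """Raised when a FASTA file is malformed; the message names the offending record."""


class DuplicateIdError(ValueError):
    """Raised when a loaded sequence set contains duplicate record IDs."""

    def __init__(self, duplicates):
        self.duplicates = sorted(duplicates)
        super().__init__(
            "duplicate record id(s) in FASTA: " + ", ".join(self.duplicates)
        )


class InsufficientBackgroundError(ValueError):
    """Raised when too few usable reference sequences are available for a background model."""

    def __init__(self, usable: int, required: int, total: int):
        self.usable = usable
        self.required = required
        self.total = total
        super().__init__(
            f"background requires >= {required} records with defined mean stretch "
            f"length, got {usable} usable of {total} total"
        )


class UnknownGroupError(ValueError):
    """Raised when a requested group label is absent; lists the available labels."""

    def __init__(self, label: str, available):
        self.label = label
        self.available = sorted(available)
        super().__init__(
            f"unknown group label {label!r}; available: {', '.join(self.available) or '(none)'}"
        )


class ParameterError(ValueError):
    """Raised when a simulation or analysis parameter is outside its valid range."""
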