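"""Exception hierarchy shared across the toolkit."""


class TptcrError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(TptcrError, ValueError):
    """An argument violates a documented precondition."""


class AmbiguousChargeError(TptcrError):
    """Adjacent-peak charge inference does not resolve to a unique integer."""


class IsolationLimitError(TptcrError):
    """One or more precursors exceed the quadrupole isolation m/z limit."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        names = ", ".join(f"{n} (m/z {mz:.1f})" for n, mz in self.offenders)
        super().__init__(f"precursor m/z above isolation limit: {names}")


class InsufficientEvidenceError(TptcrError):
    """Too few ladder members to report a deconvolved mass."""
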